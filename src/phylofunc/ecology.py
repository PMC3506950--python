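"""Per-sample alpha-diversity: inverse Simpson, Chao1 richness, Pielou evenness.

Metric arithmetic is delegated to :mod:`skbio.diversity.alpha`; this
module adds the input contracts the pipeline needs (normalization,
undefined-value flagging, the count conversion for Chao1) and the
per-sample table builder whose columns can be appended to a metadata
table and tested as responses in the association stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio.diversity import alpha as _alpha

from .containers import FeatureTable


def _as_vector(abundances) -> np.ndarray:
    vec = np.asarray(abundances, dtype=float)
    if vec.ndim != 1:
        raise ValueError("expected a 1-D abundance vector")
    if np.any(vec < 0) or np.any(np.isnan(vec)):
        raise ValueError("abundances must be non-negative and non-missing")
    return vec


def observed_richness(abundances) -> int:
    """Number of features with positive abundance."""
    return int(np.count_nonzero(_as_vector(abundances) > 0))


def inverse_simpson(abundances) -> float:
    """1 / sum(p_i^2): the effective number of equally common features.

    The vector is normalized to proportions internally, so the metric is
    invariant to rescaling.
    """
    vec = _as_vector(abundances)
    if vec.sum() == 0:
        raise ValueError("inverse_simpson undefined for an all-zero vector")
    return float(_alpha.enspie(vec))


def to_pseudocounts(abundances) -> np.ndarray:
    """Convert relative abundances to integer pseudo-counts.

    Divides by the smallest positive value and rounds, so the rarest
    observed feature becomes a singleton.
    """
    vec = _as_vector(abundances)
    positive = vec[vec > 0]
    if positive.size == 0:
        raise ValueError("cannot convert an all-zero vector to counts")
    return np.round(vec / positive.min()).astype(np.int64)


def chao1(counts, *, from_relative: bool = False) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1)).

    F1 and F2 are the singleton and doubleton counts, so the input must
    be integer counts.  ``from_relative`` first converts relative
    abundances via :func:`to_pseudocounts`; it is off by default because
    the estimator is count-based.
    """
    vec = _as_vector(counts)
    if from_relative:
        vec = to_pseudocounts(vec)
    elif not np.allclose(vec, np.round(vec)):
        raise ValueError(
            "chao1 requires integer counts; pass from_relative=True to convert"
        )
    return float(_alpha.chao1(vec.astype(np.int64), bias_corrected=True))


def pielou(abundances) -> float:
    """Shannon evenness H / ln(S_obs) in [0, 1]; natural-log Shannon.

    Undefined (NaN) when fewer than two features are present.
    """
    vec = _as_vector(abundances)
    if observed_richness(vec) <= 1:
        return float("nan")
    return float(_alpha.pielou_e(vec))


def alpha_diversity(
    table: FeatureTable, *, chao1_from_relative: bool = True
) -> pd.DataFrame:
    """Per-sample diversity table: inv_simpson, chao1, pielou, richness.

    Chao1 is computed on pseudo-counts derived from the relative
    abundances by default (relative tables carry no raw counts); pielou
    is NaN for samples with richness <= 1.
    """
    records = []
    for sid, row in table.data.iterrows():
        vec = row.to_numpy(dtype=float)
        records.append(
            {
                "inv_simpson": inverse_simpson(vec),
                "chao1": chao1(vec, from_relative=chao1_from_relative),
                "pielou": pielou(vec),
                "richness": observed_richness(vec),
            }
        )
    return pd.DataFrame(records, index=table.data.index)
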