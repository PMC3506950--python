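"""Sparse multivariate association of features with sample metadata.

Per feature, the composite procedure is:

1. variance-stabilize the relative abundance: y = arcsin(sqrt(abundance));
2. **boosted covariate selection** — gradient-boost y on all metadata
   with additive stumps and keep every metadatum used in at least 1% of
   the boosting iterations;
3. **linear model** — ordinary least squares of y on an intercept plus
   the selected metadata (categorical covariates dummy-encoded against
   their most frequent level), giving per-coefficient two-sided t-test
   p-values:  arcsin(sqrt(y_i)) = b0 + sum_p b_p X_ip + e_i;
4. **within-factor Bonferroni** — each categorical level's p is
   multiplied by the factor's number of non-reference levels (capped at
   1);
5. **global Benjamini-Hochberg** — one step-up FDR correction across
   all (feature, metadatum, level) records of the run, yielding q.

A feature counts as significantly associated when any of its records
has q below the threshold (default 0.25).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from ._boost import boost_split_counts
from .config import RunConfig
from .containers import FeatureTable, MetadataTable, ValidationError, align
from .qc import arcsine_sqrt

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "feature", "metadatum", "level", "reference", "n",
    "coefficient", "stderr", "p", "p_adj", "q", "selected_fraction",
]


@dataclass
class BoostingSelection:
    """Per-feature boosting outcome: selection fractions over metadata."""

    feature: str
    fractions: pd.Series  # metadatum -> fraction of iterations (or influence share)
    threshold: float
    mode: str
    seed: int
    selected: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.selected = list(self.fractions.index[self.fractions >= self.threshold])


def _reference_level(col: pd.Series) -> str:
    """Most frequent level; ties broken lexicographically."""
    counts = col.value_counts()
    top = counts[counts == counts.max()].index
    return sorted(top)[0]


def _encode_all(meta: MetadataTable) -> tuple[np.ndarray, list[str]]:
    """Full dummy encoding (no reference drop) for the tree booster."""
    blocks: list[np.ndarray] = []
    owners: list[str] = []
    for name in meta.names:
        col = meta.data[name]
        if meta.types[name] == "continuous":
            blocks.append(col.to_numpy(dtype=float)[:, None])
            owners.append(name)
        else:
            for level in sorted(col.astype(str).unique()):
                blocks.append((col.astype(str) == level).to_numpy(float)[:, None])
                owners.append(name)
    return np.hstack(blocks), owners


def boost_select(
    response,
    meta: MetadataTable,
    config: RunConfig,
    *,
    feature: str = "",
    seed: int | None = None,
) -> BoostingSelection:
    """Select metadata used in at least ``boost_selection_fraction`` of
    boosting iterations (default 1%).

    The response is boosted on all metadata with seeded additive stumps
    (see :mod:`phylofunc._boost`); per metadatum the selection statistic
    is the fraction of iterations whose stump split on it (dummy columns
    of one factor are pooled).  ``selection_mode="influence"`` instead
    uses the metadatum's share of the total squared-error gain.
    """
    if not meta.names:
        raise ValidationError("no metadata columns to select from")
    y = np.asarray(response, dtype=float)
    if np.isnan(y).any():
        raise ValidationError("response contains missing values; impute first")
    if y.size < 10:
        raise ValidationError("boosting selection requires >= 10 samples")
    X, owners = _encode_all(meta)
    if np.isnan(X).any():
        raise ValidationError("metadata contain missing values; impute first")
    seed = config.seed if seed is None else seed
    counts, gains = boost_split_counts(
        X, y,
        n_rounds=config.boost_n_estimators,
        learning_rate=config.boost_learning_rate,
        subsample=config.boost_subsample,
        seed=seed,
    )
    per_meta = pd.Series(0.0, index=pd.Index(meta.names, name="metadatum"))
    values = counts / config.boost_n_estimators
    if config.selection_mode == "influence":
        total = gains.sum()
        values = gains / total if total > 0 else np.zeros_like(gains)
    for owner, v in zip(owners, values):
        per_meta[owner] += v
    return BoostingSelection(
        feature=feature,
        fractions=per_meta,
        threshold=config.boost_selection_fraction,
        mode=config.selection_mode,
        seed=seed,
    )


def _design(meta: MetadataTable, names: list[str]):
    """OLS design for the selected metadata: intercept + z columns.

    Returns (matrix, column descriptors) where each descriptor is
    (metadatum, level or None, reference or None).
    """
    cols = [np.ones(len(meta.data))]
    info: list[tuple[str, str | None, str | None]] = [("Intercept", None, None)]
    for name in names:
        col = meta.data[name]
        if meta.types[name] == "continuous":
            cols.append(col.to_numpy(dtype=float))
            info.append((name, None, None))
        else:
            ref = _reference_level(col.astype(str))
            for level in sorted(col.astype(str).unique()):
                if level == ref:
                    continue
                cols.append((col.astype(str) == level).to_numpy(float))
                info.append((name, level, ref))
    return np.column_stack(cols), info


def _drop_aliased(X: np.ndarray, info: list):
    """Greedily drop columns that do not increase the design rank."""
    keep = [0]
    rank = 1
    for j in range(1, X.shape[1]):
        candidate = X[:, keep + [j]]
        r = np.linalg.matrix_rank(candidate)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            logger.warning("dropping aliased design column %s", info[j])
    return X[:, keep], [info[j] for j in keep]


def fit_feature_model(
    response,
    meta: MetadataTable,
    selected: list[str],
    *,
    feature: str = "",
) -> list[dict]:
    """OLS of the transformed response on the selected metadata.

    One record per non-intercept coefficient: for a continuous
    metadatum its slope; for a categorical one, each level against the
    most frequent (reference) level.  p is the two-sided t-test
    p-value.
    """
    if not selected:
        raise ValidationError("no metadata selected; nothing to fit")
    y = np.asarray(response, dtype=float)
    X, info = _design(meta, list(selected))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        X, info = _drop_aliased(X, info)
    n, k = X.shape
    if n <= k:
        raise ValidationError(
            f"cannot fit: {n} samples for {k} parameters (feature {feature!r})"
        )
    fit = sm.OLS(y, X).fit()
    records = []
    for j, (name, level, ref) in enumerate(info):
        if name == "Intercept":
            continue
        records.append(
            {
                "feature": feature,
                "metadatum": name,
                "level": "" if level is None else level,
                "reference": "" if ref is None else ref,
                "n": int(n),
                "coefficient": float(fit.params[j]),
                "stderr": float(fit.bse[j]),
                "p": float(fit.pvalues[j]),
            }
        )
    return records


def adjust_within_factor(records: list[dict]) -> list[dict]:
    """Bonferroni over a factor's levels, per (feature, metadatum).

    Each record's p is multiplied by the number of non-reference levels
    of its metadatum in the model (1 for continuous), capped at 1.
    """
    counts: dict[tuple[str, str], int] = {}
    for r in records:
        key = (r["feature"], r["metadatum"])
        counts[key] = counts.get(key, 0) + 1
    for r in records:
        k = counts[(r["feature"], r["metadatum"])]
        r["p_adj"] = min(1.0, r["p"] * k)
    return records


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} p_(j) m / j."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def adjust_global_bh(records: list[dict]) -> list[dict]:
    """Attach global BH q-values computed over the level-adjusted p."""
    if not records:
        return records
    q = bh_qvalues([r["p_adj"] for r in records])
    for r, qi in zip(records, q):
        r["q"] = float(qi)
    return records


class BoostedLinearAssociation(BaseEstimator):
    """The full per-feature association procedure over a feature table.

    Parameters mirror :class:`~phylofunc.config.RunConfig`; ``fit``
    takes an (already QC'd and imputed) feature table plus metadata and
    produces:

    ``results_``
        one row per (feature, metadatum, level) with coefficient,
        stderr, nominal p, within-factor-adjusted p, global q and the
        boosting selection fraction;
    ``selections_``
        features x metadata selection fractions;
    ``summary_``
        one row: feature kind, features tested, features with any
        q < ``q_threshold``, and the fraction;
    ``failures_``
        (feature, message) for per-feature errors (the run continues).
    """

    def __init__(self, config: RunConfig | None = None, transform: bool = True):
        self.config = config
        self.transform = transform

    def fit(self, features: FeatureTable, meta: MetadataTable) -> "BoostedLinearAssociation":
        config = self.config if self.config is not None else RunConfig()
        features, meta = align(features, meta)
        records: list[dict] = []
        fractions: dict[str, pd.Series] = {}
        failures: list[tuple[str, str]] = []
        for idx, fid in enumerate(features.feature_ids):
            y = features.data[fid].to_numpy(dtype=float)
            if self.transform:
                y = arcsine_sqrt(y)
            seed = (config.seed * 1000003 + idx) % 2**31
            try:
                sel = boost_select(y, meta, config, feature=fid, seed=seed)
                fractions[fid] = sel.fractions
                if not sel.selected:
                    continue
                recs = fit_feature_model(y, meta, sel.selected, feature=fid)
                for r in recs:
                    r["selected_fraction"] = float(sel.fractions[r["metadatum"]])
                records.extend(adjust_within_factor(recs))
            except ValidationError as exc:
                failures.append((fid, str(exc)))
                logger.warning("feature %r skipped: %s", fid, exc)
        records = adjust_global_bh(records)
        self.results_ = pd.DataFrame(records, columns=RESULT_COLUMNS)
        self.selections_ = pd.DataFrame(fractions).T.reindex(features.feature_ids)
        self.failures_ = failures
        n_tested = len(features.feature_ids) - len(failures)
        if len(self.results_):
            sig = self.results_[self.results_["q"] < config.q_threshold]["feature"].nunique()
        else:
            sig = 0
        self.summary_ = pd.DataFrame(
            [
                {
                    "feature_kind": features.feature_kind,
                    "n_features_tested": n_tested,
                    "n_significant": sig,
                    "fraction_significant": sig / n_tested if n_tested else np.nan,
                }
            ]
        )
        return self


def associate_all(
    features: FeatureTable,
    meta: MetadataTable,
    config: RunConfig | None = None,
    *,
    transform: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Functional wrapper over :class:`BoostedLinearAssociation`.

    Returns the (results, summary) tables.
    """
    est = BoostedLinearAssociation(config=config, transform=transform).fit(features, meta)
    return est.results_, est.summary_
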