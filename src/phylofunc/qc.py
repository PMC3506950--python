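"""Pre-modeling quality control.

The chain, in the order applied by :class:`QCPipeline`:

1. drop metadata columns with more than 10% missing values or constant
   over the non-missing entries;
2. drop features of very low abundance (< 0.001 in at least 90% of
   samples);
3. set per-feature outlier cells outside the outer Tukey fence
   (quartiles +/- 3x IQR) to missing;
4. impute: missing feature cells with the feature's mean abundance,
   missing categorical metadata with a dedicated ``"NA"`` level, missing
   continuous metadata with the column mean.

The variance-stabilizing arcsine square-root transform applied to
relative abundances before linear modeling also lives here.

Every alteration is recorded in a :class:`QCReport`; replaying a report
on the original input reproduces the output exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import RunConfig
from .containers import FeatureTable, MetadataTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Full record of what QC dropped, masked and imputed, with reasons."""

    dropped_metadata: list[tuple[str, str]] = field(default_factory=list)
    dropped_features: list[tuple[str, str]] = field(default_factory=list)
    outlier_cells: list[tuple[str, str, float]] = field(default_factory=list)
    imputed_feature_cells: list[tuple[str, str, float]] = field(default_factory=list)
    imputed_metadata_cells: list[tuple[str, str, object]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    quantile_rule: str = "linear"  # fences depend on the quantile definition

    @property
    def n_imputed(self) -> int:
        return len(self.imputed_feature_cells) + len(self.imputed_metadata_cells)

    def merge(self, other: "QCReport") -> "QCReport":
        self.dropped_metadata += other.dropped_metadata
        self.dropped_features += other.dropped_features
        self.outlier_cells += other.outlier_cells
        self.imputed_feature_cells += other.imputed_feature_cells
        self.imputed_metadata_cells += other.imputed_metadata_cells
        self.warnings += other.warnings
        return self

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, reason in self.dropped_metadata:
            rows.append(("dropped_metadata", "", name, reason))
        for fid, reason in self.dropped_features:
            rows.append(("dropped_feature", "", fid, reason))
        for s, f, v in self.outlier_cells:
            rows.append(("outlier_cell", s, f, repr(v)))
        for s, f, v in self.imputed_feature_cells:
            rows.append(("imputed_feature_cell", s, f, repr(v)))
        for s, m, v in self.imputed_metadata_cells:
            rows.append(("imputed_metadata_cell", s, m, repr(v)))
        for w in self.warnings:
            rows.append(("warning", "", "", w))
        return pd.DataFrame(rows, columns=["event", "sample", "target", "detail"])

    def replay(
        self, features: FeatureTable, meta: MetadataTable
    ) -> tuple[FeatureTable, MetadataTable]:
        """Reapply the recorded transformation to the original inputs."""
        fdata = features.data.drop(columns=[f for f, _ in self.dropped_features])
        mdata = meta.data.drop(columns=[m for m, _ in self.dropped_metadata])
        mdata = mdata.astype(object)
        for s, f, _ in self.outlier_cells:
            fdata.loc[s, f] = np.nan
        for s, f, v in self.imputed_feature_cells:
            fdata.loc[s, f] = v
        for s, m, v in self.imputed_metadata_cells:
            mdata.loc[s, m] = v
        types = {n: t for n, t in meta.types.items() if n in mdata.columns}
        for n, t in types.items():
            if t == "continuous":
                mdata[n] = mdata[n].astype(float)
        return (
            FeatureTable(fdata, feature_kind=features.feature_kind,
                         relative=False),
            MetadataTable(mdata, types),
        )


def filter_metadata(
    meta: MetadataTable, max_missing: float = 0.10
) -> tuple[MetadataTable, QCReport]:
    """Drop metadata with missing fraction strictly above ``max_missing``
    or constant over the non-missing entries."""
    report = QCReport()
    keep = []
    for name in meta.names:
        col = meta.data[name]
        if col.isna().mean() > max_missing:
            report.dropped_metadata.append((name, f"missingness>{max_missing:g}"))
        elif col.dropna().nunique() <= 1:
            report.dropped_metadata.append((name, "invariant"))
        else:
            keep.append(name)
    if not keep:
        raise ValidationError("all metadata columns removed by QC; nothing to model")
    return meta.subset(keep), report


def filter_features(
    table: FeatureTable, low_abundance: float = 0.001, prevalence: float = 0.90
) -> tuple[FeatureTable, QCReport]:
    """Drop features below ``low_abundance`` in at least ``prevalence``
    of samples (missing cells count as below)."""
    report = QCReport()
    below = (table.data < low_abundance) | table.data.isna()
    frac_below = below.mean(axis=0)
    drop = frac_below[frac_below >= prevalence].index
    for fid in drop:
        report.dropped_features.append(
            (fid, f"<{low_abundance:g} in >={prevalence:.0%} of samples")
        )
    kept = table.data.drop(columns=drop)
    if kept.shape[1] == 0:
        raise ValidationError("all features removed by the low-abundance filter")
    return (
        FeatureTable(kept, feature_kind=table.feature_kind, relative=table.relative),
        report,
    )


def _fences(values: np.ndarray, multiplier: float) -> tuple[float, float]:
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    return q1 - multiplier * iqr, q3 + multiplier * iqr


def remove_outliers(
    table: FeatureTable, fence_multiplier: float = 3.0
) -> tuple[FeatureTable, QCReport]:
    """Mask per-feature cells outside the outer fence as missing.

    The fence is computed per feature from its non-missing values with
    linearly interpolated quartiles.  Features with fewer than 4
    non-missing values, or zero IQR, are left untouched with a warning.
    """
    report = QCReport()
    data = table.data.copy()
    for fid in data.columns:
        col = data[fid]
        values = col.dropna().to_numpy(dtype=float)
        if values.size < 4:
            report.warnings.append(f"feature {fid!r}: <4 values, fence skipped")
            continue
        lo, hi = _fences(values, fence_multiplier)
        if hi == lo:
            if not np.all(values == values[0]):
                report.warnings.append(f"feature {fid!r}: zero IQR, fence skipped")
                continue
            continue  # constant feature: nothing outside the (degenerate) fence
        mask = (col < lo) | (col > hi)
        for sid in col.index[mask.fillna(False)]:
            report.outlier_cells.append((sid, fid, float(col[sid])))
            data.loc[sid, fid] = np.nan
    return (
        FeatureTable(data, feature_kind=table.feature_kind, relative=table.relative),
        report,
    )


def impute(
    table: FeatureTable,
    meta: MetadataTable,
    mode: str = "feature",
) -> tuple[FeatureTable, MetadataTable, QCReport]:
    """Fill missing cells.

    Feature cells get the feature's mean over non-missing samples
    (``mode="feature"``, the default) or the sample's mean over
    non-missing features (``mode="sample"``).  Missing categorical
    metadata become a dedicated ``"NA"`` level; missing continuous
    metadata get the column mean.

    Mean-imputing masked cells can push a sample's total slightly above
    1, so the output table is no longer declared strictly relative
    (cells remain valid proportions).
    """
    if mode not in ("feature", "sample"):
        raise ValueError("impute mode must be 'feature' or 'sample'")
    report = QCReport()
    fdata = table.data.copy()
    for fid in fdata.columns:
        col = fdata[fid]
        if col.isna().all():
            raise ValidationError(f"feature {fid!r} is entirely missing")
    missing = np.asarray(fdata.isna())
    if missing.any():
        if mode == "feature":
            fill = np.broadcast_to(
                fdata.mean(axis=0, skipna=True).to_numpy()[None, :], fdata.shape
            )
        else:
            fill = np.broadcast_to(
                fdata.mean(axis=1, skipna=True).to_numpy()[:, None], fdata.shape
            )
        for i, j in zip(*missing.nonzero()):
            v = float(fill[i, j])
            report.imputed_feature_cells.append((fdata.index[i], fdata.columns[j], v))
            fdata.iloc[i, j] = v
    mdata = meta.data.copy().astype(object)
    for name in mdata.columns:
        col = mdata[name]
        na = col.isna()
        if not na.any():
            continue
        if meta.types[name] == "categorical":
            value: object = "NA"
        else:
            value = float(pd.to_numeric(col.dropna()).mean())
        for sid in col.index[na]:
            report.imputed_metadata_cells.append((sid, name, value))
            mdata.loc[sid, name] = value
    for name, t in meta.types.items():
        if t == "continuous":
            mdata[name] = mdata[name].astype(float)
    return (
        FeatureTable(fdata, feature_kind=table.feature_kind, relative=False),
        MetadataTable(mdata, dict(meta.types)),
        report,
    )


def arcsine_sqrt(x):
    """Variance-stabilizing arcsin(sqrt(x)) for proportions in [0, 1].

    Values in (1, 1 + 1e-6] are clamped to 1; anything else outside
    [0, 1] raises.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1 + 1e-6):
        bad = arr[(arr < 0) | (arr > 1 + 1e-6)].ravel()[0]
        raise ValueError(f"arcsine_sqrt: value {bad!r} outside [0, 1]")
    out = np.arcsin(np.sqrt(np.clip(arr, 0.0, 1.0)))
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(out, index=x.index, columns=x.columns)
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index)
    return out


def inverse_arcsine_sqrt(z):
    """Back-transform sin^2(z); inverse of :func:`arcsine_sqrt` on [0, pi/2]."""
    arr = np.asarray(z, dtype=float)
    if np.any(arr < 0) or np.any(arr > math.pi / 2 + 1e-12):
        raise ValueError("inverse_arcsine_sqrt: value outside [0, pi/2]")
    out = np.sin(arr) ** 2
    return float(out) if np.ndim(z) == 0 else out


class QCPipeline(BaseEstimator):
    """The full QC chain as one configurable step.

    Order: metadata filter -> low-abundance feature filter -> outer-fence
    outlier masking -> imputation.  Masking before imputation keeps
    outliers out of the imputed means.

    After :meth:`fit_transform`, ``report_`` holds the merged
    :class:`QCReport`.
    """

    def __init__(
        self,
        low_abundance: float = 0.001,
        prevalence: float = 0.90,
        fence_multiplier: float = 3.0,
        max_missing: float = 0.10,
        impute_mode: str = "feature",
    ):
        self.low_abundance = low_abundance
        self.prevalence = prevalence
        self.fence_multiplier = fence_multiplier
        self.max_missing = max_missing
        self.impute_mode = impute_mode

    @classmethod
    def from_config(cls, config: RunConfig) -> "QCPipeline":
        return cls(
            low_abundance=config.low_abundance,
            prevalence=config.prevalence,
            fence_multiplier=config.fence_multiplier,
            max_missing=config.max_missing,
            impute_mode=config.impute_mode,
        )

    #: safety cap on the outlier-mask/impute fixed-point iteration
    MAX_FENCE_PASSES = 10

    def fit_transform(
        self, features: FeatureTable, meta: MetadataTable
    ) -> tuple[FeatureTable, MetadataTable]:
        meta2, report = filter_metadata(meta, self.max_missing)
        feats, r2 = filter_features(features, self.low_abundance, self.prevalence)
        report.merge(r2)
        # Iterate masking + imputation to a fixed point: imputing an
        # outlier shifts the feature's quantiles, which can expose
        # further cells; stopping only when a pass flags nothing makes
        # the whole chain idempotent.
        meta3 = meta2
        for i in range(self.MAX_FENCE_PASSES):
            masked, r_mask = remove_outliers(feats, self.fence_multiplier)
            if i > 0 and not r_mask.outlier_cells:
                report.warnings.extend(
                    w for w in r_mask.warnings if w not in report.warnings
                )
                break
            feats, meta3, r_imp = impute(masked, meta3, self.impute_mode)
            report.merge(r_mask).merge(r_imp)
        else:
            report.warnings.append(
                f"outlier fences did not stabilize in {self.MAX_FENCE_PASSES} passes"
            )
        self.report_ = report
        return feats, meta3


def run_qc(
    features: FeatureTable, meta: MetadataTable, config: RunConfig | None = None
) -> tuple[FeatureTable, MetadataTable, QCReport]:
    """Functional wrapper over :class:`QCPipeline`."""
    qc = QCPipeline() if config is None else QCPipeline.from_config(config)
    f, m = qc.fit_transform(features, meta)
    return f, m, qc.report_
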