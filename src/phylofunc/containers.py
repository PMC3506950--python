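"""Core tabular containers shared by all pipeline stages.

Two light wrappers around :class:`pandas.DataFrame` carry the domain
semantics the pipeline needs beyond raw numbers: a feature table knows
whether its features are taxa, genes (KO families) or gene sets and
whether its rows are relative abundances; a metadata table knows the
declared statistical type of every column and keeps missingness explicit
(``NaN``) instead of silently dropping rows.

The canonical orientation everywhere in the package is samples x features
(samples as rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_KINDS = ("taxon", "gene", "gene_set")
METADATA_TYPES = ("continuous", "categorical")

#: tolerance on per-sample sums of a relative-abundance table
REL_SUM_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} IDs: {dups}")


@dataclass
class FeatureTable:
    """Samples x features matrix of non-negative abundances.

    Parameters
    ----------
    data
        DataFrame with sample IDs as index and feature IDs as columns.
    feature_kind
        One of ``taxon``, ``gene``, ``gene_set``.
    relative
        Declare rows as relative abundances; per-sample sums must then
        not exceed ``1 + 1e-6``.  Raw copy-number mixtures (e.g. inferred
        KO abundance before renormalization) use ``relative=False``.
    taxonomy
        Optional per-feature lineage strings (rank:name pairs), indexed
        by feature ID.
    """

    data: pd.DataFrame
    feature_kind: str = "taxon"
    relative: bool = True
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValidationError(
                f"feature_kind must be one of {FEATURE_KINDS}, got {self.feature_kind!r}"
            )
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "feature")
        values = self.data.to_numpy(dtype=float, na_value=np.nan)
        neg = np.asarray(values < 0).nonzero()
        if neg[0].size:
            i, j = neg[0][0], neg[1][0]
            raise ValidationError(
                f"negative abundance {values[i, j]!r} at sample "
                f"{self.data.index[i]!r}, feature {self.data.columns[j]!r}"
            )
        if self.relative:
            sums = np.nansum(values, axis=1)
            bad = np.nonzero(sums > 1 + REL_SUM_TOL)[0]
            if bad.size:
                raise ValidationError(
                    f"sample {self.data.index[bad[0]]!r} declared relative but "
                    f"sums to {sums[bad[0]]:.6g} > 1"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.data.copy(),
            feature_kind=self.feature_kind,
            relative=self.relative,
            taxonomy=None if self.taxonomy is None else self.taxonomy.copy(),
        )

    def renormalized(self) -> "FeatureTable":
        """Return a copy with each sample rescaled to sum to 1."""
        sums = self.data.sum(axis=1)
        if (sums <= 0).any():
            bad = sums.index[sums <= 0][0]
            raise ValidationError(f"sample {bad!r} has zero total abundance")
        return FeatureTable(
            self.data.div(sums, axis=0), feature_kind=self.feature_kind,
            relative=True, taxonomy=self.taxonomy,
        )


@dataclass
class MetadataTable:
    """Samples x metadata with explicit per-column types and missingness.

    Continuous columns are float with ``NaN`` for missing; categorical
    columns are object/string with ``NaN`` for missing (until imputation
    introduces the dedicated ``"NA"`` level).
    """

    data: pd.DataFrame
    types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "metadata")
        for name in self.data.columns:
            t = self.types.get(name)
            if t is None:
                raise ValidationError(f"no declared type for metadatum {name!r}")
            if t not in METADATA_TYPES:
                raise ValidationError(
                    f"metadatum {name!r}: type must be one of {METADATA_TYPES}, got {t!r}"
                )
            if t == "continuous" and not pd.api.types.is_numeric_dtype(self.data[name]):
                raise ValidationError(
                    f"metadatum {name!r} declared continuous but holds non-numeric values"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def names(self) -> list:
        return list(self.data.columns)

    def missing_fraction(self, name: str) -> float:
        return float(self.data[name].isna().mean())

    def copy(self) -> "MetadataTable":
        return MetadataTable(self.data.copy(), dict(self.types))

    def subset(self, names) -> "MetadataTable":
        names = list(names)
        return MetadataTable(self.data[names].copy(), {n: self.types[n] for n in names})


def align(features: FeatureTable, meta: MetadataTable) -> tuple[FeatureTable, MetadataTable]:
    """Row-align a feature table with its metadata.

    Every feature-table sample must have a metadata row; extra metadata
    rows are dropped.
    """
    missing = [s for s in features.sample_ids if s not in meta.data.index]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing}")
    meta_aligned = MetadataTable(meta.data.loc[features.sample_ids].copy(), dict(meta.types))
    return features, meta_aligned
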