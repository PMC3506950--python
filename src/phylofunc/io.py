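"""Readers and writers for the tab-delimited interchange formats.

All tables are UTF-8 TSV with a header row.  Feature tables are accepted
in either orientation (the field uses both; PCL-style files put features
as rows) and normalized internally to samples x features.  Missing
metadata cells are an empty string or literal ``NA`` on disk and ``NaN``
in memory; ``NA`` is written on output.

Writers can embed the :class:`~phylofunc.config.RunConfig` used for a
run as a ``#``-prefixed comment line, so every output file records the
seed and thresholds that produced it; readers skip comment lines.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .containers import FeatureTable, MetadataTable, ValidationError

MISSING_MARKERS = ("", "NA")
CONFIG_PREFIX = "# phylofunc-config: "


def _read_rows(path: str | Path) -> list[list[str]]:
    """Read TSV rows, skipping comment lines, enforcing rectangularity."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")
                if r and not r[0].startswith("#")]
    if not rows:
        raise ValidationError(f"{path}: empty table")
    width = len(rows[0])
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValidationError(
                f"{path}: ragged row {i} has {len(row)} fields, expected {width}"
            )
    return rows


def _parse_numeric_body(rows: list[list[str]], path) -> pd.DataFrame:
    header = [c.strip() for c in rows[0][1:]]
    index = []
    body = np.empty((len(rows) - 1, len(header)), dtype=float)
    for i, row in enumerate(rows[1:]):
        index.append(row[0].strip())
        for j, cell in enumerate(row[1:]):
            try:
                body[i, j] = float(cell)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric cell {cell!r} at row {row[0]!r}, "
                    f"column {header[j]!r}"
                ) from None
    return pd.DataFrame(body, index=index, columns=header)


def read_feature_table(
    path: str | Path,
    orientation: str = "samples_as_rows",
    *,
    feature_kind: str = "taxon",
    relative: bool = True,
) -> FeatureTable:
    """Read a feature table TSV in either orientation.

    Negative values, duplicate IDs, non-numeric and ragged rows are
    rejected with the offending row/column named.
    """
    if orientation not in ("samples_as_rows", "features_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _parse_numeric_body(_read_rows(path), path)
    if orientation == "features_as_rows":
        df = df.T
    return FeatureTable(df, feature_kind=feature_kind, relative=relative)


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    orientation: str = "samples_as_rows",
    *,
    config: RunConfig | None = None,
) -> None:
    df = table.data if orientation == "samples_as_rows" else table.data.T
    label = "sample" if orientation == "samples_as_rows" else "feature"
    with open(path, "w", encoding="utf-8") as fh:
        if config is not None:
            fh.write(CONFIG_PREFIX + config.to_json() + "\n")
        df.to_csv(fh, sep="\t", index_label=label)


def read_metadata(path: str | Path, type_spec: dict[str, str]) -> MetadataTable:
    """Read a samples-as-rows metadata TSV with declared column types.

    Empty cells and literal ``NA`` mark missing values; a continuous
    column with an unparseable cell raises with the cell named.
    """
    rows = _read_rows(path)
    header = [c.strip() for c in rows[0][1:]]
    unknown = [c for c in header if c not in type_spec]
    if unknown:
        raise ValidationError(f"{path}: columns without declared type: {unknown}")
    index = [r[0].strip() for r in rows[1:]]
    columns: dict[str, list] = {c: [] for c in header}
    for row in rows[1:]:
        for name, cell in zip(header, row[1:]):
            cell = cell.strip()
            if cell in MISSING_MARKERS:
                columns[name].append(np.nan)
            elif type_spec[name] == "continuous":
                try:
                    columns[name].append(float(cell))
                except ValueError:
                    raise ValidationError(
                        f"{path}: metadatum {name!r} declared continuous but "
                        f"sample {row[0]!r} holds {cell!r}"
                    ) from None
            else:
                columns[name].append(cell)
    data = pd.DataFrame(columns, index=index)
    return MetadataTable(data, {c: type_spec[c] for c in header})


def write_metadata(
    meta: MetadataTable, path: str | Path, *, config: RunConfig | None = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if config is not None:
            fh.write(CONFIG_PREFIX + config.to_json() + "\n")
        fh.write("# types: " + ",".join(f"{n}={t}" for n, t in meta.types.items()) + "\n")
        meta.data.to_csv(fh, sep="\t", index_label="sample", na_rep="NA")


def read_gene_set_map(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column (gene_set_id, ko_id) membership TSV."""
    rows = _read_rows(path)
    if [c.strip() for c in rows[0]] != ["gene_set_id", "ko_id"]:
        raise ValidationError(
            f"{path}: expected header 'gene_set_id<TAB>ko_id', got {rows[0]!r}"
        )
    mapping: dict[str, list[str]] = {}
    for row in rows[1:]:
        mapping.setdefault(row[0].strip(), []).append(row[1].strip())
    return mapping


def write_gene_set_map(mapping: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_set_id\tko_id\n")
        for gs, kos in mapping.items():
            for ko in kos:
                fh.write(f"{gs}\t{ko}\n")


def write_table(
    df: pd.DataFrame, path: str | Path, *,
    index_label: str = "id", config: RunConfig | None = None,
) -> None:
    """Write a generic results table with an optional embedded config line."""
    with open(path, "w", encoding="utf-8") as fh:
        if config is not None:
            fh.write(CONFIG_PREFIX + config.to_json() + "\n")
        df.to_csv(fh, sep="\t", index_label=index_label, na_rep="NA")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")
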