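"""Tabular data model and TSV input/output.

Two containers travel through the pipeline:

* :class:`FeatureTable` — a features x samples numeric matrix (taxon counts,
  relative abundances, or gene expression) in the classic OTU-table layout:
  tab-separated, header row of sample identifiers, first column of feature
  identifiers, ``#`` comment lines ignored.
* sample metadata — a :class:`pandas.DataFrame` indexed by ``sample_id`` with
  required columns ``group`` and ``experiment``, an optional
  ``strain_or_cohort`` column, and any number of numeric phenotype columns
  (e.g. fasting glucose in mg/dl, AUC-GTT in arbitrary units). Missing
  phenotype cells are kept as NaN and handled pairwise-complete downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, SchemaError

__all__ = [
    "FeatureTable",
    "read_feature_table",
    "write_feature_table",
    "read_sample_metadata",
    "write_records",
    "check_alignment",
    "phenotype_columns",
    "METADATA_RESERVED",
]

#: metadata columns that are not phenotypes
METADATA_RESERVED = ("group", "experiment", "strain_or_cohort")

_KINDS = ("counts", "relative")


@dataclass
class FeatureTable:
    """Features x samples matrix with identifier bookkeeping.

    ``kind`` is ``"counts"`` (non-negative reads) or ``"relative"`` (each
    sample column sums to 1 within 1e-6). Identifiers must be unique;
    validation runs on construction.
    """

    values: pd.DataFrame
    kind: str = "counts"
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise DataError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        df = self.values
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate feature id(s): {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample id(s): {dupes}")
        arr = df.to_numpy(dtype=float)
        if np.isnan(arr).any():
            rows, cols = np.nonzero(np.isnan(arr))
            raise DataError(
                f"missing/non-numeric value at feature {df.index[rows[0]]!r}, "
                f"sample {df.columns[cols[0]]!r}"
            )
        if (arr < 0).any():
            rows, cols = np.nonzero(arr < 0)
            raise DataError(
                f"negative value at feature {df.index[rows[0]]!r}, "
                f"sample {df.columns[cols[0]]!r}"
            )
        if self.kind == "relative":
            sums = arr.sum(axis=0)
            bad = np.nonzero(np.abs(sums - 1.0) > 1e-6)[0]
            if bad.size:
                raise DataError(
                    f"relative-abundance column(s) not summing to 1: "
                    f"{[str(df.columns[i]) for i in bad[:5]]}"
                )
        self._validated = True

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_feature_table(path, kind: str = "counts") -> FeatureTable:
    """Read a classic tab-separated feature table.

    Header row of sample ids, first column of feature ids. Duplicate ids,
    ragged rows and non-numeric cells raise :class:`SchemaError` naming the
    offending row/column.
    """
    try:
        raw = pd.read_csv(
            path, sep="\t", comment="#", index_col=0, dtype=str, header=0
        )
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise SchemaError(f"cannot parse feature table {path}: {exc}") from exc
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise SchemaError(f"{path}: duplicated feature id(s) {dupes}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        raise SchemaError(
            f"{path}: non-numeric cell at feature {raw.index[rows[0]]!r}, "
            f"sample {raw.columns[cols[0]]!r} (value {raw.iloc[rows[0], cols[0]]!r})"
        )
    if numeric.isna().to_numpy().any():
        rows, cols = np.nonzero(numeric.isna().to_numpy())
        raise SchemaError(
            f"{path}: empty cell at feature {raw.index[rows[0]]!r}, "
            f"sample {raw.columns[cols[0]]!r}"
        )
    numeric.index = numeric.index.astype(str)
    numeric.index.name = "feature_id"
    numeric.columns = numeric.columns.astype(str)
    try:
        return FeatureTable(values=numeric.astype(float), kind=kind)
    except DataError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table as TSV (full float precision, round-trip safe)."""
    table.values.to_csv(path, sep="\t", float_format="%.17g", index_label="feature_id")


def read_sample_metadata(path) -> pd.DataFrame:
    """Read sample metadata as a DataFrame indexed by ``sample_id``.

    Required columns: ``sample_id``, ``group``, ``experiment``. Any column
    outside :data:`METADATA_RESERVED` is parsed as a numeric phenotype;
    blank cells become NaN (explicit missing markers).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "group", "experiment"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise SchemaError(f"{path}: duplicated sample id(s) {dupes}")
    df = df.set_index("sample_id")
    for col in df.columns:
        if col in METADATA_RESERVED:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            raise SchemaError(
                f"{path}: non-numeric phenotype value in column {col!r} "
                f"for sample {bad.idxmax()!r}"
            )
        df[col] = converted
    return df


def write_records(records: pd.DataFrame, path) -> None:
    """Write a record table as TSV.

    Deterministic column order (as given), stable row order (input order),
    floats rendered with 10 significant digits. An empty collection yields a
    header-only file.
    """
    records.to_csv(path, sep="\t", float_format="%.10g", index=False)


def phenotype_columns(meta: pd.DataFrame) -> list[str]:
    """Names of the numeric phenotype columns of a metadata table."""
    return [c for c in meta.columns if c not in METADATA_RESERVED]


def check_alignment(table: FeatureTable, meta: pd.DataFrame) -> None:
    """Fail fast when a feature table and metadata disagree on samples.

    Every sample of the feature table must be present in the metadata
    (the metadata may describe additional samples, e.g. from a second
    experiment). Raises :class:`AlignmentError` listing the set difference.
    """
    table_samples = set(table.sample_ids)
    meta_samples = set(map(str, meta.index))
    missing = sorted(table_samples - meta_samples)
    if missing:
        raise AlignmentError(
            f"samples present in feature table but absent from metadata: {missing}"
        )
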