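"""Loading ChEMBL-schema tables and applying record-validity filters.

Tables are held as :class:`pandas.DataFrame` objects with fixed column sets
(see :data:`ACTIVITY_COLUMNS` and :data:`ASSAY_COLUMNS`).  Two source kinds are
supported: a directory of per-table delimited text dumps (tab-separated, header
row mandatory, UTF-8, ``\\N`` as the explicit null token — ChEMBL's own dump
conventions) or an SQLite database (a file path or ``sqlite:///`` URL) holding
the same tables.

Required tables
---------------
``activities``
    activity_id, assay_key, compound_id, pchembl, standard_type,
    standard_relation, standard_units, data_validity_comment
``assays``
    assay_key, chembl_assay_id, target_id, doc_id, description, assay_type,
    assay_organism, assay_category, assay_tax_id, assay_strain, assay_tissue,
    assay_cell_type, assay_subcellular_fraction, bao_format, variant_id,
    confidence_score
``docs``
    doc_id, doc_date (nullable; a non-null value marks the document as dated,
    i.e. as coming from the dated literature/patent corpus rather than a
    screening deposition)
"""

from __future__ import annotations

import sqlite3
from pathlib import Path

import numpy as np
import pandas as pd

NULL_TOKEN = r"\N"

ACTIVITY_COLUMNS = [
    "activity_id",
    "assay_key",
    "compound_id",
    "pchembl",
    "standard_type",
    "standard_relation",
    "standard_units",
    "data_validity_comment",
]

ASSAY_METADATA_FIELDS = [
    "assay_type",
    "assay_organism",
    "assay_category",
    "assay_tax_id",
    "assay_strain",
    "assay_tissue",
    "assay_cell_type",
    "assay_subcellular_fraction",
    "bao_format",
]

ASSAY_COLUMNS = [
    "assay_key",
    "chembl_assay_id",
    "target_id",
    "doc_id",
    "description",
    *ASSAY_METADATA_FIELDS,
    "variant_id",
    "confidence_score",
]

DOC_COLUMNS = ["doc_id", "doc_date"]

_ACTIVITY_INT = ["activity_id", "assay_key", "compound_id"]
_ASSAY_INT = ["assay_key"]
_ASSAY_NULLABLE_INT = ["doc_id", "assay_tax_id", "variant_id", "confidence_score"]

TABLE_FILES = {"activities": "activities.txt", "assays": "assays.txt", "docs": "docs.txt"}


class SchemaError(ValueError):
    """A required table or column is missing from the source."""


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"table {table!r} is missing required column(s): {missing}")


def _read_dump_table(path: Path) -> pd.DataFrame:
    # keep_default_na=False so empty strings stay as "" and only \N is null
    return pd.read_csv(
        path,
        sep="\t",
        na_values=[NULL_TOKEN],
        keep_default_na=False,
        dtype=str,
        encoding="utf-8",
    )


def _read_sqlite_table(con: sqlite3.Connection, table: str) -> pd.DataFrame:
    try:
        df = pd.read_sql_query(f"SELECT * FROM {table}", con)
    except (pd.errors.DatabaseError, sqlite3.Error) as exc:  # pragma: no cover
        raise SchemaError(f"cannot read table {table!r}: {exc}") from exc
    return df


def _coerce_nullable_int(s: pd.Series) -> pd.Series:
    return pd.to_numeric(s, errors="raise").astype("Int64")


def _typed_activities(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, ACTIVITY_COLUMNS, "activities")
    out = df[ACTIVITY_COLUMNS].copy()
    for c in _ACTIVITY_INT:
        out[c] = pd.to_numeric(out[c], errors="raise").astype(np.int64)
    out["pchembl"] = pd.to_numeric(out["pchembl"], errors="coerce")
    for c in ["standard_type", "standard_relation", "standard_units", "data_validity_comment"]:
        out[c] = out[c].astype("string")
    if out["activity_id"].duplicated().any():
        raise SchemaError("activities table contains duplicate activity_id values")
    bad = out["pchembl"].notna() & ~out["pchembl"].between(0.0, 14.0)
    if bad.any():
        raise SchemaError(
            f"{int(bad.sum())} pchembl value(s) outside the plausible 0-14 range"
        )
    return out


def _typed_assays(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, ASSAY_COLUMNS, "assays")
    out = df[ASSAY_COLUMNS].copy()
    for c in _ASSAY_INT:
        out[c] = pd.to_numeric(out[c], errors="raise").astype(np.int64)
    for c in _ASSAY_NULLABLE_INT:
        out[c] = _coerce_nullable_int(out[c])
    text_cols = [
        c for c in ASSAY_COLUMNS if c not in _ASSAY_INT and c not in _ASSAY_NULLABLE_INT
    ]
    for c in text_cols:
        out[c] = out[c].astype("string")
    if out["assay_key"].duplicated().any():
        raise SchemaError("assays table contains duplicate assay_key values")
    if out["chembl_assay_id"].duplicated().any():
        raise SchemaError("assays table contains duplicate chembl_assay_id values")
    conf = out["confidence_score"]
    bad = conf.notna() & ~conf.between(0, 9)
    if bad.any():
        raise SchemaError("confidence_score values must be in 0-9 when present")
    return out


def _load_raw(source) -> dict[str, pd.DataFrame]:
    """Resolve *source* to the three raw tables."""
    if isinstance(source, dict):
        tables = {}
        for name in TABLE_FILES:
            if name not in source:
                raise SchemaError(f"in-memory source is missing table {name!r}")
            tables[name] = source[name].copy()
        return tables
    src = str(source)
    if src.startswith("sqlite:///"):
        src = src[len("sqlite:///"):]
    path = Path(src)
    if path.is_dir():
        tables = {}
        for name, fname in TABLE_FILES.items():
            fpath = path / fname
            if not fpath.exists():
                raise FileNotFoundError(f"table dump not found: {fpath}")
            tables[name] = _read_dump_table(fpath)
        return tables
    if path.is_file():
        con = sqlite3.connect(str(path))
        try:
            return {name: _read_sqlite_table(con, name) for name in TABLE_FILES}
        finally:
            con.close()
    raise FileNotFoundError(f"cannot resolve table source: {source!r}")


def load_tables(source, readout: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load activity and assay tables for one readout.

    Parameters
    ----------
    source
        Directory of per-table dumps, SQLite path/URL, or a dict of raw
        DataFrames keyed ``activities``/``assays``/``docs``.
    readout
        ``"IC50"`` or ``"Ki"`` — selects on ``standard_type``.

    Returns
    -------
    activities, assays
        Typed DataFrames.  Activities are restricted to the requested readout;
        assays are restricted to those referenced by at least one returned
        activity.  The assay table gains a boolean ``source_has_doc_date``
        column: True iff the assay's document carries a non-null date.
    """
    readout = str(readout)
    if readout.upper() not in {"IC50", "KI"}:
        raise ValueError(f"readout must be 'IC50' or 'Ki', got {readout!r}")
    raw = _load_raw(source)
    activities = _typed_activities(raw["activities"])
    assays = _typed_assays(raw["assays"])
    docs = raw["docs"].copy()
    _require_columns(docs, DOC_COLUMNS, "docs")
    docs["doc_id"] = _coerce_nullable_int(docs["doc_id"])
    docs["doc_date"] = docs["doc_date"].astype("string")

    mask = activities["standard_type"].str.upper() == readout.upper()
    activities = activities.loc[mask].reset_index(drop=True)

    referenced = set(activities["assay_key"].tolist())
    assays = assays.loc[assays["assay_key"].isin(referenced)].reset_index(drop=True)

    dated = set(
        docs.loc[docs["doc_date"].notna(), "doc_id"].dropna().astype(int).tolist()
    )
    assays["source_has_doc_date"] = [
        (d in dated) if pd.notna(d) else False for d in assays["doc_id"]
    ]
    return activities, assays


def filter_valid_activities(activities: pd.DataFrame) -> pd.DataFrame:
    """Keep only records usable for compatibility analysis.

    A record survives iff its relation is the unqualified ``"="``, its units
    are ``"nM"``, its pchembl value is present, and it carries no data-validity
    comment.  Order is preserved and the operation is idempotent.
    """
    if activities.empty:
        return activities.copy()
    mask = (
        (activities["standard_relation"] == "=")
        & (activities["standard_units"] == "nM")
        & activities["pchembl"].notna()
        & activities["data_validity_comment"].isna()
    )
    return activities.loc[mask.fillna(False)].reset_index(drop=True)


def write_dump(tables: dict[str, pd.DataFrame], directory) -> None:
    """Write tables back out in the flat-file dump dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        fname = TABLE_FILES.get(name, f"{name}.txt")
        out = df.copy()
        if "source_has_doc_date" in out.columns:
            out = out.drop(columns=["source_has_doc_date"])
        out.to_csv(
            directory / fname,
            sep="\t",
            index=False,
            na_rep=NULL_TOKEN,
            encoding="utf-8",
        )
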