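"""Conditions hash and combined per-target dataset assembly.

Two assays that share a target and agree on every available metadata field are
equivalent as far as the database can tell.  The *conditions hash* is the MD5
digest of a canonical serialization of ten assay metadata fields (the nine
matching fields plus ``variant_id``); grouping by (target_id, conditions_hash)
partitions the retained assays into combinable datasets.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import pandas as pd

from assaycompat.chembl_io import ASSAY_METADATA_FIELDS
from assaycompat.curation import flag_mutant_assays, filter_confidence, filter_document_sources

#: Fields entering the conditions hash, in canonical order.
HASH_FIELDS = [*ASSAY_METADATA_FIELDS, "variant_id"]

_SEP = "\x1f"  # unit separator
_NULL = "␀NULL"  # distinguishable from any real metadata string

_INT_FIELDS = {"assay_tax_id", "variant_id"}


def _canonical_token(field_name: str, value) -> str:
    if pd.isna(value):
        return _NULL
    if field_name in _INT_FIELDS:
        # database loads give ints, text dumps give strings; both must hash
        # identically, so canonicalize to a plain decimal rendering
        return str(int(float(str(value).strip())))
    return str(value)


def conditions_hash(assay) -> str:
    """32-character lowercase hex MD5 of an assay's ten-field metadata tuple.

    ``assay`` is a mapping (e.g. a DataFrame row) exposing the
    :data:`HASH_FIELDS`.  Nulls are encoded with a sentinel token, numeric
    fields are canonicalized to plain decimal strings, and fields are joined
    with the U+001F unit separator, so the digest is stable across source
    kinds and platforms.
    """
    tokens = [_canonical_token(f, assay[f]) for f in HASH_FIELDS]
    payload = _SEP.join(tokens).encode("utf-8")
    return hashlib.md5(payload).hexdigest()


def hash_assays(assays: pd.DataFrame) -> pd.Series:
    """Conditions hash for every row, indexed like ``assays``."""
    return pd.Series(
        [conditions_hash(row) for _, row in assays.iterrows()],
        index=assays.index,
        name="conditions_hash",
    )


@dataclass
class CombinedDataset:
    """One combinable per-target dataset.

    ``key`` is the bare target_id (minimum mode) or
    ``(target_id, conditions_hash)`` (maximal mode).  ``members`` maps
    compound_id → list of (pchembl, assay_key, chembl_assay_id) with one entry
    per member assay measuring the compound; no aggregation to a single value
    is performed.
    """

    key: object
    target_id: str
    members: dict = field(default_factory=dict)
    n_assays: int = 0

    @property
    def n_compounds(self) -> int:
        return len(self.members)


def dedup_document_assays(
    assays: pd.DataFrame, activities: pd.DataFrame
) -> set[int]:
    """One assay per (document, target): keep the assay with the most distinct
    qualifying compounds; ties break to the smaller assay_key.  Assays with a
    null doc_id are never deduplicated against each other."""
    counts = activities.groupby("assay_key")["compound_id"].nunique()
    sized = assays[["assay_key", "doc_id", "target_id"]].copy()
    sized["n"] = [counts.get(k, 0) for k in sized["assay_key"]]
    retained: set[int] = set()
    with_doc = sized.loc[sized["doc_id"].notna()]
    for _, grp in with_doc.groupby(["doc_id", "target_id"]):
        best = grp.sort_values(["n", "assay_key"], ascending=[False, True]).iloc[0]
        retained.add(int(best["assay_key"]))
    retained |= set(sized.loc[sized["doc_id"].isna(), "assay_key"].astype(int))
    return retained


def assemble_datasets(
    assays: pd.DataFrame, activities: pd.DataFrame, mode: str = "maximal"
) -> list[CombinedDataset]:
    """Assemble combined datasets from validity-filtered activities.

    ``mode="minimum"`` groups every assay of a target under the bare
    target_id.  ``mode="maximal"`` first applies the extraction filters —
    document-associated sources only, confidence score 9, mutant-text assays
    removed unless they carry a variant_id, one assay per (document, target) —
    then groups by (target_id, conditions_hash).
    """
    if mode not in {"minimum", "maximal"}:
        raise ValueError(f"mode must be 'minimum' or 'maximal', got {mode!r}")
    work = assays.reset_index(drop=True)
    if mode == "maximal":
        keep = filter_document_sources(work)
        keep &= filter_confidence(work)
        keep -= flag_mutant_assays(work, mode="extraction")
        work = work.loc[work["assay_key"].isin(keep)].reset_index(drop=True)
        keep = dedup_document_assays(work, activities)
        work = work.loc[work["assay_key"].isin(keep)].reset_index(drop=True)
        work["conditions_hash"] = hash_assays(work)
        group_cols = ["target_id", "conditions_hash"]
    else:
        group_cols = ["target_id"]

    meta = work[["assay_key", "chembl_assay_id"] + group_cols]
    acts = activities.merge(meta, on="assay_key", how="inner")

    datasets: list[CombinedDataset] = []
    for key_vals, grp in acts.groupby(group_cols, sort=True):
        if mode == "maximal":
            key = (key_vals[0], key_vals[1])
            target_id = key_vals[0]
        else:
            key = key_vals[0] if not isinstance(key_vals, tuple) else key_vals[0]
            target_id = key
        members: dict = {}
        for row in grp.itertuples(index=False):
            members.setdefault(int(row.compound_id), []).append(
                (float(row.pchembl), int(row.assay_key), str(row.chembl_assay_id))
            )
        datasets.append(
            CombinedDataset(
                key=key,
                target_id=str(target_id),
                members=members,
                n_assays=int(grp["assay_key"].nunique()),
            )
        )
    return datasets


def dataset_size_census(
    datasets: list[CombinedDataset],
    rules: list[tuple[int, int]],
) -> list[int]:
    """Count datasets satisfying each (min_assays, min_compounds) rule.

    A rule like ``(20, 1000)`` counts datasets with at least 20 member assays
    and at least 1000 distinct compounds; ``(1, 500)`` counts datasets of at
    least 500 compounds regardless of assay count.
    """
    out = []
    for min_assays, min_compounds in rules:
        out.append(
            sum(
                1
                for d in datasets
                if d.n_assays >= min_assays and d.n_compounds >= min_compounds
            )
        )
    return out


def export_datasets(datasets: list[CombinedDataset], directory) -> None:
    """One delimited file per dataset plus a manifest.

    Dataset files carry compound_id, pchembl, assay_key, chembl_assay_id; the
    manifest lists key, n_assays, n_compounds.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, d in enumerate(datasets):
        if isinstance(d.key, tuple):
            stem = f"{d.key[0]}_{d.key[1]}"
        else:
            stem = str(d.key)
        rows = [
            (cid, v, ak, caid)
            for cid, entries in sorted(d.members.items())
            for (v, ak, caid) in entries
        ]
        pd.DataFrame(
            rows, columns=["compound_id", "pchembl", "assay_key", "chembl_assay_id"]
        ).to_csv(directory / f"{stem}.txt", sep="\t", index=False)
        manifest.append((stem, d.n_assays, d.n_compounds))
    pd.DataFrame(manifest, columns=["key", "n_assays", "n_compounds"]).to_csv(
        directory / "manifest.txt", sep="\t", index=False
    )
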