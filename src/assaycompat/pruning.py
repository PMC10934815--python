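"""Removal of problematic assay clusters by compound overlap with seeds.

Some assay families report mutually inconsistent values that only reading the
primary literature can diagnose (for the Ki data this was a carbonic anhydrase
cluster seeded on one named assay).  Given a set of seed assays, every assay
sharing more than ``min_shared`` distinct compounds with any seed is removed,
seeds included.  Expansion is strictly one hop unless ``transitive`` is set,
in which case removal propagates through overlap chains.
"""

from __future__ import annotations

import pandas as pd


def compound_sets(activities: pd.DataFrame) -> dict[int, set[int]]:
    """Distinct validity-filtered compounds per assay."""
    return {
        int(k): set(int(c) for c in grp)
        for k, grp in activities.groupby("assay_key")["compound_id"]
    }


def resolve_seed_ids(assays: pd.DataFrame, chembl_ids: list[str]) -> set[int]:
    """Map seed "CHEMBL…" accession strings to assay keys."""
    lut = assays.set_index("chembl_assay_id")["assay_key"]
    missing = [c for c in chembl_ids if c not in lut.index]
    if missing:
        raise KeyError(f"seed assay id(s) not found: {missing}")
    return {int(lut[c]) for c in chembl_ids}


def expand_problem_assays(
    seed_keys: set[int],
    values: dict[int, set[int]],
    min_shared: int = 10,
    transitive: bool = False,
) -> set[int]:
    """Assay keys to remove given seed assays and per-assay compound sets.

    An assay is removed when its distinct-compound overlap with any seed
    strictly exceeds ``min_shared`` (an overlap of exactly ``min_shared``
    survives).  Seeds are always removed.  With ``transitive=True`` the rule
    is re-applied with removed assays acting as new seeds until closure.
    """
    if not seed_keys:
        raise ValueError("seed_keys must be non-empty")
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    unknown = set(seed_keys) - set(values)
    if unknown:
        raise KeyError(f"seed assay key(s) without activity data: {sorted(unknown)}")

    removed = set(int(k) for k in seed_keys)
    frontier = set(removed)
    while frontier:
        new = set()
        for key, compounds in values.items():
            if key in removed:
                continue
            if any(len(compounds & values[s]) > min_shared for s in frontier):
                new.add(key)
        removed |= new
        frontier = new if transitive else set()
    return removed


def removal_table(
    removed: set[int],
    seed_keys: set[int],
    values: dict[int, set[int]],
    assays: pd.DataFrame,
) -> pd.DataFrame:
    """Exportable list of removed assays with their maximum seed overlap."""
    lut = assays.set_index("assay_key")["chembl_assay_id"]
    rows = []
    for key in sorted(removed):
        overlap = max(
            (len(values.get(key, set()) & values[s]) for s in seed_keys),
            default=0,
        )
        rows.append((key, str(lut.get(key, "")), overlap))
    return pd.DataFrame(
        rows, columns=["assay_key", "chembl_assay_id", "max_overlap_with_seed"]
    )
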