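"""Curation filters for measurement pairs and the two named presets.

Each filter is independent and switchable.  Assay-level filters (mutants,
document sources, assay size, confidence) produce retained-key sets and drop
every pair touching a removed assay; pair-level filters (activity duplicates,
same document, assay type, metadata match) act on the pair table directly.
:func:`apply_curation` composes the enabled steps and returns a per-step
removal ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from assaycompat.chembl_io import ASSAY_METADATA_FIELDS

MUTANT_KEYWORDS = ("mutant", "mutation", "variant")

#: Order in which apply_curation runs its steps (assay-level first).
STEP_ORDER = [
    "mutants",
    "document_source",
    "assay_size",
    "confidence",
    "same_document",
    "assay_type",
    "metadata_match",
    "activity_dups",
]


@dataclass(frozen=True)
class CurationConfig:
    """Switches for each curation step.

    ``delta_tolerance`` absorbs the two-decimal rounding of stored pchembl
    values when testing the exact-copy and 3-log-unit unit-error rules.
    ``max_assay_size`` is the largest number of distinct compounds an assay
    may hold before it is treated as a review/aggregate source (100 default;
    1000 for the "large" variant).
    """

    drop_exact_and_unit_dups: bool = False
    drop_same_document: bool = False
    drop_mutants: bool = False
    require_same_assay_type: bool = False
    require_metadata_match: bool = False
    require_document_source: bool = False
    max_assay_size: int = 100
    enforce_assay_size: bool = False
    require_confidence_9: bool = False
    delta_tolerance: float = 0.005

    def __post_init__(self):
        if self.max_assay_size < 1:
            raise ValueError("max_assay_size must be >= 1")
        if self.delta_tolerance < 0:
            raise ValueError("delta_tolerance must be >= 0")


def only_activity_preset(**overrides) -> CurationConfig:
    """Only the duplicate-activity rule (verbatim copies and unit errors)."""
    return replace(CurationConfig(drop_exact_and_unit_dups=True), **overrides)


def maximal_preset(**overrides) -> CurationConfig:
    """Every curation step enabled."""
    return replace(
        CurationConfig(
            drop_exact_and_unit_dups=True,
            drop_same_document=True,
            drop_mutants=True,
            require_same_assay_type=True,
            require_metadata_match=True,
            require_document_source=True,
            enforce_assay_size=True,
            require_confidence_9=True,
        ),
        **overrides,
    )


PRESETS = {"only-activity": only_activity_preset, "maximal": maximal_preset}


# ---------------------------------------------------------------------------
# pair-level filters
# ---------------------------------------------------------------------------

def filter_activity_pairs(pairs: pd.DataFrame, tol: float = 0.005) -> pd.DataFrame:
    """Drop likely copied values: |Δ| ≈ 0 (verbatim copy) or |Δ| ≈ 3 (copy
    with a unit error in either publication).  ``tol`` is the half-width of
    each window in log units."""
    if pairs.empty:
        return pairs.copy()
    absd = pairs["delta"].abs()
    copied = (absd <= tol) | ((absd - 3.0).abs() <= tol)
    return pairs.loc[~copied].reset_index(drop=True)


def _pair_assay_field(pairs: pd.DataFrame, assays: pd.DataFrame, field: str):
    lut = assays.set_index("assay_key")[field]
    return lut.reindex(pairs["assay_hi"]).to_numpy(), lut.reindex(
        pairs["assay_lo"]
    ).to_numpy()


def filter_same_document(pairs: pd.DataFrame, assays: pd.DataFrame) -> pd.DataFrame:
    """Drop pairs whose two assays were published in the same document.

    A null doc_id never matches anything, including another null."""
    if pairs.empty:
        return pairs.copy()
    hi, lo = _pair_assay_field(pairs, assays, "doc_id")
    same = np.array(
        [pd.notna(a) and pd.notna(b) and a == b for a, b in zip(hi, lo)]
    )
    return pairs.loc[~same].reset_index(drop=True)


def filter_assay_type(pairs: pd.DataFrame, assays: pd.DataFrame) -> pd.DataFrame:
    """Keep pairs whose assays share the same assay type (B, F, ...); a null
    type never equals anything."""
    if pairs.empty:
        return pairs.copy()
    hi, lo = _pair_assay_field(pairs, assays, "assay_type")
    same = np.array(
        [pd.notna(a) and pd.notna(b) and a == b for a, b in zip(hi, lo)]
    )
    return pairs.loc[same].reset_index(drop=True)


def filter_metadata_match(pairs: pd.DataFrame, assays: pd.DataFrame) -> pd.DataFrame:
    """Keep pairs where all nine assay metadata fields agree pairwise.

    Unlike :func:`filter_assay_type`, here null == null counts as a match:
    most ChEMBL metadata fields are sparsely populated, and two assays that
    both leave a field blank are indistinguishable on that field.
    """
    if pairs.empty:
        return pairs.copy()
    keep = np.ones(len(pairs), dtype=bool)
    for field in ASSAY_METADATA_FIELDS:
        hi, lo = _pair_assay_field(pairs, assays, field)
        match = np.array(
            [
                (pd.isna(a) and pd.isna(b)) or (pd.notna(a) and pd.notna(b) and a == b)
                for a, b in zip(hi, lo)
            ]
        )
        keep &= match
    return pairs.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# assay-level filters: return the set of retained (or flagged) assay keys
# ---------------------------------------------------------------------------

def flag_mutant_assays(
    assays: pd.DataFrame, mode: str = "pair-analysis"
) -> set[int]:
    """Assay keys flagged as protein-variant ("mutant") assays.

    ``mode="pair-analysis"``: flagged when the description contains any of
    "mutant"/"mutation"/"variant" (case-insensitive substring) OR variant_id
    is set — the conservative rule used when measuring pair noise.

    ``mode="extraction"``: flagged only when the description text matches AND
    variant_id is null — assays with an explicit variant_id are identifiable
    variants and stay usable for dataset assembly (the variant_id takes part
    in the conditions hash).
    """
    if mode not in {"pair-analysis", "extraction"}:
        raise ValueError(f"unknown mutant-flag mode {mode!r}")
    desc = assays["description"].fillna("").str.lower()
    text_hit = np.zeros(len(assays), dtype=bool)
    for kw in MUTANT_KEYWORDS:
        text_hit |= desc.str.contains(kw, regex=False).to_numpy()
    has_variant = assays["variant_id"].notna().to_numpy()
    if mode == "pair-analysis":
        flagged = text_hit | has_variant
    else:
        flagged = text_hit & ~has_variant
    return set(assays.loc[flagged, "assay_key"].tolist())


def filter_document_sources(assays: pd.DataFrame) -> set[int]:
    """Retain assays whose source carries an associated document date —
    keeping the dated medicinal-chemistry literature and patents, excluding
    screening depositions."""
    keep = assays["source_has_doc_date"].astype(bool)
    return set(assays.loc[keep, "assay_key"].tolist())


def filter_assay_size(
    assays: pd.DataFrame, activities: pd.DataFrame, max_n: int = 100
) -> set[int]:
    """Retain assays with at most ``max_n`` distinct measured compounds;
    larger assays are typically review articles or aggregated depositions."""
    counts = activities.groupby("assay_key")["compound_id"].nunique()
    keep = []
    for key in assays["assay_key"]:
        if counts.get(key, 0) <= max_n:
            keep.append(int(key))
    return set(keep)


def filter_confidence(assays: pd.DataFrame) -> set[int]:
    """Retain assays with target-assignment confidence score exactly 9
    (direct single protein target)."""
    keep = assays["confidence_score"] == 9
    return set(assays.loc[keep.fillna(False), "assay_key"].tolist())


def _drop_pairs_touching(pairs: pd.DataFrame, removed: set[int]) -> pd.DataFrame:
    if pairs.empty or not removed:
        return pairs.reset_index(drop=True)
    mask = pairs["assay_hi"].isin(removed) | pairs["assay_lo"].isin(removed)
    return pairs.loc[~mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def apply_curation(
    pairs: pd.DataFrame,
    assays: pd.DataFrame,
    activities: pd.DataFrame,
    config: CurationConfig,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run every enabled curation step and return (surviving pairs, ledger).

    The ledger maps step name → number of pairs that step removed when applied
    in :data:`STEP_ORDER`; ledger counts sum to ``len(pairs) - len(result)``.
    Assay-level steps run first, so a pair touching a removed assay is charged
    to the assay-level step, not to any later pair rule.
    """
    ledger: dict[str, int] = {}
    current = pairs.reset_index(drop=True)

    def _charge(step: str, after: pd.DataFrame):
        nonlocal current
        ledger[step] = len(current) - len(after)
        current = after

    for step in STEP_ORDER:
        if step == "mutants" and config.drop_mutants:
            flagged = flag_mutant_assays(assays, mode="pair-analysis")
            _charge(step, _drop_pairs_touching(current, flagged))
        elif step == "document_source" and config.require_document_source:
            retained = filter_document_sources(assays)
            removed = set(assays["assay_key"].tolist()) - retained
            _charge(step, _drop_pairs_touching(current, removed))
        elif step == "assay_size" and config.enforce_assay_size:
            retained = filter_assay_size(assays, activities, config.max_assay_size)
            removed = set(assays["assay_key"].tolist()) - retained
            _charge(step, _drop_pairs_touching(current, removed))
        elif step == "confidence" and config.require_confidence_9:
            retained = filter_confidence(assays)
            removed = set(assays["assay_key"].tolist()) - retained
            _charge(step, _drop_pairs_touching(current, removed))
        elif step == "same_document" and config.drop_same_document:
            _charge(step, filter_same_document(current, assays))
        elif step == "assay_type" and config.require_same_assay_type:
            _charge(step, filter_assay_type(current, assays))
        elif step == "metadata_match" and config.require_metadata_match:
            _charge(step, filter_metadata_match(current, assays))
        elif step == "activity_dups" and config.drop_exact_and_unit_dups:
            _charge(step, filter_activity_pairs(current, config.delta_tolerance))
    return current.reset_index(drop=True), ledger
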