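import itertools

import numpy as np
import pandas as pd
import pytest

from assaycompat import curation as cur
from assaycompat.chembl_io import ASSAY_METADATA_FIELDS
from assaycompat.overlap import PAIR_COLUMNS

from conftest import make_activities, make_assays


def make_pairs(rows):
    """(compound, assay_lo, assay_hi, value_lo, value_hi) -> pair frame."""
    recs = [
        {
            "target_id": "T001",
            "compound_id": c,
            "assay_hi": hi,
            "assay_lo": lo,
            "value_hi": vh,
            "value_lo": vl,
            "delta": vh - vl,
        }
        for c, lo, hi, vl, vh in rows
    ]
    return pd.DataFrame(recs, columns=PAIR_COLUMNS)


@pytest.mark.parametrize(
    "vl,vh,removed",
    [
        (5.00, 5.00, True),  # verbatim copy
        (4.25, 7.25, True),  # unit error: +3
        (7.25, 4.25, True),  # unit error: -3
        (5.90, 6.10, False),  # ordinary disagreement
        (5.00, 5.004, True),  # inside the rounding tolerance
        (5.00, 5.02, False),  # outside it
    ],
)
def test_activity_pair_rule(vl, vh, removed):
    pairs = make_pairs([(1, 1, 2, vl, vh)])
    out = cur.filter_activity_pairs(pairs, tol=0.005)
    assert out.empty is removed


@pytest.mark.parametrize(
    "description,variant_id,flagged",
    [
        ("Inhibition of T315I mutant kinase", pd.NA, True),
        ("Point mutation study", pd.NA, True),
        ("Splice variant assay", pd.NA, True),
        ("MUTANT enzyme", pd.NA, True),  # case-insensitive
        ("wild type enzyme", 42, True),  # variant_id alone
        ("wild type enzyme", pd.NA, False),
    ],
)
def test_mutant_flagging_pair_analysis(description, variant_id, flagged):
    assays = make_assays([{"assay_key": 1, "description": description, "variant_id": variant_id}])
    assert (1 in cur.flag_mutant_assays(assays)) is flagged


def test_mutant_flagging_extraction_mode_spares_variant_id():
    assays = make_assays(
        [
            {"assay_key": 1, "description": "mutant enzyme", "variant_id": pd.NA},
            {"assay_key": 2, "description": "mutant enzyme", "variant_id": 7},
            {"assay_key": 3, "description": "clean", "variant_id": 7},
        ]
    )
    assert cur.flag_mutant_assays(assays, mode="extraction") == {1}


@pytest.mark.parametrize(
    "doc_lo,doc_hi,removed",
    [(7, 7, True), (7, 8, False), (pd.NA, pd.NA, False), (pd.NA, 7, False)],
)
def test_same_document_rule(doc_lo, doc_hi, removed):
    assays = make_assays(
        [{"assay_key": 1, "doc_id": doc_lo}, {"assay_key": 2, "doc_id": doc_hi}]
    )
    out = cur.filter_same_document(make_pairs([(1, 1, 2, 5.0, 6.0)]), assays)
    assert out.empty is removed


@pytest.mark.parametrize(
    "t_lo,t_hi,kept", [("B", "B", True), ("B", "F", False), ("B", pd.NA, False)]
)
def test_assay_type_rule(t_lo, t_hi, kept):
    assays = make_assays(
        [{"assay_key": 1, "assay_type": t_lo}, {"assay_key": 2, "assay_type": t_hi}]
    )
    out = cur.filter_assay_type(make_pairs([(1, 1, 2, 5.0, 6.0)]), assays)
    assert (not out.empty) is kept


def test_metadata_match_null_semantics():
    # identical including shared nulls -> kept
    assays = make_assays([{"assay_key": 1}, {"assay_key": 2}])
    assert len(cur.filter_metadata_match(make_pairs([(1, 1, 2, 5.0, 6.0)]), assays)) == 1
    # one differing field -> removed
    assays = make_assays(
        [
            {"assay_key": 1, "assay_cell_type": "CHO"},
            {"assay_key": 2, "assay_cell_type": "HEK293"},
        ]
    )
    assert cur.filter_metadata_match(make_pairs([(1, 1, 2, 5.0, 6.0)]), assays).empty
    # null vs value is a mismatch
    assays = make_assays(
        [
            {"assay_key": 1, "assay_organism": "Homo sapiens"},
            {"assay_key": 2, "assay_organism": pd.NA},
        ]
    )
    assert cur.filter_metadata_match(make_pairs([(1, 1, 2, 5.0, 6.0)]), assays).empty


def test_document_source_rule():
    assays = make_assays(
        [
            {"assay_key": 1, "source_has_doc_date": True},
            {"assay_key": 2, "source_has_doc_date": False},
        ]
    )
    assert cur.filter_document_sources(assays) == {1}
    assert cur.filter_document_sources(assays.iloc[0:0]) == set()


@pytest.mark.parametrize(
    "n_compounds,max_n,kept", [(100, 100, True), (101, 100, False), (740, 1000, True)]
)
def test_assay_size_rule(n_compounds, max_n, kept):
    assays = make_assays([{"assay_key": 1}])
    acts = make_activities(
        [
            (i + 1, 1, i + 1, 6.0, "IC50", "=", "nM", pd.NA)
            for i in range(n_compounds)
        ]
    )
    assert (1 in cur.filter_assay_size(assays, acts, max_n)) is kept


@pytest.mark.parametrize("score,kept", [(9, True), (8, False), (pd.NA, False)])
def test_confidence_rule(score, kept):
    assays = make_assays([{"assay_key": 1, "confidence_score": score}])
    assert (1 in cur.filter_confidence(assays)) is kept


def test_presets():
    oa = cur.only_activity_preset()
    assert oa.drop_exact_and_unit_dups and not oa.drop_mutants
    mx = cur.maximal_preset(max_assay_size=1000)
    assert all(
        [
            mx.drop_exact_and_unit_dups,
            mx.drop_same_document,
            mx.drop_mutants,
            mx.require_same_assay_type,
            mx.require_metadata_match,
            mx.require_document_source,
            mx.enforce_assay_size,
            mx.require_confidence_9,
        ]
    )
    assert mx.max_assay_size == 1000


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        cur.CurationConfig(max_assay_size=0)
    with pytest.raises(ValueError):
        cur.CurationConfig(delta_tolerance=-0.1)


def _mini_scene():
    """3 assays, one mutant, with pairs; used by composition tests."""
    assays = make_assays(
        [
            {"assay_key": 1, "doc_id": 100},
            {"assay_key": 2, "doc_id": 101},
            {"assay_key": 3, "doc_id": 102, "description": "mutant enzyme"},
        ]
    )
    pairs = make_pairs(
        [
            (1, 1, 2, 5.0, 5.0),  # verbatim copy
            (2, 1, 2, 5.5, 6.1),
            (3, 1, 3, 6.0, 6.9),
            (4, 2, 3, 6.2, 7.4),
            (5, 1, 3, 5.1, 5.6),
        ]
    )
    acts = make_activities(
        [
            (i + 1, k, c, 6.0, "IC50", "=", "nM", pd.NA)
            for i, (k, c) in enumerate(
                [(1, 1), (1, 2), (1, 3), (1, 5), (2, 1), (2, 2), (2, 4), (3, 3), (3, 4), (3, 5)]
            )
        ]
    )
    return pairs, assays, acts


def test_apply_curation_identity_when_disabled():
    pairs, assays, acts = _mini_scene()
    out, ledger = cur.apply_curation(pairs, assays, acts, cur.CurationConfig())
    pd.testing.assert_frame_equal(out, pairs)
    assert ledger == {}


def test_apply_curation_single_filter_composition():
    pairs, assays, acts = _mini_scene()
    out, ledger = cur.apply_curation(pairs, assays, acts, cur.only_activity_preset())
    assert ledger == {"activity_dups": 1}
    assert len(out) == 4 and not ((out["delta"].abs() <= 0.005).any())


def test_apply_curation_mutant_removes_touching_pairs():
    pairs, assays, acts = _mini_scene()
    config = cur.CurationConfig(drop_mutants=True)
    out, ledger = cur.apply_curation(pairs, assays, acts, config)
    assert ledger == {"mutants": 3}
    assert not (out["assay_hi"].eq(3) | out["assay_lo"].eq(3)).any()


def test_ledger_counts_sum_to_removed_total(pathology_fixture):
    from assaycompat.chembl_io import filter_valid_activities
    from assaycompat.overlap import aggregate_within_assay, find_measurement_pairs

    _, tables, _ = pathology_fixture
    acts = filter_valid_activities(tables["activities"])
    pairs = find_measurement_pairs(aggregate_within_assay(acts), tables["assays"])
    out, ledger = cur.apply_curation(pairs, tables["assays"], acts, cur.maximal_preset())
    assert sum(ledger.values()) == len(pairs) - len(out)


def test_filters_idempotent_and_monotone(pathology_fixture):
    from assaycompat.chembl_io import filter_valid_activities
    from assaycompat.overlap import aggregate_within_assay, find_measurement_pairs

    _, tables, _ = pathology_fixture
    acts = filter_valid_activities(tables["activities"])
    assays = tables["assays"]
    pairs = find_measurement_pairs(aggregate_within_assay(acts), assays)

    once = cur.filter_activity_pairs(pairs)
    pd.testing.assert_frame_equal(once, cur.filter_activity_pairs(once))
    once = cur.filter_metadata_match(pairs, assays)
    pd.testing.assert_frame_equal(once, cur.filter_metadata_match(once, assays))

    # enabling one more filter never increases the survivor count
    base = cur.CurationConfig(drop_exact_and_unit_dups=True)
    n_base = len(cur.apply_curation(pairs, assays, acts, base)[0])
    for extra in [
        {"drop_mutants": True},
        {"drop_same_document": True},
        {"require_metadata_match": True},
        {"require_confidence_9": True},
        {"enforce_assay_size": True},
    ]:
        grown = cur.CurationConfig(drop_exact_and_unit_dups=True, **extra)
        assert len(cur.apply_curation(pairs, assays, acts, grown)[0]) <= n_base


def test_assay_level_filter_order_irrelevant(pathology_fixture):
    """Survivor sets agree for every ordering of the assay-level removals."""
    from assaycompat.chembl_io import filter_valid_activities
    from assaycompat.overlap import aggregate_within_assay, find_measurement_pairs

    _, tables, _ = pathology_fixture
    acts = filter_valid_activities(tables["activities"])
    assays = tables["assays"]
    pairs = find_measurement_pairs(aggregate_within_assay(acts), assays)

    removers = {
        "mutants": lambda: cur.flag_mutant_assays(assays),
        "size": lambda: set(assays["assay_key"]) - cur.filter_assay_size(assays, acts, 100),
        "confidence": lambda: set(assays["assay_key"]) - cur.filter_confidence(assays),
    }
    reference = None
    for order in itertools.permutations(removers):
        removed = set()
        for name in order:
            removed |= removers[name]()
        survivors = pairs.loc[
            ~(pairs["assay_hi"].isin(removed) | pairs["assay_lo"].isin(removed))
        ]
        key = set(map(tuple, survivors[["compound_id", "assay_lo", "assay_hi"]].values))
        if reference is None:
            reference = key
        assert key == reference
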