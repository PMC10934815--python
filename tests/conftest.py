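import numpy as np
import pandas as pd
import pytest

from assaycompat.synthetic_data import GeneratorConfig, generate_fixture


def make_activities(rows):
    """Build a typed activities table from (activity_id, assay_key,
    compound_id, pchembl, type, relation, units, validity) tuples."""
    df = pd.DataFrame(
        rows,
        columns=[
            "activity_id",
            "assay_key",
            "compound_id",
            "pchembl",
            "standard_type",
            "standard_relation",
            "standard_units",
            "data_validity_comment",
        ],
    )
    for c in ["standard_type", "standard_relation", "standard_units", "data_validity_comment"]:
        df[c] = df[c].astype("string")
    return df


def make_assays(rows, **common):
    """Build a typed assays table from dicts; unspecified metadata is null."""
    defaults = {
        "doc_id": pd.NA,
        "description": "inhibition assay",
        "assay_type": "B",
        "assay_organism": pd.NA,
        "assay_category": pd.NA,
        "assay_tax_id": pd.NA,
        "assay_strain": pd.NA,
        "assay_tissue": pd.NA,
        "assay_cell_type": pd.NA,
        "assay_subcellular_fraction": pd.NA,
        "bao_format": pd.NA,
        "variant_id": pd.NA,
        "confidence_score": 9,
        "source_has_doc_date": True,
    }
    defaults.update(common)
    records = []
    for row in rows:
        rec = dict(defaults)
        rec.update(row)
        rec.setdefault("chembl_assay_id", f"CHEMBL{9000000 + rec['assay_key']}")
        rec.setdefault("target_id", "T001")
        records.append(rec)
    df = pd.DataFrame(records)
    for c in ["doc_id", "assay_tax_id", "variant_id", "confidence_score"]:
        df[c] = df[c].astype("Int64")
    for c in [
        "chembl_assay_id",
        "target_id",
        "description",
        "assay_type",
        "assay_organism",
        "assay_category",
        "assay_strain",
        "assay_tissue",
        "assay_cell_type",
        "assay_subcellular_fraction",
        "bao_format",
    ]:
        df[c] = df[c].astype("string")
    return df


@pytest.fixture
def pathology_fixture():
    """Small seeded fixture with one of each plantable pathology."""
    cfg = GeneratorConfig(
        seed=7,
        n_targets=2,
        assays_per_target=6,
        compounds_per_assay=20,
        n_copied_values=3,
        n_unit_errors=2,
        n_mutant_assays=2,
        n_mega_assays=1,
        n_low_confidence_assays=1,
        incompatible_cluster_size=3,
    )
    tables, truth = generate_fixture(cfg)
    return cfg, tables, truth


@pytest.fixture
def clean_fixture():
    cfg = GeneratorConfig(
        seed=5,
        n_targets=1,
        assays_per_target=6,
        compounds_per_assay=40,
        assay_bias_sd=0.1,
        noise_sd=0.3,
    )
    tables, truth = generate_fixture(cfg)
    return cfg, tables, truth
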