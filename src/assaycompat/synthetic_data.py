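"""Miniature ChEMBL-like fixtures with known ground truth.

The generator emulates the joined activity/assay/document structure used by
the pipeline.  Each clean measurement is

    pchembl = true_affinity(compound) + bias(assay) + Normal(0, noise_sd²)

rounded to two decimals (matching database storage).  Per-assay biases model
systematic lab/protocol offsets; the compound affinity spread sets how much
ranking signal the data carry.  On top of the clean signal the generator
plants the pathologies the curation filters target, each attributable to
exactly one filter:

* verbatim copied values across assay pairs (Δpchembl exactly 0);
* copies shifted by exactly ±3 log units (unit errors);
* protein-variant ("mutant") assays, flagged either by description text or by
  an explicit variant_id, measuring a shifted protein;
* oversized review-style assays exceeding the size cap, with inflated noise;
* sub-confidence assays (confidence score < 9) with a target-assignment shift;
* a cluster of mutually inconsistent assays sharing more than ``min_shared``
  compounds with a designated seed assay, plus one boundary assay sharing
  exactly the threshold number of compounds (which pruning must keep).

By default pathologies are planted disjointly and accidental Δ ∈ {0, ±3}
coincidences among non-planted pairs are nudged away (by one or two
hundredths of a log unit), so each filter's removals equal its planted set
exactly.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from assaycompat import chembl_io


class ConfigError(ValueError):
    """The generator configuration is internally inconsistent."""


@dataclass
class GeneratorConfig:
    """Knobs of the fixture generator.

    Rates translate to counts (assay rates scale the total assay number,
    value rates the total measurement number); the explicit ``n_*`` overrides
    pin exact counts when a test needs them.  All log-unit quantities are in
    pchembl units.
    """

    n_targets: int = 2
    assays_per_target: int = 8
    compounds_per_assay: int = 25
    overlap_fraction: float = 1.0

    affinity_mean: float = 7.0
    affinity_spread: float = 1.0
    assay_bias_sd: float = 0.1
    noise_sd: float = 0.3

    copied_value_rate: float = 0.0
    unit_error_rate: float = 0.0
    mutant_assay_rate: float = 0.0
    mega_assay_rate: float = 0.0
    low_confidence_rate: float = 0.0
    incompatible_cluster_size: int = 0

    n_copied_values: int | None = None
    n_unit_errors: int | None = None
    n_mutant_assays: int | None = None
    n_mega_assays: int | None = None
    n_low_confidence_assays: int | None = None

    mega_assay_size: int = 120
    mega_extra_noise_sd: float = 0.5
    cluster_shared_compounds: int = 15
    cluster_boundary_overlap: int = 10
    plant_cluster_boundary: bool = True

    readout: str = "IC50"
    disjoint_pathologies: bool = True
    duplicate_tolerance: float = 0.005
    seed: int = 0

    def __post_init__(self):
        for name in (
            "copied_value_rate",
            "unit_error_rate",
            "mutant_assay_rate",
            "mega_assay_rate",
            "low_confidence_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("affinity_spread", "assay_bias_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_targets < 1 or self.assays_per_target < 1:
            raise ConfigError("need at least one target and one assay per target")
        if self.compounds_per_assay < 1:
            raise ConfigError("compounds_per_assay must be >= 1")
        if not 0.0 < self.overlap_fraction <= 1.0:
            raise ConfigError("overlap_fraction must be in (0, 1]")
        if self.incompatible_cluster_size:
            if self.cluster_shared_compounds <= self.cluster_boundary_overlap:
                raise ConfigError(
                    "cluster_shared_compounds must exceed cluster_boundary_overlap"
                )


@dataclass
class SyntheticGroundTruth:
    """Generator-side labels for everything the fixture contains."""

    true_affinity: dict[int, float] = field(default_factory=dict)
    assay_bias: dict[int, float] = field(default_factory=dict)
    #: kind -> identifiers; pair pathologies are (target_id, compound_id,
    #: assay_lo, assay_hi) tuples, assay pathologies are assay_key lists.
    planted: dict[str, list] = field(default_factory=dict)


def _pool_size(cfg: GeneratorConfig) -> int:
    return max(
        cfg.compounds_per_assay,
        int(math.ceil(cfg.compounds_per_assay / cfg.overlap_fraction)),
    )


def _derived_counts(cfg: GeneratorConfig, n_assays: int, n_measurements: int):
    def pick(explicit, rate, base):
        if explicit is not None:
            return int(explicit)
        return int(round(rate * base))

    return {
        "copied": pick(cfg.n_copied_values, cfg.copied_value_rate, n_measurements),
        "unit_error": pick(cfg.n_unit_errors, cfg.unit_error_rate, n_measurements),
        "mutant": pick(cfg.n_mutant_assays, cfg.mutant_assay_rate, n_assays),
        "mega": pick(cfg.n_mega_assays, cfg.mega_assay_rate, n_assays),
        "low_confidence": pick(
            cfg.n_low_confidence_assays, cfg.low_confidence_rate, n_assays
        ),
    }


def _round2(x: float) -> float:
    return float(np.round(x, 2))


def generate_fixture(
    cfg: GeneratorConfig,
) -> tuple[dict[str, pd.DataFrame], SyntheticGroundTruth]:
    """Generate the activities/assays/docs tables and their ground truth.

    Returns typed DataFrames in the layout :mod:`assaycompat.chembl_io`
    produces, plus a :class:`SyntheticGroundTruth`.  Use
    :func:`write_fixture` to materialize the flat-file dump dialect.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = SyntheticGroundTruth(
        planted={
            "copied": [],
            "unit_error": [],
            "mutant": [],
            "mega": [],
            "low_confidence": [],
            "cluster": [],
            "cluster_seed": [],
            "cluster_boundary": [],
        }
    )

    next_compound = 1
    next_assay = 1
    pool_size = _pool_size(cfg)
    targets = [f"T{i:03d}" for i in range(1, cfg.n_targets + 1)]

    pools: dict[str, np.ndarray] = {}
    for t in targets:
        ids = np.arange(next_compound, next_compound + pool_size)
        next_compound += pool_size
        pools[t] = ids
        for cid in ids:
            truth.true_affinity[int(cid)] = float(
                rng.normal(cfg.affinity_mean, cfg.affinity_spread)
            )

    # assay bookkeeping: key -> (target, compound array); separate metadata
    assay_target: dict[int, str] = {}
    assay_compounds: dict[int, np.ndarray] = {}
    assay_extra_noise: dict[int, float] = {}
    regular_keys: list[int] = []

    for t in targets:
        for _ in range(cfg.assays_per_target):
            key = next_assay
            next_assay += 1
            assay_target[key] = t
            assay_compounds[key] = rng.choice(
                pools[t], size=cfg.compounds_per_assay, replace=False
            )
            truth.assay_bias[key] = float(rng.normal(0.0, cfg.assay_bias_sd))
            assay_extra_noise[key] = 0.0
            regular_keys.append(key)

    n_reg = len(regular_keys)
    counts = _derived_counts(
        cfg, n_reg, n_reg * cfg.compounds_per_assay
    )

    # --- assay-level pathologies among the regular assays -------------------
    available = list(regular_keys)
    rng.shuffle(available)

    def take(n: int) -> list[int]:
        if n > len(available):
            raise ConfigError(
                "not enough assays to plant pathologies disjointly; "
                "increase n_targets or assays_per_target"
            )
        picked = [available.pop() for _ in range(n)]
        return sorted(picked)

    mutant_keys = take(counts["mutant"])
    lowconf_keys = take(counts["low_confidence"])
    for i, key in enumerate(mutant_keys):
        # a variant protein genuinely differs: shift the whole assay
        shift = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.8, 2.0))
        truth.assay_bias[key] += shift
        truth.planted["mutant"].append(key)
    for key in lowconf_keys:
        # indirect target assignment: systematic offset
        shift = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5))
        truth.assay_bias[key] += shift
        truth.planted["low_confidence"].append(key)

    # --- oversized review-style assays (extra assays) ------------------------
    mega_keys: list[int] = []
    for _ in range(counts["mega"]):
        key = next_assay
        next_assay += 1
        t = targets[int(rng.integers(len(targets)))]
        base = pools[t]
        n_fill = max(0, cfg.mega_assay_size - len(base))
        fill = np.arange(next_compound, next_compound + n_fill)
        next_compound += n_fill
        for cid in fill:
            truth.true_affinity[int(cid)] = float(
                rng.normal(cfg.affinity_mean, cfg.affinity_spread)
            )
        assay_target[key] = t
        assay_compounds[key] = np.concatenate([base, fill])[: max(cfg.mega_assay_size, len(base))]
        truth.assay_bias[key] = float(rng.normal(0.0, cfg.assay_bias_sd))
        assay_extra_noise[key] = cfg.mega_extra_noise_sd
        mega_keys.append(key)
        truth.planted["mega"].append(key)

    # --- incompatible cluster on the first target ----------------------------
    cluster_keys: list[int] = []
    boundary_key: int | None = None
    if cfg.incompatible_cluster_size > 0:
        t = targets[0]
        shared = np.arange(next_compound, next_compound + cfg.cluster_shared_compounds)
        next_compound += cfg.cluster_shared_compounds
        for cid in shared:
            truth.true_affinity[int(cid)] = float(
                rng.normal(cfg.affinity_mean, cfg.affinity_spread)
            )
        for i in range(cfg.incompatible_cluster_size):
            key = next_assay
            next_assay += 1
            assay_target[key] = t
            assay_compounds[key] = shared.copy()
            # mutually inconsistent: each member has its own large offset
            truth.assay_bias[key] = float(
                rng.choice([-1.0, 1.0]) * rng.uniform(1.0, 2.5)
            )
            assay_extra_noise[key] = 0.0
            cluster_keys.append(key)
            truth.planted["cluster"].append(key)
        truth.planted["cluster_seed"].append(cluster_keys[0])
        if cfg.plant_cluster_boundary:
            key = next_assay
            next_assay += 1
            n_fresh = max(1, cfg.compounds_per_assay - cfg.cluster_boundary_overlap)
            fresh = np.arange(next_compound, next_compound + n_fresh)
            next_compound += n_fresh
            for cid in fresh:
                truth.true_affinity[int(cid)] = float(
                    rng.normal(cfg.affinity_mean, cfg.affinity_spread)
                )
            assay_target[key] = t
            assay_compounds[key] = np.concatenate(
                [shared[: cfg.cluster_boundary_overlap], fresh]
            )
            truth.assay_bias[key] = float(rng.normal(0.0, cfg.assay_bias_sd))
            assay_extra_noise[key] = 0.0
            boundary_key = key
            truth.planted["cluster_boundary"].append(key)

    # --- draw measurements ----------------------------------------------------
    values: dict[tuple[int, int], float] = {}
    for key in sorted(assay_target):
        bias = truth.assay_bias[key]
        extra = assay_extra_noise[key]
        sd = math.sqrt(cfg.noise_sd**2 + extra**2)
        noise = rng.normal(0.0, sd, size=len(assay_compounds[key]))
        for cid, eps in zip(assay_compounds[key], noise):
            v = truth.true_affinity[int(cid)] + bias + float(eps)
            values[(key, int(cid))] = _round2(min(max(v, 0.05), 13.95))

    # --- value-level pathologies (copies and unit errors) ---------------------
    clean_set = set(regular_keys) - set(mutant_keys) - set(lowconf_keys)
    planted_slots: set[tuple[int, int]] = set()
    planted_pairs: set[tuple[int, int, int]] = set()  # (compound, lo, hi)
    used_compounds: set[int] = set()

    def plant_pairs(n: int, kind: str):
        if n == 0:
            return
        # candidate: two clean assays of one target sharing a compound,
        # compound not yet used for any planted pair
        candidates = []
        by_target: dict[str, list[int]] = {}
        for key in sorted(clean_set):
            by_target.setdefault(assay_target[key], []).append(key)
        for t, keys in sorted(by_target.items()):
            for i, a in enumerate(keys):
                for b in keys[i + 1:]:
                    shared = set(map(int, assay_compounds[a])) & set(
                        map(int, assay_compounds[b])
                    )
                    for cid in sorted(shared):
                        candidates.append((t, cid, a, b))
        rng.shuffle(candidates)
        planted = 0
        for t, cid, lo, hi in candidates:
            if planted >= n:
                break
            if cid in used_compounds:
                continue
            if (lo, cid) in planted_slots or (hi, cid) in planted_slots:
                continue
            src = values[(lo, cid)]
            if kind == "copied":
                values[(hi, cid)] = src
            else:
                shift = float(rng.choice([-3.0, 3.0]))
                if not 0.0 <= src + shift <= 14.0:
                    shift = -shift
                values[(hi, cid)] = _round2(src + shift)
            planted_slots.update({(lo, cid), (hi, cid)})
            planted_pairs.add((cid, lo, hi))
            used_compounds.add(cid)
            truth.planted[kind].append((t, cid, lo, hi))
            planted += 1
        if planted < n:
            raise ConfigError(
                f"could not plant {n} {kind} pairs; fixture has too little overlap"
            )

    plant_pairs(counts["copied"], "copied")
    plant_pairs(counts["unit_error"], "unit_error")

    # --- nudge accidental duplicate-rule coincidences away --------------------
    if cfg.disjoint_pathologies:
        _avoid_collisions(
            values, assay_target, planted_slots, planted_pairs, cfg.duplicate_tolerance
        )

    tables = _emit_tables(cfg, values, assay_target, mutant_keys, lowconf_keys, rng)
    return tables, truth


def _avoid_collisions(values, assay_target, planted_slots, planted_pairs, tol):
    """Nudge non-planted pairs off the Δ ∈ {0, ±3} windows.

    Bumps one slot of each colliding pair by +0.01 (preferring the slot not
    involved in a planted copy) and re-checks; converges in a few sweeps
    because each bump moves a pair strictly off a measure-zero window.
    """
    by_tc: dict[tuple[str, int], list[int]] = {}
    for (key, cid) in values:
        by_tc.setdefault((assay_target[key], cid), []).append(key)
    for _ in range(50):
        bumped: set[tuple[int, int]] = set()
        for (t, cid), keys in by_tc.items():
            if len(keys) < 2:
                continue
            ks = sorted(keys)
            for i, lo in enumerate(ks):
                for hi in ks[i + 1:]:
                    if (cid, lo, hi) in planted_pairs:
                        continue
                    d = abs(values[(hi, cid)] - values[(lo, cid)])
                    if d <= tol or abs(d - 3.0) <= tol:
                        slot = (hi, cid) if (hi, cid) not in planted_slots else (lo, cid)
                        if slot in bumped:
                            continue
                        v = values[slot] + 0.01
                        if v > 14.0:
                            v = values[slot] - 0.02
                        values[slot] = _round2(v)
                        bumped.add(slot)
        if not bumped:
            return
    raise RuntimeError("collision avoidance failed to converge")


def _emit_tables(cfg, values, assay_target, mutant_keys, lowconf_keys, rng):
    assay_rows = []
    doc_rows = []
    mutant_keys = sorted(mutant_keys)
    for idx, key in enumerate(sorted(assay_target)):
        t = assay_target[key]
        doc_id = 1000 + key  # one document per assay
        doc_rows.append((doc_id, f"20{10 + (key % 15):02d}-01-01"))
        description = f"Inhibition of {t} catalytic activity"
        variant_id = pd.NA
        if key in mutant_keys:
            # alternate flavors: description keyword vs explicit variant_id
            if mutant_keys.index(key) % 2 == 0:
                description = f"Inhibition of {t} mutant enzyme"
            else:
                variant_id = 7000 + key
        confidence = 8 if key in lowconf_keys else 9
        assay_rows.append(
            {
                "assay_key": key,
                "chembl_assay_id": f"CHEMBL{9000000 + key}",
                "target_id": t,
                "doc_id": doc_id,
                "description": description,
                "assay_type": "B",
                "assay_organism": "Homo sapiens",
                "assay_category": pd.NA,
                "assay_tax_id": 9606,
                "assay_strain": pd.NA,
                "assay_tissue": pd.NA,
                "assay_cell_type": pd.NA,
                "assay_subcellular_fraction": pd.NA,
                "bao_format": "BAO_0000357",
                "variant_id": variant_id,
                "confidence_score": confidence,
            }
        )
    assays = pd.DataFrame(assay_rows)
    for c in ["doc_id", "assay_tax_id", "variant_id", "confidence_score"]:
        assays[c] = assays[c].astype("Int64")
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
        assays[c] = assays[c].astype("string")

    act_rows = []
    for i, ((key, cid), v) in enumerate(sorted(values.items()), start=1):
        act_rows.append(
            {
                "activity_id": i,
                "assay_key": key,
                "compound_id": cid,
                "pchembl": v,
                "standard_type": cfg.readout,
                "standard_relation": "=",
                "standard_units": "nM",
                "data_validity_comment": pd.NA,
            }
        )
    activities = pd.DataFrame(act_rows)
    for c in ["standard_type", "standard_relation", "standard_units", "data_validity_comment"]:
        activities[c] = activities[c].astype("string")

    docs = pd.DataFrame(doc_rows, columns=["doc_id", "doc_date"])
    docs["doc_id"] = docs["doc_id"].astype("Int64")
    docs["doc_date"] = docs["doc_date"].astype("string")

    # source_has_doc_date mirrors what load_tables derives: every generated
    # assay's document is dated
    assays["source_has_doc_date"] = True
    return {"activities": activities, "assays": assays, "docs": docs}


def write_fixture(cfg: GeneratorConfig, directory) -> SyntheticGroundTruth:
    """Generate a fixture and write it in the flat-file dump dialect."""
    tables, truth = generate_fixture(cfg)
    chembl_io.write_dump(tables, directory)
    return truth


def expected_metrics(cfg: GeneratorConfig, thresholds=(0.3, 1.0)) -> dict:
    """Closed-form expectations for metrics on clean (pathology-free) data.

    With per-side noise σ_eff² = noise_sd² + assay_bias_sd², the signed pair
    difference is Normal(0, 2 σ_eff²), so

    * E[MAE]  = 2 σ_eff / √π  (folded-normal mean),
    * E[f>t]  = 2 (1 − Φ(t / (σ_eff √2))),
    * E[τ]    = (2/π) arcsin(s² / (s² + σ_eff²))  for affinity spread s
      (Greiner's relation for a bivariate normal).
    """
    sigma_eff = math.sqrt(cfg.noise_sd**2 + cfg.assay_bias_sd**2)
    s2 = cfg.affinity_spread**2
    out = {
        "sigma_eff": sigma_eff,
        "mae": 2.0 * sigma_eff / math.sqrt(math.pi),
        "f_gt": {},
        "tau": 1.0
        if sigma_eff == 0
        else (2.0 / math.pi) * math.asin(s2 / (s2 + sigma_eff**2)),
    }
    for t in thresholds:
        if sigma_eff == 0:
            out["f_gt"][float(t)] = 0.0
        else:
            out["f_gt"][float(t)] = 2.0 * (
                1.0 - norm.cdf(t / (sigma_eff * math.sqrt(2.0)))
            )
    return out
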