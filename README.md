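# assaycompat

Curation and compatibility analysis for duplicate dose–response measurements
in ChEMBL-schema bioactivity data.

## The problem

Public bioactivity databases hold tens of thousands of IC50 and K_i assays,
but very few individual assays cover enough compounds to train a model, so it
is common practice to pool results from many assays measured against the
"same" target.  Two assays with the same target annotation can nevertheless
disagree badly: different substrates and substrate concentrations, different
protein variants sharing one target ID, different cell types and assay
technologies, values copied between publications (sometimes with a unit
error), and screening depositions mixed in with the primary literature.  All
of this turns into noise in the pooled dataset and caps the accuracy of any
model trained on it.

`assaycompat` quantifies that noise and curates it away.  The key idea is to
use compounds measured in **two or more assays against the same target** as
internal duplicates: for each such compound we form an oriented measurement
pair and study the difference

    Δpchembl = pchembl(higher assay key) − pchembl(lower assay key)

where pchembl = −log10(molar activity), so a pchembl of 6 is 1 μM and a Δ of
1 is a ten-fold disagreement.

## What it computes

Over any set of measurement pairs the package reports the standard agreement
battery:

* **R²** — coefficient of determination of the later measurement against the
  earlier one on the identity line (can be negative);
* **Kendall τ** (tie-corrected τ-b) — rank equivalence of the two assays;
* **MAE** — mean |Δpchembl| in log units;
* **f > 0.3** and **f > 1.0** — fractions of pairs disagreeing by more than
  the typical experimental-error window (0.3 log units ≈ factor 2) and by
  more than one log unit;
* **κ_bin / MCC_bin** — Cohen's κ and the Matthews correlation after binning
  into active/inactive at pchembl thresholds of 5, 6 and 7.

On the curation side, every filter is independent and switchable:

| filter | removes |
|---|---|
| activity curation | pairs with \|Δ\| ≈ 0 (copied values) or \|Δ\| ≈ 3 (copies with a unit error) |
| duplicate papers | pairs whose assays come from the same document |
| remove mutants | assays with "mutant"/"mutation"/"variant" in the description or a variant_id |
| assay type | pairs with differing assay types (binding vs functional, …) |
| assay metadata | pairs differing in any of nine metadata fields (organism, cell type, tissue, BAO format, …) |
| document sources | assays whose source has no associated document date (screening depositions) |
| assay size | assays with more than 100 (or 1000) distinct compounds (review articles) |
| curation confidence | assays without a target-assignment confidence score of 9 |

Two presets are named: **only-activity** (just the copied-value rule) and
**maximal** (everything).  For dataset extraction, assays surviving maximal
curation are grouped by target ID and a **conditions hash** — the MD5 digest
of the ten metadata fields — so that each combined dataset only pools assays
that are equivalent as far as the database can tell.  A separate pruning step
removes clusters of mutually inconsistent assays that share more than ten
compounds with a known-problematic seed assay.

A synthetic-data generator emits miniature ChEMBL-like fixtures (activities,
assays, docs tables) with known true affinities, per-assay biases, and
planted pathologies of every kind, so the whole pipeline is testable without
any database download.

## Worked example

Generate a noisy two-target fixture (20 assays, per-measurement noise 0.3
log units, per-assay bias 0.15, plus 8 copied values, 4 unit errors, 3
variant assays, 1 oversized assay and 2 sub-confidence assays), then analyze
it at both curation levels:

```bash
python - <<'EOF'
from assaycompat.synthetic_data import GeneratorConfig, write_fixture
cfg = GeneratorConfig(seed=42, n_targets=2, assays_per_target=10,
                      compounds_per_assay=40, noise_sd=0.3, assay_bias_sd=0.15,
                      n_copied_values=8, n_unit_errors=4, n_mutant_assays=3,
                      n_mega_assays=1, n_low_confidence_assays=2)
write_fixture(cfg, "demo/fixture")
EOF
assaycompat analyze demo/fixture --curation only-activity --out demo/oa
assaycompat analyze demo/fixture --curation maximal      --out demo/mx
```

The two report rows (abridged):

| curation | #pairs | τ | MAE | f>0.3 | f>1.0 | MCC₆ |
|---|---|---|---|---|---|---|
| only-activity | 3988 | 0.41 | 0.78 | 0.73 | 0.31 | 0.34 |
| maximal | 1948 | 0.64 | 0.40 | 0.52 | 0.04 | 0.53 |

Reading: with only the copied-value rule, 73% of duplicate measurements
disagree by more than the experimental-error window and 31% by more than
ten-fold — pooling these assays naively would bury the signal.  Maximal
curation discards half the pairs (those touching variant, oversized,
sub-confidence or metadata-mismatched assays) and the survivors agree far
better: τ rises from 0.41 to 0.64 and the mean absolute disagreement halves.
The residual MAE ≈ 0.40 is what the planted noise model predicts for clean
duplicates (2σ_eff/√π with σ_eff ≈ 0.34), i.e. the curation removed the
artifacts without touching the genuine experimental scatter.

`assaycompat datasets` assembles the combined per-target datasets (grouped
by conditions hash under maximal curation) and `assaycompat histogram`
reports compounds-per-assay counts and how many assays exceed 10/100/500
compounds.

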