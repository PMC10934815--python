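# Methods

## Measurement pairs and orientation

The unit of analysis is the *measurement pair*: one compound's two pchembl
values from two distinct assays annotated with the same target.  Pairs are
oriented by the sequential database assay key — the member with the larger
key is the "hi" side and Δpchembl = value_hi − value_lo.  Because keys are
assigned in load order, the hi side is usually the more recent publication;
orientation only matters for R² (which treats the lo side as reference) and
is irrelevant for MAE, the f>t fractions, τ, κ and MCC, which are symmetric
under a global swap (asserted by a regression test).

Records enter the analysis only if the activity value is unqualified
(standard_relation exactly `"="`; a null relation is treated as qualified and
dropped), the standard units are nM, pchembl is present, and no
data-validity comment is attached.  Within-assay replicates are collapsed to
one value per (assay, compound) before pairing; the default aggregator is
the median, which is robust to the copy/typo artifacts this package is
about, with `mean` and `drop-replicated` available as options.  A compound
appearing in k assays of a target contributes k(k−1)/2 pairs.

## Metric suite

* R² = 1 − Σ(y−x)²/Σ(y−ȳ)² with y the lo-side values; unbounded below.
* Kendall τ in the tie-corrected τ-b variant (scipy), because stored pchembl
  values are rounded to two decimals and tie frequently.
* MAE = mean |Δ|; f>t = fraction with |Δ| strictly greater than t, for
  t = 0.3 (the conventional experimental-error window, about a factor of
  two) and t = 1.0 (a ten-fold difference).
* κ and MCC (scikit-learn) after binning at pchembl ≥ b for b ∈ {5, 6, 7}
  (10 μM, 1 μM, 100 nM); the cut is inclusive, so a pchembl of exactly 5.0
  is active at the 10 μM threshold.
* Degenerate inputs — an empty pair set, constant vectors, a single class on
  either side of a binning — yield NaN as an explicit undefined flag, never
  a silent 0.

## Curation filters

Assay-level filters (variant/"mutant" assays, undocumented sources,
oversized assays, sub-confidence assays) compute a retained-key set and drop
every pair touching a removed assay; pair-level filters (copied values, same
document, assay type, nine-field metadata match) act on the pair table.
`apply_curation` runs assay-level filters first so that a pair touching a
removed assay is charged to that filter in the removal ledger; the final
survivor set is independent of the order of the assay-level filters, and
ledger counts sum to the total number removed.

Null-handling choices, each a genuine design decision:

* **Copied-value rule.**  |Δ| ≤ 0.005 or ||Δ| − 3.0| ≤ 0.005.  The 0.005
  tolerance absorbs the two-decimal rounding of stored values; bitwise
  equality would miss stored-rounded copies.  The 3-log-unit rule is applied
  to |Δ| in both directions, since a unit error can occur in either
  publication.
* **Same document.**  A null doc_id never matches anything — two
  undocumented assays are not "the same paper".
* **Metadata match.**  null == null counts as a match; most metadata fields
  are sparsely populated and demanding non-null equality would empty the
  data.  null vs a value is a mismatch.  The assay-type filter, by contrast,
  requires two equal non-null types.
* **Variant flagging.**  Case-insensitive plain substring match on
  "mutant"/"mutation"/"variant" (no word boundaries — deliberately
  conservative) plus any non-null variant_id.  Two modes exist:
  *pair-analysis* flags text OR variant_id (used when quantifying pair
  noise); *extraction* flags text only when variant_id is null, because an
  assay with an explicit variant_id is an identifiable variant and the
  variant_id participates in the conditions hash.
* **Document-date requirement.**  An assay passes when its doc_id resolves
  to a docs-table row with a non-null date; this is the package's reading of
  "source with an associated document date" and is derived once at load time
  into a per-assay boolean.
* **Assay size.**  Distinct validity-filtered compounds ≤ 100 by default
  (≤ 1000 for the "large" variant); strict `>` removal, so exactly 100
  survives.

## Conditions hash and dataset assembly

The hash is MD5 over ten fields — assay_type, assay_organism,
assay_category, assay_tax_id, assay_strain, assay_tissue, assay_cell_type,
assay_subcellular_fraction, bao_format, variant_id — serialized in that
order, joined with the U+001F unit separator, nulls encoded with a sentinel
token and numeric fields canonicalized to plain decimal strings so database
and flat-file loads hash identically.  Minimum-mode assembly pools all
assays of a target; maximal mode first applies the extraction filters
(documented sources, confidence 9, extraction-mode variant removal, one
assay per (document, target) keeping the largest with ties broken to the
smaller assay key — deterministic under input permutation), then groups by
(target_id, hash).  A compound measured by several member assays keeps all
values with assay provenance; aggregation to a single training value is
left to downstream users.

## Pruning

Given seed assays (specified by their public accession and resolved to keys
at run time), every assay whose distinct-compound overlap with any seed
strictly exceeds `min_shared` (default 10) is removed, seeds included.
Expansion is one hop by default; a transitive flag re-applies the rule with
removed assays as new seeds until closure, and its output is always a
superset of the one-hop result.  Overlap is counted on validity-filtered
distinct compounds, consistent with all other size accounting.

## Synthetic-data generator

Clean measurements are `true_affinity(c) + bias(a) + N(0, noise_sd²)`,
rounded to two decimals.  Compound affinities are N(affinity_mean = 7.0,
affinity_spread² = 1.0) — a realistic single-target potency spread; assay
biases are N(0, assay_bias_sd²) with default 0.1 for ordinary inter-lab
offsets.  Each target has a compound pool of size
compounds_per_assay / overlap_fraction from which each assay samples
without replacement, so the expected pairwise overlap is
compounds_per_assay × overlap_fraction.

Planted pathologies and why they carry signal:

* copied values — the hi-side measurement is replaced by the lo-side value
  (Δ exactly 0); unit errors add exactly ±3.0 (sign flipped when it would
  leave the 0–14 range);
* variant assays — flagged by description text or variant_id in alternation,
  and given a per-assay affinity shift of ±U(0.8, 2.0) because a variant
  protein genuinely binds differently;
* sub-confidence assays — confidence score 8 and a ±U(0.5, 1.5) shift
  modelling an indirect target assignment;
* oversized assays — an extra assay with `mega_assay_size` (default 120)
  compounds and inflated measurement noise, modelling aggregated review
  data;
* the incompatible cluster — `incompatible_cluster_size` assays on one
  target sharing a dedicated set of 15 compounds, each with its own ±U(1.0,
  2.5) offset so they disagree with each other; the first member is the
  designated seed.  A boundary assay sharing exactly 10 compounds with the
  seed is planted alongside so the strictness of the pruning threshold is
  observable.

With disjoint planting (the default), pathologies never overlap, and any
accidental Δ ∈ {0, ±3} coincidence among non-planted pairs is nudged away by
one or two hundredths of a log unit — otherwise clean pairs whose rounded
values happen to collide (about 1% at noise 0.3) would be indistinguishable
from planted copies and per-filter attribution could not be exact.  The
nudges are far below every metric tolerance used.  Each emitted fixture is
byte-identical for a given seed.

`expected_metrics` gives the closed forms the clean fixtures are checked
against, with σ_eff² = noise_sd² + assay_bias_sd²:

* E[MAE] = 2σ_eff/√π (folded normal),
* E[f>t] = 2(1 − Φ(t/(σ_eff√2))),
* E[τ] = (2/π)·arcsin(s²/(s² + σ_eff²)) for affinity spread s (Greiner's
  relation for a bivariate normal).

What the generator does **not** emulate: real chemical structures (compounds
are abstract integers), heavy-tailed and censored activity distributions,
correlated metadata patterns, multiple readouts per assay, and the long-tail
assay-size distribution of a real database.  Passing tests therefore
demonstrate that the pipeline's mechanics — extraction, pairing, filtering,
hashing, pruning, metrics — are correct under a controlled noise model, not
that any particular noise magnitude holds for real data.

## Problem sizes and numerical checks

The verification fixtures are sized so that Monte-Carlo error sits well
inside the check tolerances: ~100,000 pairs (10 assays × 2,223 compounds)
for the f>0.3 and MAE recovery (tolerances ±0.02 and ±0.01), ~10,000 pairs
(4 assays × 1,667 compounds) for τ (±0.03), and 50 random small
configurations (5–8 assays per target, 15–25 compounds per assay) for the
curation monotonicity property.  Using many compounds and few assay
replicates keeps the pairs nearly independent, which is what makes those
tolerances attainable; two-decimal rounding biases f>0.3 by about −0.005
and τ by about +0.004 at these settings, both absorbed by the tolerances.
Metric implementations are cross-checked against O(n²) concordance counting
(τ-b), the direct R² formula, and the explicit 2×2-table formulas for κ and
MCC to 10⁻⁹ on short random vectors.

## Known limitations

* The monotonicity property "maximal MAE ≤ only-activity MAE" holds because
  every planted pathology is noisier than clean data; on real data a filter
  can remove pairs that happen to agree, and an inconsistent cluster that no
  metadata distinguishes will *survive* maximal curation and degrade its
  metrics until pruned — the Ki-style failure mode the pruning step exists
  for.
* Pruning requires externally identified seed assays; the package does not
  detect problematic clusters automatically.
* Conditions hashes are not comparable across database releases.
* Cross-readout pairs (IC50 vs K_i) are never formed.
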