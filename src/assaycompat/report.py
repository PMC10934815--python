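"""End-to-end analysis driver and summary artifacts.

:func:`run_analysis` chains load → validity filter → within-assay aggregation
→ pair construction → curation → optional pruning → metric suite, and
optionally writes the report row, the per-step removal ledger, the oriented
pair table and the Δpchembl histogram as delimited files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from assaycompat import chembl_io, overlap, curation as cur, metrics, pruning

log = logging.getLogger("assaycompat")

SIZE_THRESHOLDS = (10, 100, 500)


def delta_histogram(deltas, width: float = 0.1) -> pd.DataFrame:
    """Counts of Δpchembl in bins of ``width`` log units symmetric about 0.

    Bin k covers ((k - 1/2)·width, (k + 1/2)·width]; the center bin straddles
    zero.  Empty bins inside the observed range are included.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        return pd.DataFrame(columns=["bin_center", "count"])
    idx = np.round(deltas / width).astype(int)
    lo, hi = idx.min(), idx.max()
    centers = np.arange(lo, hi + 1)
    counts = np.bincount(idx - lo, minlength=len(centers))
    return pd.DataFrame(
        {"bin_center": centers * width, "count": counts.astype(int)}
    )


def assay_size_histogram(
    activities: pd.DataFrame, thresholds=SIZE_THRESHOLDS
) -> dict:
    """Distinct-compound counts per assay, binned, plus threshold tallies.

    Only measurements with a non-null pchembl count toward an assay's size.
    Returns ``{"per_assay": Series, "histogram": DataFrame, "exceeding":
    {t: n_assays_with_more_than_t_compounds}}``.
    """
    withp = activities.loc[activities["pchembl"].notna()]
    per_assay = withp.groupby("assay_key")["compound_id"].nunique()
    hist = (
        per_assay.value_counts().sort_index().rename("n_assays").rename_axis("n_compounds")
    )
    exceeding = {int(t): int((per_assay > t).sum()) for t in thresholds}
    return {
        "per_assay": per_assay,
        "histogram": hist.reset_index(),
        "exceeding": exceeding,
    }


def run_analysis(
    source,
    readout: str = "IC50",
    curation_level="only-activity",
    max_assay_size: int = 100,
    aggregator: str = "median",
    prune_seeds: list[str] | None = None,
    prune_min_shared: int = 10,
    bins=metrics.DEFAULT_BINS,
    out=None,
) -> dict:
    """Run the full compatibility analysis for one readout and curation level.

    ``curation_level`` is a preset name (``"only-activity"``/``"maximal"``),
    a :class:`~assaycompat.curation.CurationConfig`, or ``None`` for no
    curation.  ``prune_seeds`` is a list of "CHEMBL…" assay accession strings
    seeding the problematic-cluster removal.

    Returns a dict with the surviving pairs, the metric report, the per-step
    ledger, and the Δpchembl histogram; when ``out`` is given the same
    artifacts are written as tab-delimited files.
    """
    activities, assays = chembl_io.load_tables(source, readout)
    log.info("loaded %d activities, %d assays", len(activities), len(assays))
    valid = chembl_io.filter_valid_activities(activities)
    log.info("validity filter kept %d/%d activities", len(valid), len(activities))
    values = overlap.aggregate_within_assay(valid, how=aggregator)
    pairs = overlap.find_measurement_pairs(values, assays)
    log.info("built %d measurement pairs", len(pairs))

    if curation_level is None:
        config = cur.CurationConfig()
    elif isinstance(curation_level, cur.CurationConfig):
        config = curation_level
    else:
        config = cur.PRESETS[str(curation_level)](max_assay_size=max_assay_size)

    curated, ledger = cur.apply_curation(pairs, assays, valid, config)
    for step, n in ledger.items():
        log.info("curation step %-16s removed %d pairs", step, n)

    if prune_seeds:
        sets = pruning.compound_sets(valid)
        seeds = pruning.resolve_seed_ids(assays, list(prune_seeds))
        removed = pruning.expand_problem_assays(seeds, sets, prune_min_shared)
        before = len(curated)
        mask = curated["assay_hi"].isin(removed) | curated["assay_lo"].isin(removed)
        curated = curated.loc[~mask].reset_index(drop=True)
        ledger["pruning"] = before - len(curated)
        log.info("pruning removed %d assays, %d pairs", len(removed), before - len(curated))

    report = metrics.compatibility_report(curated, bins=bins)
    hist = delta_histogram(curated["delta"]) if len(curated) else delta_histogram([])

    result = {
        "report": report,
        "row": report.as_row(),
        "ledger": ledger,
        "pairs": curated,
        "delta_histogram": hist,
    }
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([report.as_row()]).to_csv(out / "report.txt", sep="\t", index=False)
        pd.DataFrame(
            sorted(ledger.items()), columns=["step", "pairs_removed"]
        ).to_csv(out / "ledger.txt", sep="\t", index=False)
        overlap.write_pairs(curated, out / "pairs.txt")
        hist.to_csv(out / "delta_histogram.txt", sep="\t", index=False)
        (out / "run.json").write_text(
            json.dumps(
                {
                    "readout": readout,
                    "curation": str(curation_level),
                    "n_pairs": int(report.n_pairs),
                    "ledger": {k: int(v) for k, v in ledger.items()},
                },
                indent=2,
            )
        )
    return result
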