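"""Matched measurement pairs for compounds assayed repeatedly on one target.

A *measurement pair* is one compound's two pchembl values from two distinct
assays against the same target.  Pairs are oriented by the sequential database
assay key: the member with the larger ``assay_key`` sits in the ``hi`` slot and
``delta = value_hi - value_lo``.  Because assay keys are assigned in load
order, the hi value is typically the more recent publication.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PAIR_COLUMNS = [
    "target_id",
    "compound_id",
    "assay_hi",
    "assay_lo",
    "value_hi",
    "value_lo",
    "delta",
]

AGGREGATORS = {"median", "mean", "drop-replicated"}


def aggregate_within_assay(
    activities: pd.DataFrame, how: str = "median"
) -> pd.DataFrame:
    """Collapse within-assay replicates to one pchembl per (assay, compound).

    ``how`` is ``"median"`` (default), ``"mean"``, or ``"drop-replicated"``
    (discard any (assay, compound) with more than one measurement).  Input is
    expected to be validity-filtered already.

    Returns a DataFrame with columns ``assay_key``, ``compound_id``,
    ``pchembl``.
    """
    if how not in AGGREGATORS:
        raise ValueError(f"unknown aggregator {how!r}; choose from {sorted(AGGREGATORS)}")
    if activities.empty:
        return pd.DataFrame(columns=["assay_key", "compound_id", "pchembl"])
    grouped = activities.groupby(["assay_key", "compound_id"], sort=True)["pchembl"]
    if how == "drop-replicated":
        agg = grouped.agg(["median", "size"]).reset_index()
        agg = agg.loc[agg["size"] == 1].drop(columns="size")
        agg = agg.rename(columns={"median": "pchembl"})
    else:
        agg = grouped.agg(how).reset_index()
    return agg.reset_index(drop=True)


def find_measurement_pairs(
    values: pd.DataFrame, assays: pd.DataFrame
) -> pd.DataFrame:
    """Build all oriented measurement pairs.

    Parameters
    ----------
    values
        Output of :func:`aggregate_within_assay` — one pchembl per
        (assay_key, compound_id).
    assays
        Assay table supplying the ``target_id`` of each ``assay_key``.

    Returns
    -------
    DataFrame with :data:`PAIR_COLUMNS`.  One row per unordered assay pair per
    shared compound, restricted to assays with identical ``target_id``; a
    compound present in *k* assays of one target contributes k(k-1)/2 rows.
    """
    if values.empty:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    known = set(assays["assay_key"].tolist())
    missing = set(values["assay_key"].tolist()) - known
    if missing:
        raise KeyError(
            f"assay_key(s) without an assay record: {sorted(missing)[:10]}"
        )
    v = values.merge(
        assays[["assay_key", "target_id"]], on="assay_key", how="left"
    )
    # self-join on (target, compound); keep ordered combinations only
    pairs = v.merge(v, on=["target_id", "compound_id"], suffixes=("_hi", "_lo"))
    pairs = pairs.loc[pairs["assay_key_hi"] > pairs["assay_key_lo"]]
    out = pd.DataFrame(
        {
            "target_id": pairs["target_id"].to_numpy(),
            "compound_id": pairs["compound_id"].to_numpy(),
            "assay_hi": pairs["assay_key_hi"].to_numpy(),
            "assay_lo": pairs["assay_key_lo"].to_numpy(),
            "value_hi": pairs["pchembl_hi"].to_numpy(),
            "value_lo": pairs["pchembl_lo"].to_numpy(),
        }
    )
    out["delta"] = out["value_hi"] - out["value_lo"]
    out = out.sort_values(
        ["target_id", "compound_id", "assay_lo", "assay_hi"], kind="mergesort"
    ).reset_index(drop=True)
    return out


def write_pairs(pairs: pd.DataFrame, path) -> None:
    """Export pairs as a tab-delimited table with the seven pair columns."""
    pairs[PAIR_COLUMNS].to_csv(path, sep="\t", index=False)
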