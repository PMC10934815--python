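"""Compatibility metric suite over a set of oriented measurement pairs.

The suite mirrors the standard agreement battery for duplicate dose-response
measurements: coefficient of determination on the identity line, tie-corrected
Kendall τ-b, mean absolute Δpchembl, fractions of pairs exceeding the
experimental-error window (0.3 log units) and one log unit, and chance-
corrected binary agreement (Cohen's κ, Matthews correlation) after binning
into active/inactive at pchembl thresholds of 5, 6 and 7.

Degenerate inputs (too few pairs, a single class on one side of a binning)
yield ``math.nan`` rather than a silent 0 — NaN is the explicit
undefined-flag throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score, matthews_corrcoef

DEFAULT_DELTA_THRESHOLDS = (0.3, 1.0)
DEFAULT_BINS = (5.0, 6.0, 7.0)


def frac_exceeding(deltas, t: float) -> float:
    """Fraction of pairs with |Δpchembl| strictly greater than ``t``."""
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        return math.nan
    return float(np.mean(np.abs(deltas) > t))


def kendall_tau(x, y) -> float:
    """Tie-corrected Kendall rank correlation (τ-b).

    Stored pchembl values are rounded to two decimals and tie frequently, so
    the tie-corrected variant is the meaningful one.  Undefined (fewer than
    two pairs, or a constant vector) → NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def r_squared(x, y) -> float:
    """Coefficient of determination of hi-assay values against lo-assay values.

    Computed as ``1 - Σ(y_i - x_i)² / Σ(y_i - ȳ)²`` with the lower-assay-key
    values ``y`` as reference and the higher-assay-key values ``x`` as the
    prediction; can be negative when duplicate values disagree more than the
    reference spread.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        return math.nan
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - x) ** 2))
    if ss_tot == 0.0:
        return math.nan if ss_res > 0 else 1.0
    return 1.0 - ss_res / ss_tot


def binned_agreement(x, y, b: float) -> tuple[float, float]:
    """Cohen's κ and Matthews correlation after binning at threshold ``b``.

    A value is active iff it is ≥ b (a pchembl of exactly 5.0 is active at
    the 10 μM cut).  When either side shows a single class the 2×2 table is
    degenerate and both coefficients are NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        return math.nan, math.nan
    ax = (x >= b).astype(int)
    ay = (y >= b).astype(int)
    if len(np.unique(ax)) < 2 or len(np.unique(ay)) < 2:
        return math.nan, math.nan
    kappa = float(cohen_kappa_score(ay, ax))
    mcc = float(matthews_corrcoef(ay, ax))
    return kappa, mcc


@dataclass
class CompatibilityReport:
    """Machine form of one summary-table row for a pair set."""

    n_assays: int
    n_pairs: int
    n_compounds: int
    r2: float
    tau: float
    mae: float
    f_gt: dict[float, float] = field(default_factory=dict)
    kappa: dict[float, float] = field(default_factory=dict)
    mcc: dict[float, float] = field(default_factory=dict)

    def as_row(self) -> dict:
        """Flat dict suitable for a delimited report table."""
        row = {
            "n_assays": self.n_assays,
            "n_pairs": self.n_pairs,
            "n_compounds": self.n_compounds,
            "r2": self.r2,
            "tau": self.tau,
            "mae": self.mae,
        }
        for t, v in self.f_gt.items():
            row[f"f_gt_{t:g}"] = v
        for b in self.kappa:
            row[f"kappa_{b:g}"] = self.kappa[b]
            row[f"mcc_{b:g}"] = self.mcc[b]
        return row


def compatibility_report(
    pairs: pd.DataFrame,
    bins=DEFAULT_BINS,
    delta_thresholds=DEFAULT_DELTA_THRESHOLDS,
) -> CompatibilityReport:
    """Compute the full metric suite over an oriented pair table."""
    n_pairs = len(pairs)
    if n_pairs == 0:
        return CompatibilityReport(
            n_assays=0,
            n_pairs=0,
            n_compounds=0,
            r2=math.nan,
            tau=math.nan,
            mae=math.nan,
            f_gt={float(t): math.nan for t in delta_thresholds},
            kappa={float(b): math.nan for b in bins},
            mcc={float(b): math.nan for b in bins},
        )
    hi = pairs["value_hi"].to_numpy(dtype=float)
    lo = pairs["value_lo"].to_numpy(dtype=float)
    deltas = pairs["delta"].to_numpy(dtype=float)
    n_assays = len(
        set(pairs["assay_hi"].tolist()) | set(pairs["assay_lo"].tolist())
    )
    n_compounds = int(pairs["compound_id"].nunique())
    report = CompatibilityReport(
        n_assays=n_assays,
        n_pairs=n_pairs,
        n_compounds=n_compounds,
        r2=r_squared(hi, lo),
        tau=kendall_tau(hi, lo),
        mae=float(np.mean(np.abs(deltas))),
    )
    for t in delta_thresholds:
        report.f_gt[float(t)] = frac_exceeding(deltas, float(t))
    for b in bins:
        k, m = binned_agreement(hi, lo, float(b))
        report.kappa[float(b)] = k
        report.mcc[float(b)] = m
    return report
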