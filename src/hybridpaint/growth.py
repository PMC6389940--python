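"""Colony growth-curve metrics and the mid-parent d statistic.

Curves are replicate medians of log2 colony size, baseline-subtracted.
Three metrics summarise each curve: AUC (integral of a cubic smoothing
spline), MS (98th percentile of sliding-window regression slopes with a
correlation filter) and ECS (final value).  A strain's deviation from the
mid-parent point is scaled by half the difference between the parental
medians,

    d = (x_s - [med(X_P1) + med(X_P2)]/2) / (|med(X_P1) - med(X_P2)|/2),

so the parents sit at -1/+1, the midpoint at 0 and transgressive strains
beyond +-1.  Hybrid-vs-parent comparisons use one-sided Mann-Whitney U
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "GrowthCurve",
    "GrowthMetrics",
    "MidParentScore",
    "MannWhitneyResult",
    "build_growth_curve",
    "compute_growth_metrics",
    "midparent_d",
    "mann_whitney_u",
    "compare_hybrid_to_parents",
]


@dataclass
class GrowthCurve:
    strain: str
    condition: str
    times: np.ndarray
    values: np.ndarray  # log2 size, baseline-subtracted
    n_replicates_per_point: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time points must be strictly increasing")
        if abs(self.values[0]) > 1e-12:
            raise ValueError("curve must start at 0 after normalization")


@dataclass
class GrowthMetrics:
    AUC: float
    MS: float | None
    ECS: float


@dataclass
class MidParentScore:
    strain: str
    condition: str
    x_s: float
    parent_medians: tuple[float, float]
    a: float
    d: float


@dataclass
class MannWhitneyResult:
    U: float
    p: float
    method: str


def build_growth_curve(
    raw: pd.DataFrame,
    strain: str = "",
    condition: str = "",
    truncate_at: float | None = None,
    min_points: int = 5,
) -> GrowthCurve:
    """Median replicate curve in normalized log2 units.

    ``raw`` needs columns ``time_h``, ``colony_size`` and optionally
    ``flag`` (truthy = abnormal entry).  Zero-size and flagged entries are
    dropped per time point; the per-time median is log2-transformed and the
    initial median subtracted.  Curves with fewer than ``min_points``
    usable time points after filtering/truncation are rejected.
    """
    df = raw.copy()
    if "flag" in df.columns:
        df = df[~df["flag"].astype(bool)]
    df = df[df["colony_size"] > 0]
    if truncate_at is not None:
        df = df[df["time_h"] <= truncate_at]
    grouped = df.groupby("time_h")["colony_size"]
    med = grouped.median()
    counts = grouped.size()
    if len(med) < min_points:
        raise ValueError(
            f"only {len(med)} usable time points after filtering; need {min_points}"
        )
    times = med.index.to_numpy(dtype=float)
    values = np.log2(med.to_numpy(dtype=float))
    values = values - values[0]
    return GrowthCurve(strain, condition, times, values, counts.to_numpy())


def compute_growth_metrics(
    curve: GrowthCurve,
    window: int = 5,
    r_min: float = 0.8,
    slope_percentile: float = 98.0,
) -> GrowthMetrics:
    """AUC, maximum slope and endpoint size for one curve.

    AUC integrates a cubic smoothing spline (GCV-chosen smoothing) over
    the observed time range.  MS is the ``slope_percentile`` percentile
    (linear interpolation between order statistics) of least-squares
    slopes in overlapping ``window``-point windows whose |r| exceeds
    ``r_min``; if no window passes, MS is None (flagged undefined).
    ECS is the final curve value.
    """
    t, y = curve.times, curve.values
    if len(t) < window:
        raise ValueError("curve shorter than the slope window")
    if np.allclose(y, y[0]):
        auc = float(y[0]) * (t[-1] - t[0])
    else:
        spline = make_smoothing_spline(t, y)
        auc = float(spline.integrate(t[0], t[-1]))
    slopes = []
    for i in range(len(t) - window + 1):
        tw, yw = t[i : i + window], y[i : i + window]
        if np.ptp(yw) == 0:  # r undefined on a flat window
            continue
        res = stats.linregress(tw, yw)
        if abs(res.rvalue) > r_min:
            slopes.append(res.slope)
    ms = float(np.percentile(slopes, slope_percentile)) if slopes else None
    return GrowthMetrics(AUC=auc, MS=ms, ECS=float(y[-1]))


def midparent_d(
    x_s: float,
    parent1_values,
    parent2_values,
    strain: str = "",
    condition: str = "",
) -> MidParentScore:
    """Scaled deviation of a strain's metric from the mid-parent point."""
    p1 = np.asarray(parent1_values, dtype=float)
    p2 = np.asarray(parent2_values, dtype=float)
    if p1.size == 0 or p2.size == 0:
        raise ValueError("both parental groups must be non-empty")
    m1, m2 = float(np.median(p1)), float(np.median(p2))
    a = abs(m1 - m2) / 2.0
    if a == 0:
        raise ValueError("parental medians are equal; d undefined")
    d = (x_s - (m1 + m2) / 2.0) / a
    return MidParentScore(strain, condition, float(x_s), (m1, m2), a, d)


def mann_whitney_u(x, y, alternative: str = "two_sided") -> MannWhitneyResult:
    """Mann-Whitney U test for x against y.

    Exact p-value (full enumeration of orderings) when the smaller sample
    has at most 8 observations and there are no ties; tie-corrected normal
    approximation with continuity correction otherwise.  The method used is
    reported alongside U and p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    alt = alternative.replace("_", "-")
    if alt not in ("less", "greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < combined.size
    if min(x.size, y.size) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alt, method=method)
    return MannWhitneyResult(U=float(res.statistic), p=float(res.pvalue), method=method)


def compare_hybrid_to_parents(
    d_table: pd.DataFrame,
    hybrid: str,
    parents: tuple[str, str],
) -> tuple[pd.DataFrame, list[str]]:
    """One-sided hybrid-vs-parent tests on pooled d scores.

    ``d_table`` needs columns ``lineage``, ``condition`` and ``d``.  The
    hybrid is tested against the lower-median parent with alternative
    "greater" and against the higher-median parent with alternative
    "less" (an intermediate hybrid rejects both nulls).  Also returns the
    conditions in which the hybrid's median d exceeds both parents'
    medians (transgression screen).
    """
    for lin in (hybrid, *parents):
        if lin not in set(d_table["lineage"]):
            raise ValueError(f"lineage {lin!r} missing from d table")
    vals = {lin: d_table.loc[d_table["lineage"] == lin, "d"].to_numpy() for lin in (hybrid, *parents)}
    p_low, p_high = sorted(parents, key=lambda lin: np.median(vals[lin]))
    rows = []
    for parent, alt in ((p_low, "greater"), (p_high, "less")):
        res = mann_whitney_u(vals[hybrid], vals[parent], alternative=alt)
        rows.append(
            {
                "hybrid": hybrid,
                "parent": parent,
                "alternative": alt,
                "U": res.U,
                "p": res.p,
                "method": res.method,
                "n_hybrid": len(vals[hybrid]),
                "n_parent": len(vals[parent]),
            }
        )
    transgressive = []
    for cond, sub in d_table.groupby("condition"):
        med = {
            lin: np.median(sub.loc[sub["lineage"] == lin, "d"])
            for lin in (hybrid, *parents)
            if (sub["lineage"] == lin).any()
        }
        if len(med) == 3 and med[hybrid] > max(med[parents[0]], med[parents[1]]):
            transgressive.append(cond)
    return pd.DataFrame(rows), transgressive
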