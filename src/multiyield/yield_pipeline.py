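"""From per-well produced biomass to overall-biomass-yield estimates.

The overall biomass yield of a nutrient is the slope of produced biomass ΔB
against its initial amount, fitted on replicate-averaged endpoints over the
range that is actually linear.  This module provides replicate averaging,
automatic linear-region detection (R² gate), ordinary least-squares yield
fits, two-phase segmented fits for complex dose-response curves, the
yield-vs-base-amount profile, and the acetate secretion-rate computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .curve_processing import CalibrationModel

__all__ = [
    "LinearFit",
    "SegmentedFit",
    "YieldProfile",
    "average_replicates",
    "detect_linear_region",
    "fit_overall_yield",
    "fit_segmented_two_phase",
    "yield_vs_base_analysis",
    "acetate_secretion_rate",
]

ENDPOINT_COLUMNS = [
    "measured_amount_ug", "base_amount_ug",
    "delta_B_mean_ug", "delta_B_se_ug", "n_reps",
]


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of ΔB vs amount; the slope is the overall biomass yield."""

    slope: float
    intercept: float
    r2: float
    slope_se: float
    range: tuple[int, int]  # (first_index, last_index), inclusive

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r2 <= 1 + 1e-9):
            raise ValueError(f"r2 out of [0,1]: {self.r2}")


@dataclass(frozen=True)
class SegmentedFit:
    """Two-phase piecewise-linear fit with a single breakpoint."""

    slope1: float
    slope2: float
    breakpoint_ug: float
    r2_1: float
    r2_2: float
    intercept1: float
    intercept2: float
    constant_phase_flags: tuple[bool, bool]
    sse: float
    effectively_linear: bool


@dataclass(frozen=True)
class YieldProfile:
    """Overall biomass yield as a function of the base-nutrient amount."""

    base_amounts_ug: np.ndarray
    yields: np.ndarray
    yield_ses: np.ndarray
    trend_fit: LinearFit


def average_replicates(endpoints: pd.DataFrame) -> pd.DataFrame:
    """Replicate-average per-well ΔB into an endpoint table.

    Input is one row per well (columns ``measured_amount_ug``,
    ``base_amount_ug``, ``delta_B_ug``, optionally ``well``); output is one
    row per (base_amount, measured_amount) condition with mean, standard
    error of the mean, and replicate count, ordered deterministically.
    """
    if "well" in endpoints.columns and endpoints["well"].duplicated().any():
        dupes = endpoints.loc[endpoints["well"].duplicated(), "well"].tolist()
        raise ValueError(f"duplicate well ids: {dupes}")
    grouped = endpoints.groupby(
        ["base_amount_ug", "measured_amount_ug"], sort=True
    )["delta_B_ug"]
    table = grouped.agg(
        delta_B_mean_ug="mean",
        delta_B_se_ug=lambda x: x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else 0.0,
        n_reps="count",
    ).reset_index()
    return table[ENDPOINT_COLUMNS].sort_values(
        ["base_amount_ug", "measured_amount_ug"], ignore_index=True
    )


def _ols(x: np.ndarray, y: np.ndarray) -> LinearFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("degenerate x-values: need >= 2 distinct amounts")
    res = stats.linregress(x, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    pred = res.slope * x + res.intercept
    ss_res = float(np.sum((y - pred) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return LinearFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=r2, slope_se=se, range=(0, x.size - 1),
    )


def detect_linear_region(
    table: pd.DataFrame, r2_min: float = 0.9, min_points: int = 4
) -> tuple[int, int]:
    """Longest contiguous run of endpoints that fits a line with R² >= r2_min.

    All contiguous windows of at least ``min_points`` rows are enumerated;
    among the longest qualifying runs, ties go to the higher R², then to the
    leftmost.  Raises if no window qualifies (the data need a manual range).
    """
    x = table["measured_amount_ug"].to_numpy(float)
    y = table["delta_B_mean_ug"].to_numpy(float)
    n = x.size
    if n < min_points:
        raise ValueError(f"need >= {min_points} rows, have {n}")
    best: tuple[int, float, int] | None = None  # (length, r2, start)
    for i in range(n):
        for j in range(i + min_points - 1, n):
            xs = x[i : j + 1]
            if np.unique(xs).size < 2:
                continue
            fit = _ols(xs, y[i : j + 1])
            if fit.r2 < r2_min:
                continue
            cand = (j - i + 1, fit.r2, -i)
            if best is None or cand > best:
                best = cand
    if best is None:
        raise ValueError(
            f"no contiguous window of >= {min_points} points reaches "
            f"R^2 >= {r2_min}; specify the fit range manually"
        )
    length, _, neg_i = best
    i = -neg_i
    return (i, i + length - 1)


def fit_overall_yield(
    table: pd.DataFrame, fit_range: tuple[int, int] | None = None
) -> LinearFit:
    """OLS of replicate-mean ΔB on the measured amount; slope = overall yield."""
    if fit_range is None:
        fit_range = (0, len(table) - 1)
    i, j = fit_range
    if j - i + 1 < 2:
        raise ValueError("fit range needs >= 2 points")
    x = table["measured_amount_ug"].to_numpy(float)[i : j + 1]
    y = table["delta_B_mean_ug"].to_numpy(float)[i : j + 1]
    fit = _ols(x, y)
    return LinearFit(
        slope=fit.slope, intercept=fit.intercept, r2=fit.r2,
        slope_se=fit.slope_se, range=(i, j),
    )


def _segment_sse(x: np.ndarray, y: np.ndarray) -> tuple[float, LinearFit]:
    fit = _ols(x, y)
    pred = fit.slope * x + fit.intercept
    return float(np.sum((y - pred) ** 2)), fit


def _constant_f_test(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> bool:
    """True when a constant model is NOT rejected against the linear one.

    Standard nested-model F-test: does adding the slope significantly reduce
    the residual sum of squares?
    """
    n = x.size
    if n < 3:
        return True
    sse_const = float(np.sum((y - y.mean()) ** 2))
    sse_lin, _ = _segment_sse(x, y)
    if sse_lin <= 0:
        return sse_const <= 0
    f = (sse_const - sse_lin) / (sse_lin / (n - 2))
    p = stats.f.sf(f, 1, n - 2)
    return bool(p >= alpha)


def fit_segmented_two_phase(
    table: pd.DataFrame, min_seg_points: int = 3, alpha: float = 0.05
) -> SegmentedFit:
    """Two linear phases with a breakpoint chosen by exhaustive grid search.

    The breakpoint grid is the observed measured amounts (interior points
    only, each segment keeping at least ``min_seg_points`` rows); the pair of
    per-segment OLS fits minimising total SSE wins, ties to the smaller
    breakpoint.  Each segment is additionally tested against a constant
    model (nested F-test at ``alpha``), and the whole curve is flagged
    effectively-linear when the two slopes agree within their joint SE.
    """
    x = table["measured_amount_ug"].to_numpy(float)
    y = table["delta_B_mean_ug"].to_numpy(float)
    n = x.size
    if n < 2 * min_seg_points:
        raise ValueError(
            f"need >= {2 * min_seg_points} points for a two-phase fit, have {n}"
        )
    best: tuple[float, float, int] | None = None  # (sse, breakpoint, k)
    for k in range(min_seg_points - 1, n - min_seg_points):
        # segment 1 = rows [0..k], segment 2 = rows [k+1..n-1]
        try:
            sse1, _ = _segment_sse(x[: k + 1], y[: k + 1])
            sse2, _ = _segment_sse(x[k + 1 :], y[k + 1 :])
        except ValueError:
            continue
        sse = sse1 + sse2
        bp = float(x[k])
        # SSE ties (exactly continuous piecewise data fits with the junction
        # point in either segment) resolve to the larger breakpoint, keeping
        # the junction sample in the first phase
        if best is None or (sse, -bp) < (best[0], -best[1]):
            best = (sse, bp, k)
    if best is None:
        raise ValueError("no valid breakpoint (repeated amounts in segments)")
    sse, bp, k = best
    _, fit1 = _segment_sse(x[: k + 1], y[: k + 1])
    _, fit2 = _segment_sse(x[k + 1 :], y[k + 1 :])
    const1 = _constant_f_test(x[: k + 1], y[: k + 1], alpha)
    const2 = _constant_f_test(x[k + 1 :], y[k + 1 :], alpha)
    joint_se = math.hypot(fit1.slope_se, fit2.slope_se)
    effectively_linear = abs(fit1.slope - fit2.slope) <= 2.0 * joint_se
    return SegmentedFit(
        slope1=fit1.slope, slope2=fit2.slope, breakpoint_ug=bp,
        r2_1=fit1.r2, r2_2=fit2.r2,
        intercept1=fit1.intercept, intercept2=fit2.intercept,
        constant_phase_flags=(const1, const2), sse=sse,
        effectively_linear=effectively_linear,
    )


def yield_vs_base_analysis(fits: dict[float, LinearFit]) -> YieldProfile:
    """Assemble yields across base amounts and fit the linear trend.

    A positive trend slope means the base nutrient raises the measured
    nutrient's overall biomass yield — the signature of a positive mutual
    catabolic effect.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 base amounts")
    base = np.array(sorted(fits), dtype=float)
    yields = np.array([fits[b].slope for b in base])
    ses = np.array([fits[b].slope_se for b in base])
    trend = _ols(base, yields)
    # the residual-based OLS error of the trend can understate the true
    # uncertainty when only a few base amounts are available: combine it in
    # quadrature with the per-yield errors propagated through the slope
    # estimator (slope = sum w_i * y_i, w_i = (x_i - mean)/Sxx)
    sxx = float(np.sum((base - base.mean()) ** 2))
    w = (base - base.mean()) / sxx
    propagated = math.sqrt(float(np.sum((w * ses) ** 2)))
    trend = LinearFit(
        slope=trend.slope, intercept=trend.intercept, r2=trend.r2,
        slope_se=math.hypot(trend.slope_se, propagated), range=trend.range,
    )
    return YieldProfile(
        base_amounts_ug=base, yields=yields, yield_ses=ses, trend_fit=trend
    )


def acetate_secretion_rate(
    points: Sequence[tuple[float, float]],
    mu: float,
    cal: CalibrationModel | None = None,
) -> dict[str, float]:
    """Acetate secretion rate from supernatant assays during exponential growth.

    The slope of acetate concentration (mM) vs OD600 across all replicates,
    multiplied by the growth rate µ, gives the secretion rate in
    mM·OD⁻¹·h⁻¹.  With a calibration model the rate is also expressed per
    gram dry cell weight (mmol·gDCW⁻¹·h⁻¹) using the OD-to-biomass factor.
    """
    if len(points) < 3:
        raise ValueError("need >= 3 (OD, acetate) points")
    if mu <= 0:
        raise ValueError("mu must be > 0")
    od = np.array([p[0] for p in points], dtype=float)
    ac = np.array([p[1] for p in points], dtype=float)
    fit = _ols(od, ac)
    rate_od = fit.slope * mu
    out = {
        "slope_mm_per_od": fit.slope,
        "rate_mm_per_od_per_h": rate_od,
        "r2": fit.r2,
    }
    cal = cal or CalibrationModel()
    # mM per OD per h  ->  mmol per L per OD per h; divide by gDCW/L per OD
    out["rate_mmol_per_gdcw_per_h"] = rate_od / cal.dw_per_od_l
    return out
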