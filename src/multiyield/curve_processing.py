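"""Plate-reader growth curves to biomass trajectories and endpoint quantities.

Raw OD600 readings are linearized with a monotone calibration map, converted
to dry weight per well, and reduced to the quantities the yield analysis
needs: produced biomass ΔB (stationary endpoint minus inoculum), exponential
growth rate, and a two-phase (diauxic) segmentation with per-phase biomass
gains.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "WellTimeSeries",
    "CalibrationModel",
    "BiomassTrajectory",
    "GrowthRateFit",
    "PhaseSegment",
    "DiauxicSegmentation",
    "od_to_biomass",
    "produced_biomass_from_curve",
    "estimate_growth_rate",
    "segment_diauxic_phases",
    "read_timeseries_csv",
    "read_layout_csv",
    "read_calibration_csv",
    "extract_endpoints",
]

logger = logging.getLogger(__name__)

#: default dry-weight conversion, g dry weight per litre per OD600 unit
DW_PER_OD_L = 0.396
#: default culture volume per microplate well, litres (200 µl)
WELL_VOLUME_L = 2.0e-4


class Condition(NamedTuple):
    measured_nutrient_id: str
    measured_amount_ug: float
    base_nutrient_id: str
    base_amount_ug: float
    replicate_index: int


@dataclass(frozen=True)
class WellTimeSeries:
    """Raw OD600 readings of one well, sampled at strictly increasing times."""

    well_id: str
    times: np.ndarray           # hours
    od_raw: np.ndarray          # OD600
    condition: Condition | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od_raw, dtype=float)
        if t.ndim != 1 or od.shape != t.shape:
            raise ValueError("times and od_raw must be 1-D arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError(f"times must be strictly increasing (well {self.well_id})")
        if np.any(od < 0):
            raise ValueError(f"od_raw must be >= 0 (well {self.well_id})")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od_raw", od)


@dataclass(frozen=True)
class CalibrationModel:
    """OD linearization and dry-weight conversion for one plate reader.

    ``od_map`` is a monotone piecewise-linear map raw OD -> linearized OD
    given as (raw, linear) knots; ``None`` means identity (readings already
    linear).  ``dw_per_od_l`` converts linearized OD to g dry weight per
    litre; ``well_volume_l`` scales to per-well mass.
    """

    od_map: tuple[tuple[float, ...], tuple[float, ...]] | None = None
    dw_per_od_l: float = DW_PER_OD_L
    well_volume_l: float = WELL_VOLUME_L

    def __post_init__(self) -> None:
        if self.dw_per_od_l <= 0:
            raise ValueError("dw_per_od_l must be > 0")
        if self.well_volume_l <= 0:
            raise ValueError("well_volume_l must be > 0")
        if self.od_map is not None:
            raw, lin = (np.asarray(a, dtype=float) for a in self.od_map)
            if raw.shape != lin.shape or raw.size < 2:
                raise ValueError("od_map needs >= 2 (raw, linear) knot pairs")
            if np.any(np.diff(raw) <= 0) or np.any(np.diff(lin) < 0):
                raise ValueError("od_map knots must be monotone")
            object.__setattr__(self, "od_map", (tuple(raw), tuple(lin)))

    def linearize(self, od: np.ndarray) -> np.ndarray:
        od = np.asarray(od, dtype=float)
        if self.od_map is None:
            return od
        raw = np.asarray(self.od_map[0])
        lin = np.asarray(self.od_map[1])
        if np.any(od < raw[0]) or np.any(od > raw[-1]):
            logger.warning(
                "OD outside calibration range [%g, %g]; extrapolating linearly",
                raw[0], raw[-1],
            )
        # linear extrapolation beyond the knots using the terminal slopes
        out = np.interp(od, raw, lin)
        lo_slope = (lin[1] - lin[0]) / (raw[1] - raw[0])
        hi_slope = (lin[-1] - lin[-2]) / (raw[-1] - raw[-2])
        out = np.where(od < raw[0], lin[0] + (od - raw[0]) * lo_slope, out)
        out = np.where(od > raw[-1], lin[-1] + (od - raw[-1]) * hi_slope, out)
        return out

    def od_to_ug(self, od: np.ndarray) -> np.ndarray:
        """Linearized-OD -> µg dry weight per well."""
        return self.linearize(od) * self.dw_per_od_l * self.well_volume_l * 1e6

    def ug_to_od(self, biomass_ug: np.ndarray) -> np.ndarray:
        """Inverse conversion (linearized scale), used by the simulator."""
        lin = np.asarray(biomass_ug, dtype=float) / (
            self.dw_per_od_l * self.well_volume_l * 1e6
        )
        if self.od_map is None:
            return lin
        raw = np.asarray(self.od_map[0])
        linear = np.asarray(self.od_map[1])
        return np.interp(lin, linear, raw)


@dataclass(frozen=True)
class BiomassTrajectory:
    """Dry-weight growth curve of one well (µg vs hours)."""

    times: np.ndarray
    biomass_ug: np.ndarray
    well_id: str = ""
    condition: Condition | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        b = np.asarray(self.biomass_ug, dtype=float)
        if b.shape != t.shape:
            raise ValueError("times and biomass_ug must have equal length")
        if np.any(b < 0):
            raise ValueError("biomass_ug must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "biomass_ug", b)


def od_to_biomass(series: WellTimeSeries, cal: CalibrationModel) -> BiomassTrajectory:
    """Convert a raw OD600 time series to a dry-weight trajectory in µg."""
    return BiomassTrajectory(
        times=series.times,
        biomass_ug=cal.od_to_ug(series.od_raw),
        well_id=series.well_id,
        condition=series.condition,
    )


def produced_biomass_from_curve(
    traj: BiomassTrajectory, window_after_max_h: float = 4.0
) -> float:
    """Produced biomass ΔB: endpoint after stationary phase minus inoculum.

    The endpoint is the sample nearest ``window_after_max_h`` hours after the
    curve's maximum (default 4 h, the midpoint of a 3–5 h stationary-phase
    window), so that post-peak decline or drift is sampled consistently.
    The "maximum" is the first sample reaching 99.9% of the peak, so a
    noiseless curve approaching its plateau asymptotically anchors the
    window at the start of stationary phase, not at the last sample.
    """
    t = traj.times
    b = traj.biomass_ug
    if t.size < 2:
        raise ValueError("trajectory needs at least two samples")
    i_max = int(np.argmax(b >= 0.999 * b.max()))
    t_target = t[i_max] + window_after_max_h
    if t[-1] + 1e-9 < t_target:
        raise ValueError(
            f"trajectory ends at {t[-1]:.2f} h but the endpoint window needs "
            f"{t_target:.2f} h ({window_after_max_h} h after the maximum at "
            f"{t[i_max]:.2f} h)"
        )
    i_end = int(np.argmin(np.abs(t - t_target)))
    return float(b[i_end] - b[0])


@dataclass(frozen=True)
class GrowthRateFit:
    """Exponential growth rate from a sliding log-linear window fit."""

    mu_per_h: float
    r2: float
    t_start: float
    t_end: float
    reliable: bool


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and R² of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise ValueError("degenerate x-values in linear fit")
    slope = float(np.sum((x - xm) * (y - ym))) / sxx
    intercept = ym - slope * xm
    ss_res = float(np.sum((y - slope * x - intercept) ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r2


def estimate_growth_rate(
    traj: BiomassTrajectory,
    window_points: int = 7,
    r2_min: float = 0.95,
) -> GrowthRateFit:
    """Maximum-R² sliding-window log-linear fit of the growth rate µ (1/h).

    Scans every contiguous window of ``window_points`` samples with positive
    biomass, fits log(B) vs t, and keeps the window with the highest R²
    (ties to the earliest).  Windows with non-positive slopes are allowed so
    a flat curve reports µ ≈ 0 with ``reliable=False``.
    """
    mask = traj.biomass_ug > 0
    t = traj.times[mask]
    logb = np.log(traj.biomass_ug[mask])
    if t.size < window_points:
        raise ValueError(
            f"need >= {window_points} samples with positive biomass, have {t.size}"
        )
    best: tuple[float, float, float, float] | None = None  # r2, mu, t0, t1
    for i in range(t.size - window_points + 1):
        sl = slice(i, i + window_points)
        mu, _, r2 = _ols_slope(t[sl], logb[sl])
        if best is None or r2 > best[0] + 1e-15:
            best = (r2, mu, float(t[sl][0]), float(t[sl][-1]))
    assert best is not None
    r2, mu, t0, t1 = best
    # a rate indistinguishable from zero is never a reliable exponential fit
    reliable = bool(r2 >= r2_min and mu > 1e-3)
    return GrowthRateFit(mu_per_h=mu, r2=r2, t_start=t0, t_end=t1, reliable=reliable)


class PhaseSegment(NamedTuple):
    t_start: float
    t_end: float
    gain_ug: float
    mu_per_h: float


@dataclass(frozen=True)
class DiauxicSegmentation:
    """Two growth phases separated by a plateau, or a single phase."""

    phase1: PhaseSegment
    plateau: tuple[float, float] | None
    phase2: PhaseSegment | None
    lag2_h: float
    single_phase: bool

    @property
    def total_gain_ug(self) -> float:
        gain = self.phase1.gain_ug
        if self.phase2 is not None:
            gain += self.phase2.gain_ug
        return gain


def _moving_average(x: np.ndarray, width: int = 5) -> np.ndarray:
    """Centered moving average with edge shrinkage."""
    if width <= 1 or x.size < width:
        return x.copy()
    kernel = np.ones(width) / width
    smoothed = np.convolve(x, kernel, mode="same")
    # fix edges where the kernel hangs over the array
    half = width // 2
    for i in range(half):
        smoothed[i] = x[: i + half + 1].mean()
        smoothed[-(i + 1)] = x[-(i + half + 1):].mean()
    return smoothed


def segment_diauxic_phases(
    traj: BiomassTrajectory,
    smooth_width: int = 5,
    min_plateau_samples: int = 3,
    rate_floor_frac: float = 0.2,
) -> DiauxicSegmentation:
    """Detect two growth phases separated by a plateau in a diauxic curve.

    Works on the derivative of the smoothed log biomass: growth phases are
    intervals where the specific rate exceeds ``rate_floor_frac`` of its
    peak.  A two-changepoint search over a decimated grid picks the pair of
    breakpoints (growth-to-plateau, plateau-to-growth) minimising the
    within-segment variance of the rate signal; if no qualifying second
    phase exists the curve is flagged single-phase.
    """
    t = traj.times
    b = traj.biomass_ug
    if t.size < 20:
        raise ValueError("need >= 20 samples to segment phases")
    logb = np.log(np.maximum(b, 1e-12))
    logb_s = _moving_average(logb, smooth_width)
    rate = np.gradient(logb_s, t)
    rate_s = _moving_average(rate, smooth_width)

    peak = float(rate_s.max())
    if peak <= 0:
        raise ValueError("no growth detected (non-positive specific rate)")
    active = rate_s >= rate_floor_frac * peak

    # contiguous runs of active samples = candidate growth phases
    runs: list[tuple[int, int]] = []
    i = 0
    while i < active.size:
        if active[i]:
            j = i
            while j + 1 < active.size and active[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    runs = [r for r in runs if r[1] - r[0] + 1 >= 3]
    if not runs:
        raise ValueError("no growth phase found")

    def seg(i0: int, i1: int) -> PhaseSegment:
        gain = float(b[i1] - b[i0])
        if i1 - i0 >= 2:
            mu, _, _ = _ols_slope(t[i0 : i1 + 1], logb[i0 : i1 + 1])
        else:
            mu = float("nan")
        return PhaseSegment(float(t[i0]), float(t[i1]), gain, mu)

    # pick the two runs separated by a plateau of sufficient length;
    # refine the inner breakpoints by minimising within-segment rate variance
    first = runs[0]
    second = None
    for cand in runs[1:]:
        if cand[0] - first[1] - 1 >= min_plateau_samples:
            second = cand
            break
    if second is None:
        phase1 = seg(first[0], first[1])
        return DiauxicSegmentation(
            phase1=phase1, plateau=None, phase2=None, lag2_h=0.0, single_phase=True
        )

    # exhaustive refinement of the two changepoints between the detected runs
    lo = first[1] - min(5, first[1] - first[0])
    hi = second[0] + min(5, second[1] - second[0])
    best_pair = (first[1], second[0])
    best_cost = math.inf
    for c1 in range(max(first[0] + 1, lo), first[1] + 3):
        for c2 in range(second[0] - 2, min(hi, second[1]) + 1):
            if c2 - c1 < min_plateau_samples:
                continue
            mid = rate_s[c1 : c2 + 1]
            left = rate_s[first[0] : c1]
            right = rate_s[c2 + 1 : second[1] + 1]
            if left.size < 2 or right.size < 2 or mid.size < 2:
                continue
            cost = (
                left.var() * left.size
                + mid.var() * mid.size
                + right.var() * right.size
            )
            if cost < best_cost:
                best_cost = cost
                best_pair = (c1, c2)
    c1, c2 = best_pair
    phase1 = seg(first[0], c1)
    # gain runs to the end of the trajectory (flat stationary tail adds
    # nothing), but the rate is fitted on the active growth interval only
    phase2_gain = seg(c2, t.size - 1)
    mu2 = seg(max(c2, second[0]), second[1]).mu_per_h
    phase2 = PhaseSegment(
        phase2_gain.t_start, phase2_gain.t_end, phase2_gain.gain_ug, mu2
    )
    return DiauxicSegmentation(
        phase1=phase1,
        plateau=(float(t[c1]), float(t[c2])),
        phase2=phase2,
        lag2_h=float(t[c2] - t[c1]),
        single_phase=False,
    )


# ---------------------------------------------------------------------------
# plate-level I/O and endpoint extraction


def read_timeseries_csv(path) -> dict[str, WellTimeSeries]:
    """Read a long-format time-series CSV (columns: well, time_h, od600)."""
    df = pd.read_csv(path)
    required = {"well", "time_h", "od600"}
    if not required.issubset(df.columns):
        raise ValueError(f"time-series CSV needs columns {sorted(required)}")
    out: dict[str, WellTimeSeries] = {}
    for well, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("time_h")
        out[str(well)] = WellTimeSeries(
            well_id=str(well),
            times=grp["time_h"].to_numpy(float),
            od_raw=grp["od600"].to_numpy(float),
        )
    return out


def read_layout_csv(path) -> dict[str, Condition]:
    """Read a plate-layout CSV mapping wells to experimental conditions."""
    df = pd.read_csv(path)
    required = {
        "well", "measured_nutrient", "measured_amount_ug",
        "base_nutrient", "base_amount_ug", "replicate",
    }
    if not required.issubset(df.columns):
        raise ValueError(f"layout CSV needs columns {sorted(required)}")
    if df["well"].duplicated().any():
        dupes = df.loc[df["well"].duplicated(), "well"].tolist()
        raise ValueError(f"duplicate well ids in layout: {dupes}")
    return {
        str(r.well): Condition(
            str(r.measured_nutrient), float(r.measured_amount_ug),
            str(r.base_nutrient), float(r.base_amount_ug), int(r.replicate),
        )
        for r in df.itertuples()
    }


def read_calibration_csv(path, **kwargs) -> CalibrationModel:
    """Read a two-column (raw_od, linear_od) calibration CSV."""
    df = pd.read_csv(path)
    if not {"raw_od", "linear_od"}.issubset(df.columns):
        raise ValueError("calibration CSV needs columns raw_od, linear_od")
    df = df.sort_values("raw_od")
    return CalibrationModel(
        od_map=(tuple(df["raw_od"].astype(float)), tuple(df["linear_od"].astype(float))),
        **kwargs,
    )


def extract_endpoints(
    series: dict[str, WellTimeSeries],
    layout: dict[str, Condition],
    cal: CalibrationModel | None = None,
    window_after_max_h: float = 4.0,
) -> pd.DataFrame:
    """Per-well ΔB extraction: one row per well with its condition and ΔB (µg)."""
    cal = cal or CalibrationModel()
    rows = []
    for well_id in sorted(series):
        if well_id not in layout:
            raise ValueError(f"well {well_id!r} missing from layout")
        cond = layout[well_id]
        traj = od_to_biomass(series[well_id], cal)
        db = produced_biomass_from_curve(traj, window_after_max_h)
        rows.append(
            {
                "well": well_id,
                "measured_nutrient": cond.measured_nutrient_id,
                "measured_amount_ug": cond.measured_amount_ug,
                "base_nutrient": cond.base_nutrient_id,
                "base_amount_ug": cond.base_amount_ug,
                "replicate": cond.replicate_index,
                "delta_B_ug": db,
            }
        )
    return pd.DataFrame(rows)
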