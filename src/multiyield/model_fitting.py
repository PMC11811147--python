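"""Estimating mutual-effect coefficients from endpoint data.

Only *reduced* parameter combinations are identifiable from produced-biomass
data: dividing the two-degradable model by the baseline energetic cost
``g_X + g_an`` leaves

    ΔB = (Y1·N1 + Y2·N2 + delta·N1·N2) / (1 + alpha1·N1 + alpha2·N2)

with Y_i the single-nutrient yields, ``delta = Δm_CAT/(g_X + g_an)`` the
reduced catabolic interaction, and ``alpha_i = g_an·m_an_i/(g_X + g_an)``
the reduced anabolic coefficients.  The raw catabolic coefficients
(m_cat_1, m_cat_2) enter ΔB only through Δm_CAT and are deliberately not
exposed as separate estimates.

The precursor model is reduced analogously by its baseline cost
``G_A0 = g_X + g_an_excl + g_bsyn``: the fitted vector is the base yield
``y = g_cat/G_A0``, the biosynthesis share ``b = g_bsyn/G_A0`` (the gain per
unit of externally covered precursor requirement), the dimensionless
catabolic coupling ``m_cat``, the biosynthesis coupling ``m_bsyn`` (per µg),
and optional reduced anabolic couplings.

Fits use trust-region nonlinear least squares with a seeded multistart;
standard errors come from the Gauss-Newton covariance s²·(JᵀJ)⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core_model import (
    EnergyParams,
    ModelValidityError,
    PrecursorEffects,
    PrecursorSpec,
    TwoDegradableEffects,
    produced_biomass_precursor,
    produced_biomass_two_degradable,
)

__all__ = [
    "TwoDegradableFitResult",
    "PrecursorFitResult",
    "EffectSign",
    "EffectClassification",
    "RegimeLabel",
    "RegimeMap",
    "IdentifiabilityError",
    "fit_two_degradable_effects",
    "fit_precursor_effects",
    "classify_mutual_effect",
    "map_solution_space",
    "reduced_two_degradable_delta_b",
    "reduced_precursor_delta_b",
]


class IdentifiabilityError(ValueError):
    """The experimental design cannot separate the requested parameters."""


# ---------------------------------------------------------------------------
# reduced forward models


def reduced_two_degradable_delta_b(
    theta: np.ndarray, n1: np.ndarray, n2: np.ndarray
) -> np.ndarray:
    """ΔB of the reduced two-degradable model; theta = (Y1, Y2, delta, a1, a2)."""
    y1, y2, delta, a1, a2 = theta
    denom = 1.0 + a1 * n1 + a2 * n2
    if np.any(denom <= 0):
        raise ModelValidityError("reduced anabolic denominator <= 0 on design")
    return (y1 * n1 + y2 * n2 + delta * n1 * n2) / denom


def _reduced_precursor_params(
    theta: np.ndarray,
) -> tuple[EnergyParams, PrecursorEffects]:
    """Build magnitude-convention parameters realising a reduced vector.

    theta = (y, b, m_cat, m_bsyn, r_anN, r_anM) with baseline cost scaled to
    1: g_cat = y, g_bsyn = b, and the remaining cost split evenly between
    g_X and g_an_excl so the reduced anabolic couplings r_anN = g_an_excl·
    m_an_N and r_anM = g_an_excl·m_an_M can always be realised.
    """
    y, b, m_cat, m_bsyn, r_an_n, r_an_m = theta
    if not 0 < y:
        raise ModelValidityError(f"base yield must be > 0, got {y}")
    if not 0 <= b < 1:
        raise ModelValidityError(f"biosynthesis share must be in [0, 1), got {b}")
    e0 = (1.0 - b) / 2.0
    params = EnergyParams(
        g_X=(1.0 - b) / 2.0,
        g_cat={"N": y},
        g_an=e0 + b,
        g_an_excl=e0,
        g_bsyn=b,
    )
    effects = PrecursorEffects(
        m_cat=m_cat,
        m_an_N=r_an_n / e0,
        m_an_M=r_an_m / e0,
        m_bsyn=m_bsyn,
    )
    return params, effects


def reduced_precursor_delta_b(
    theta: np.ndarray,
    n: np.ndarray,
    m: np.ndarray,
    spec: PrecursorSpec,
) -> np.ndarray:
    """ΔB of the reduced precursor model at each (N, M) design point."""
    params, effects = _reduced_precursor_params(theta)
    out = np.empty(len(n), dtype=float)
    for i, (ni, mi) in enumerate(zip(n, m)):
        out[i] = produced_biomass_precursor(
            params, effects, spec, float(ni), float(mi)
        ).delta_B
    return out


# ---------------------------------------------------------------------------
# fit results


@dataclass(frozen=True)
class TwoDegradableFitResult:
    Y1: float
    Y2: float
    delta: float
    alpha1: float
    alpha2: float
    ses: dict[str, float]
    covariance: np.ndarray | None
    residual_sse: float
    n_points: int
    alphas_fitted: bool

    @property
    def estimates(self) -> dict[str, float]:
        return {
            "Y1": self.Y1, "Y2": self.Y2, "delta": self.delta,
            "alpha1": self.alpha1, "alpha2": self.alpha2,
        }


@dataclass(frozen=True)
class PrecursorFitResult:
    y_base: float
    b_bsyn_gain: float
    m_cat: float
    m_bsyn: float
    r_an_N: float
    r_an_M: float
    ses: dict[str, float]
    covariance: np.ndarray | None
    residual_sse: float
    n_points: int
    free_names: tuple[str, ...]

    @property
    def estimates(self) -> dict[str, float]:
        return {
            "y_base": self.y_base, "b_bsyn_gain": self.b_bsyn_gain,
            "m_cat": self.m_cat, "m_bsyn": self.m_bsyn,
            "r_an_N": self.r_an_N, "r_an_M": self.r_an_M,
        }

    def biosynthesis_gain_at(self, base_amount: float) -> float:
        """Effective biosynthesis gain b·(1 + m_bsyn·N) at a base amount.

        ``b_bsyn_gain`` and ``m_bsyn`` individually are an intercept/slope
        pair evaluated far from N = 0, so they trade off strongly against
        each other in noisy fits; their combination at a base amount inside
        the design is the precisely identifiable quantity.
        """
        return self.b_bsyn_gain * (1.0 + self.m_bsyn * base_amount)


def _multistart_least_squares(
    residual, x0: np.ndarray, n_starts: int, seed: int,
    lower: np.ndarray, upper: np.ndarray,
):
    """Seeded multistart trust-region least squares; best SSE wins."""
    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(n_starts - 1):
        # +/-50% log-uniform perturbation of nonzero entries, additive
        # jitter for entries at zero
        factor = np.exp(rng.uniform(np.log(0.5), np.log(1.5), size=x0.size))
        jitter = rng.uniform(-0.01, 0.01, size=x0.size)
        cand = np.where(np.abs(x0) > 1e-12, x0 * factor, jitter)
        starts.append(np.clip(cand, lower + 1e-12, upper - 1e-12))
    best = None
    failures = []
    for s in starts:
        try:
            res = least_squares(residual, s, bounds=(lower, upper), method="trf")
        except (ModelValidityError, ValueError) as exc:
            failures.append(str(exc))
            continue
        if not res.success:
            failures.append(res.message)
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(
            "nonlinear least squares failed on every start: "
            + "; ".join(failures[:3])
        )
    return best


def _gauss_newton_cov(res, n_obs: int) -> np.ndarray | None:
    """Covariance of the estimates from the final Jacobian."""
    n_par = res.x.size
    dof = n_obs - n_par
    if dof <= 0:
        return None
    jtj = res.jac.T @ res.jac
    try:
        inv = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        try:
            inv = np.linalg.pinv(jtj)
        except np.linalg.LinAlgError:
            return None
    s2 = 2.0 * res.cost / dof  # res.cost = 0.5 * SSE
    return s2 * inv


def fit_two_degradable_effects(
    table: pd.DataFrame,
    n_starts: int = 5,
    seed: int = 0,
    fit_alphas: bool = True,
) -> TwoDegradableFitResult:
    """Fit the reduced two-degradable mutual-effect model to endpoint data.

    ``table`` needs columns ``measured_amount_ug`` (N1), ``base_amount_ug``
    (N2) and ``delta_B_mean_ug``.  The design must span at least two
    distinct values of each amount; with a single base amount the
    interaction ``delta`` is confounded with the yields and the anabolic
    coefficients are not identifiable at all.
    """
    n1 = table["measured_amount_ug"].to_numpy(float)
    n2 = table["base_amount_ug"].to_numpy(float)
    db = table["delta_B_mean_ug"].to_numpy(float)
    if len(table) < 8:
        raise ValueError(f"need >= 8 endpoint rows, have {len(table)}")
    if np.unique(n1).size < 2 or np.unique(n2).size < 2:
        raise IdentifiabilityError(
            "design must span >= 2 distinct values of both the measured and "
            "the base amount; with a single base amount the interaction is "
            "confounded with the single-nutrient yields"
        )

    # OLS-style initialisation: yields from marginal slopes, no interaction
    def marginal_slope(x, other, y):
        sel = other == other.min()
        if np.unique(x[sel]).size >= 2:
            return max(np.polyfit(x[sel], y[sel], 1)[0], 1e-6)
        return max(np.sum(x * y) / max(np.sum(x * x), 1e-12), 1e-6)

    y1_0 = marginal_slope(n1, n2, db)
    y2_0 = marginal_slope(n2, n1, db)

    scale_n = max(n1.max(), n2.max(), 1.0)
    if fit_alphas:
        x0 = np.array([y1_0, y2_0, 0.0, 0.0, 0.0])
        lower = np.array([1e-9, 1e-9, -np.inf, -0.9 / scale_n, -0.9 / scale_n])
        upper = np.array([np.inf, np.inf, np.inf, np.inf, np.inf])
        names = ["Y1", "Y2", "delta", "alpha1", "alpha2"]

        def residual(theta):
            return reduced_two_degradable_delta_b(theta, n1, n2) - db
    else:
        x0 = np.array([y1_0, y2_0, 0.0])
        lower = np.array([1e-9, 1e-9, -np.inf])
        upper = np.array([np.inf, np.inf, np.inf])
        names = ["Y1", "Y2", "delta"]

        def residual(theta):
            full = np.array([theta[0], theta[1], theta[2], 0.0, 0.0])
            return reduced_two_degradable_delta_b(full, n1, n2) - db

    res = _multistart_least_squares(residual, x0, n_starts, seed, lower, upper)
    cov = _gauss_newton_cov(res, db.size)
    ses = {
        nm: (float(np.sqrt(max(cov[i, i], 0.0))) if cov is not None else float("nan"))
        for i, nm in enumerate(names)
    }
    vals = dict(zip(names, res.x))
    return TwoDegradableFitResult(
        Y1=float(vals["Y1"]), Y2=float(vals["Y2"]), delta=float(vals["delta"]),
        alpha1=float(vals.get("alpha1", 0.0)), alpha2=float(vals.get("alpha2", 0.0)),
        ses=ses, covariance=cov, residual_sse=float(2.0 * res.cost),
        n_points=int(db.size), alphas_fitted=fit_alphas,
    )


_PRECURSOR_NAMES = ("y_base", "b_bsyn_gain", "m_cat", "m_bsyn", "r_an_N", "r_an_M")


def fit_precursor_effects(
    table: pd.DataFrame,
    spec: PrecursorSpec,
    free: Sequence[str] = ("y_base", "b_bsyn_gain", "m_cat", "m_bsyn"),
    n_starts: int = 5,
    seed: int = 0,
    weighting: str = "relative",
) -> PrecursorFitResult:
    """Fit the reduced precursor model to (N, M, ΔB) endpoint data.

    ``table`` needs columns ``measured_amount_ug`` (precursor amount M),
    ``base_amount_ug`` (degradable nutrient N) and ``delta_B_mean_ug``.
    ``free`` selects which reduced parameters are estimated; the anabolic
    couplings default to fixed zero, which matches designs that titrate the
    precursor at a few base amounts.  ``weighting="relative"`` (default)
    minimises relative residuals, matching the multiplicative error
    structure of plate-reader endpoints; ``"absolute"`` is unweighted.
    """
    m = table["measured_amount_ug"].to_numpy(float)
    n = table["base_amount_ug"].to_numpy(float)
    db = table["delta_B_mean_ug"].to_numpy(float)
    if len(table) < 10:
        raise ValueError(f"need >= 10 endpoint rows, have {len(table)}")
    if np.unique(n).size < 2:
        raise IdentifiabilityError(
            "design must span >= 2 distinct base-nutrient amounts"
        )
    unknown = set(free) - set(_PRECURSOR_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter names: {sorted(unknown)}")
    free = tuple(nm for nm in _PRECURSOR_NAMES if nm in free)

    # initial base yield from the M = 0 (or smallest-M) endpoints
    sel = m == m.min()
    y0 = float(np.sum(n[sel] * db[sel]) / max(np.sum(n[sel] ** 2), 1e-12))
    y0 = max(y0, 1e-6)
    defaults = {
        "y_base": y0, "b_bsyn_gain": 0.1, "m_cat": 0.0,
        "m_bsyn": 0.0, "r_an_N": 0.0, "r_an_M": 0.0,
    }
    bounds = {
        "y_base": (1e-9, np.inf),
        "b_bsyn_gain": (0.0, 0.95),
        "m_cat": (-0.95, np.inf),
        "m_bsyn": (-np.inf, np.inf),
        "r_an_N": (-np.inf, np.inf),
        "r_an_M": (-np.inf, np.inf),
    }
    x0 = np.array([defaults[nm] for nm in free])
    lower = np.array([bounds[nm][0] for nm in free])
    upper = np.array([bounds[nm][1] for nm in free])

    # parameters not being fitted are pinned: y_base at its data-driven
    # initial value, every coupling at zero
    fixed = {"y_base": y0, "b_bsyn_gain": 0.0, "m_cat": 0.0,
             "m_bsyn": 0.0, "r_an_N": 0.0, "r_an_M": 0.0}

    def expand(theta):
        full = dict(fixed)
        for nm, v in zip(free, theta):
            full[nm] = v
        return np.array([full[nm] for nm in _PRECURSOR_NAMES])

    if weighting == "relative":
        wts = 1.0 / np.maximum(np.abs(db), 0.05 * np.abs(db).max())
    elif weighting == "absolute":
        wts = np.ones_like(db)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    def residual(theta):
        return (reduced_precursor_delta_b(expand(theta), n, m, spec) - db) * wts

    res = _multistart_least_squares(residual, x0, n_starts, seed, lower, upper)
    cov = _gauss_newton_cov(res, db.size)
    ses_free = {
        nm: (float(np.sqrt(max(cov[i, i], 0.0))) if cov is not None else float("nan"))
        for i, nm in enumerate(free)
    }
    full = expand(res.x)
    vals = dict(zip(_PRECURSOR_NAMES, full))
    ses = {nm: ses_free.get(nm, 0.0) for nm in _PRECURSOR_NAMES}
    return PrecursorFitResult(
        y_base=float(vals["y_base"]), b_bsyn_gain=float(vals["b_bsyn_gain"]),
        m_cat=float(vals["m_cat"]), m_bsyn=float(vals["m_bsyn"]),
        r_an_N=float(vals["r_an_N"]), r_an_M=float(vals["r_an_M"]),
        ses=ses, covariance=cov, residual_sse=float(2.0 * res.cost),
        n_points=int(db.size), free_names=free,
    )


# ---------------------------------------------------------------------------
# classification


class EffectSign(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NONE = "none"


@dataclass(frozen=True)
class EffectClassification:
    catabolic: EffectSign
    anabolic: EffectSign
    biosynthesis: EffectSign
    confidence_available: bool
    details: dict[str, tuple[float, float]] = field(default_factory=dict)


def _sign_of(estimate: float, se: float, n_se: float = 2.0) -> EffectSign:
    if not math.isfinite(se) or se <= 0:
        return EffectSign.NONE
    if estimate > n_se * se:
        return EffectSign.POSITIVE
    if estimate < -n_se * se:
        return EffectSign.NEGATIVE
    return EffectSign.NONE


def classify_mutual_effect(
    fit: TwoDegradableFitResult | PrecursorFitResult, n_se: float = 2.0
) -> EffectClassification:
    """Qualitative effect calls: a coefficient counts only beyond ``n_se`` SEs.

    For the two-degradable fit the catabolic call is on the reduced
    interaction ``delta`` and the anabolic call on the alphas; for the
    precursor fit the catabolic call is on ``m_cat`` and the biosynthesis
    call on ``m_bsyn``.
    """
    conf = fit.covariance is not None
    if isinstance(fit, TwoDegradableFitResult):
        details = {
            "delta": (fit.delta, fit.ses.get("delta", float("nan"))),
            "alpha1": (fit.alpha1, fit.ses.get("alpha1", float("nan"))),
            "alpha2": (fit.alpha2, fit.ses.get("alpha2", float("nan"))),
        }
        cat = _sign_of(*details["delta"], n_se) if conf else EffectSign.NONE
        an_signs = {
            _sign_of(*details["alpha1"], n_se),
            _sign_of(*details["alpha2"], n_se),
        } if (conf and fit.alphas_fitted) else {EffectSign.NONE}
        # anabolic cost inflation (positive alpha) DEPRESSES yield
        if EffectSign.POSITIVE in an_signs:
            an = EffectSign.POSITIVE
        elif EffectSign.NEGATIVE in an_signs:
            an = EffectSign.NEGATIVE
        else:
            an = EffectSign.NONE
        return EffectClassification(
            catabolic=cat, anabolic=an, biosynthesis=EffectSign.NONE,
            confidence_available=conf, details=details,
        )
    details = {
        "m_cat": (fit.m_cat, fit.ses.get("m_cat", float("nan"))),
        "m_bsyn": (fit.m_bsyn, fit.ses.get("m_bsyn", float("nan"))),
        "r_an_N": (fit.r_an_N, fit.ses.get("r_an_N", float("nan"))),
    }
    return EffectClassification(
        catabolic=_sign_of(*details["m_cat"], n_se) if conf else EffectSign.NONE,
        anabolic=_sign_of(*details["r_an_N"], n_se) if conf else EffectSign.NONE,
        biosynthesis=_sign_of(*details["m_bsyn"], n_se) if conf else EffectSign.NONE,
        confidence_available=conf, details=details,
    )


# ---------------------------------------------------------------------------
# solution-space mapping


class RegimeLabel(str, Enum):
    ADDITIVE = "additive"
    YIELD_INCREASE = "yield_increase"
    YIELD_DECREASE = "yield_decrease"
    NON_MONOTONE = "non_monotone"
    INVALID = "invalid"


@dataclass(frozen=True)
class RegimeMap:
    """Qualitative dose-response regimes over a grid of coefficient settings."""

    entries: pd.DataFrame  # one row per grid cell with coefficients + label

    def label_of(self, **coeffs) -> RegimeLabel:
        df = self.entries
        for k, v in coeffs.items():
            df = df[np.isclose(df[k].astype(float), v)]
        if len(df) != 1:
            raise KeyError(f"coefficients {coeffs} match {len(df)} cells")
        return RegimeLabel(df["regime"].iloc[0])


def _classify_curve(
    sweep: np.ndarray, db: np.ndarray, db_ref: np.ndarray,
    atol: float = 1e-9, tail_frac: float = 0.2,
) -> RegimeLabel:
    """Label one ΔB(measured amount) curve against the zero-coefficient one.

    Points where the model had no solution are NaN (a fold gap); the curve
    is non-monotone when the finite part strictly decreases somewhere and
    strictly increases somewhere later (or vice versa), which also covers a
    dip that spans a gap.
    """
    finite = np.isfinite(db)
    if finite.sum() < 3:
        return RegimeLabel.INVALID
    xs, ys = sweep[finite], db[finite]
    if np.allclose(db[finite], db_ref[finite], rtol=0.0, atol=atol):
        return RegimeLabel.ADDITIVE
    d = np.diff(ys)
    rel = atol * max(1.0, float(np.nanmax(np.abs(ys))))
    decreases = np.where(d < -rel)[0]
    increases = np.where(d > rel)[0]
    if decreases.size and increases.size:
        return RegimeLabel.NON_MONOTONE
    # terminal slope over the last 20% of the sweep vs the additive curve
    k = max(2, int(math.ceil(tail_frac * xs.size)))
    slope = np.polyfit(xs[-k:], ys[-k:], 1)[0]
    ref_xs, ref_ys = sweep[finite], db_ref[finite]
    slope_ref = np.polyfit(ref_xs[-k:], ref_ys[-k:], 1)[0]
    if slope > slope_ref + atol:
        return RegimeLabel.YIELD_INCREASE
    if slope < slope_ref - atol:
        return RegimeLabel.YIELD_DECREASE
    return RegimeLabel.ADDITIVE


def map_solution_space(
    params: EnergyParams,
    model: str,
    coefficient_grid: Sequence[dict[str, float]],
    measured_amounts: np.ndarray,
    base_amount: float,
    spec: PrecursorSpec | None = None,
    nutrient_ids: tuple[str, str] = ("N1", "N2"),
    closure: str = "supply_limited",
) -> RegimeMap:
    """Sweep the measured amount at fixed base amount for each coefficient cell.

    ``model`` is ``"two_degradable"`` (measured = N1, base = N2) or
    ``"precursor"`` (measured = precursor M, base = degradable N).  Each cell
    is labelled additive / yield_increase / yield_decrease / non_monotone by
    comparing its ΔB curve with the zero-coefficient reference; invalid
    cells (validity violation across the sweep) are labelled, not skipped.

    Precursor sweeps default to the supply-limited closure: the quadratic's
    solution set is explored as such, including the fold gap and the
    recovering branch beyond it, which is where the characteristic
    dip-then-linear-rise dose response lives.  Points inside a fold gap are
    treated as missing, and a curve that strictly decreases before the gap
    and strictly increases after it is non-monotone.  Under the capped
    closure ΔB(M) is monotone up to a flat saturated tail, so only the
    supply-limited exploration exhibits that regime.
    """
    sweep = np.asarray(measured_amounts, dtype=float)
    if sweep.size < 5:
        raise ValueError("need >= 5 sweep points")

    def curve(coeffs: dict[str, float]) -> np.ndarray:
        out = np.full(sweep.size, np.nan)
        if model == "two_degradable":
            eff = TwoDegradableEffects(**coeffs)
            for i, a in enumerate(sweep):
                out[i] = produced_biomass_two_degradable(
                    params, eff, a, base_amount, nutrient_ids
                )
        elif model == "precursor":
            if spec is None:
                raise ValueError("precursor model needs a PrecursorSpec")
            eff = PrecursorEffects(**coeffs)
            for i, a in enumerate(sweep):
                try:
                    out[i] = produced_biomass_precursor(
                        params, eff, spec, base_amount, a, nutrient_ids[0],
                        closure=closure,
                    ).delta_B
                except ModelValidityError:
                    out[i] = np.nan  # fold gap: no solution at this dose
        else:
            raise ValueError(f"unknown model {model!r}")
        return out

    db_ref = curve({})
    rows = []
    for coeffs in coefficient_grid:
        try:
            db = curve(coeffs)
            label = _classify_curve(sweep, db, db_ref)
        except ModelValidityError:
            label = RegimeLabel.INVALID
        rows.append({**coeffs, "regime": label.value})
    return RegimeMap(entries=pd.DataFrame(rows))
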