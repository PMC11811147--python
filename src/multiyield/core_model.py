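"""Black-box thermodynamic model of overall biomass yield on multiple nutrients.

The model treats batch growth as a small set of lumped reactions: catabolic
reactions that release Gibbs free energy by degrading nutrients, and anabolic
reactions that consume it to build biomass.  Over a full batch culture (all
nutrients and secreted byproducts ultimately consumed) the energy balance per
unit biomass fixes the *overall biomass yield* — produced dry weight per unit
of initial nutrient.

Conventions
-----------
All Gibbs dissipation terms are stored as non-negative **magnitudes**
(kJ per g).  The balance reads

    catabolic energy supply  =  g_X + anabolic costs   (per g biomass)

so the single-nutrient yield is ``Y = g_cat / (g_X + g_an)`` with every
parameter positive.  Amounts are in µg, biomass in µg dry weight, per-amount
interaction coefficients in 1/µg.

Two extensions couple nutrients phenomenologically:

* two degradable nutrients — linear "mutual effect" factors on each
  catabolic term and on the anabolic term, giving a rational ΔB(N1, N2)
  with a bilinear numerator;
* a degradable nutrient plus a non-degradable biomass precursor — the
  anabolic reaction is split into precursor biosynthesis and the rest; the
  precursor-utilization fraction ``M_utl`` (supplied / required, capped at 1)
  relieves the biosynthesis cost, and the self-consistency ΔB ↔ M_utl makes
  the produced biomass the root of a quadratic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

__all__ = [
    "EnergyParams",
    "TwoDegradableEffects",
    "PrecursorEffects",
    "PrecursorSpec",
    "BiomassSolution",
    "Branch",
    "RootUsed",
    "ModelValidityError",
    "overall_yield_single",
    "produced_biomass_linear",
    "produced_biomass_additive",
    "produced_biomass_two_degradable",
    "m_utl_value",
    "produced_biomass_precursor",
    "solve_energy_balance_numeric",
]


class ModelValidityError(ValueError):
    """The requested inputs leave the model's validity region.

    Raised instead of silently clamping: a non-positive effective anabolic
    denominator, a negative discriminant, or the absence of a positive root
    all mean the phenomenological coefficients are inconsistent with growth
    at these doses.
    """


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


def _require_nonneg(name: str, value: float) -> float:
    value = _require_finite(name, value)
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value}")
    return value


@dataclass(frozen=True)
class EnergyParams:
    """Magnitudes of the Gibbs dissipation terms of the lumped growth reactions.

    Parameters
    ----------
    g_X
        Overall dissipation per unit biomass formed, kJ/g biomass.
    g_cat
        Catabolic energy released per unit nutrient degraded, kJ/g nutrient,
        one entry per degradable nutrient id.
    g_an
        Full anabolic cost per unit biomass, kJ/g biomass.
    g_an_excl
        Anabolic cost excluding precursor biosynthesis, kJ/g biomass.  Only
        meaningful for the precursor model; must not exceed ``g_an``.
    g_bsyn
        Cost of synthesising the precursor de novo, kJ/g biomass.

    Notes
    -----
    In the signed notation common for black-box energy balances, the signed
    dissipation of the growth reaction ΔG_X corresponds to ``-g_X``, the
    catabolic ΔG_cat to ``-g_cat`` (energy releasing), and the anabolic
    ΔG_an, ΔG_bsyn to ``+g_an``, ``+g_bsyn`` (energy consuming), so the
    signed yield expression ΔG_cat/(ΔG_X − ΔG_an) becomes
    ``g_cat / (g_X + g_an)``.
    """

    g_X: float
    g_cat: Mapping[str, float]
    g_an: float
    g_an_excl: float = 0.0
    g_bsyn: float = 0.0

    def __post_init__(self) -> None:
        gx = _require_nonneg("g_X", self.g_X)
        if gx == 0:
            raise ValueError("g_X must be > 0")
        gcat = {str(k): _require_finite(f"g_cat[{k!r}]", v) for k, v in self.g_cat.items()}
        for k, v in gcat.items():
            if v <= 0:
                raise ValueError(f"g_cat[{k!r}] must be > 0, got {v}")
        _require_nonneg("g_an", self.g_an)
        _require_nonneg("g_an_excl", self.g_an_excl)
        _require_nonneg("g_bsyn", self.g_bsyn)
        if self.g_an_excl > self.g_an:
            raise ValueError(
                f"g_an_excl ({self.g_an_excl}) cannot exceed g_an ({self.g_an})"
            )
        object.__setattr__(self, "g_X", gx)
        object.__setattr__(self, "g_cat", gcat)

    def catabolic_energy(self, nutrient_id: str) -> float:
        try:
            return self.g_cat[nutrient_id]
        except KeyError:
            raise KeyError(
                f"unknown nutrient id {nutrient_id!r}; known: {sorted(self.g_cat)}"
            ) from None


@dataclass(frozen=True)
class TwoDegradableEffects:
    """Mutual-effect coefficients for two degradable nutrients (per µg).

    ``m_cat_1`` scales nutrient 1's catabolic efficiency with the dose of
    nutrient 2 (f_cat1 = 1 + m_cat_1·N2) and vice versa; ``m_an_1``/``m_an_2``
    inflate or deflate the anabolic cost (f_an = 1 + m_an_1·N1 + m_an_2·N2).
    """

    m_cat_1: float = 0.0
    m_cat_2: float = 0.0
    m_an_1: float = 0.0
    m_an_2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("m_cat_1", "m_cat_2", "m_an_1", "m_an_2"):
            _require_finite(name, getattr(self, name))

    def f_an(self, n1: float, n2: float) -> float:
        return 1.0 + self.m_an_1 * n1 + self.m_an_2 * n2


@dataclass(frozen=True)
class PrecursorEffects:
    """Mutual-effect coefficients for a degradable nutrient + precursor pair.

    ``m_cat`` (dimensionless) couples precursor utilization to catabolism:
    f_cat = 1 + m_cat·M_utl.  ``m_an_N`` (per µg) and ``m_an_M``
    (dimensionless) act on the anabolic term,
    f_an = 1 + m_an_N·N + m_an_M·M_utl, and ``m_bsyn`` (per µg) on the
    biosynthesis term, f_bsyn = 1 + m_bsyn·N.
    """

    m_cat: float = 0.0
    m_an_N: float = 0.0
    m_an_M: float = 0.0
    m_bsyn: float = 0.0

    def __post_init__(self) -> None:
        for name in ("m_cat", "m_an_N", "m_an_M", "m_bsyn"):
            _require_finite(name, getattr(self, name))
        # f_cat must stay positive over the whole utilization range
        if 1.0 + min(0.0, self.m_cat) <= 0.0:
            raise ValueError(
                f"m_cat={self.m_cat} makes f_cat non-positive at full utilization"
            )


@dataclass(frozen=True)
class PrecursorSpec:
    """Stoichiometric requirement for the non-degradable precursor.

    ``q_req`` is the precursor mass needed per unit of biomass dry weight
    (µg/µg).  For a methionine-like amino acid in enteric bacteria this is
    about 0.02 (≈1.7 µg methionine per ~80 µg dry weight).
    """

    q_req: float = 0.02

    def __post_init__(self) -> None:
        q = _require_finite("q_req", self.q_req)
        if q <= 0:
            raise ValueError(f"q_req must be > 0, got {q}")


class Branch(str, Enum):
    UNSATURATED = "unsaturated"
    SATURATED = "saturated"


class RootUsed(str, Enum):
    LARGER = "larger"
    ONLY_POSITIVE = "only_positive"
    LINEAR = "linear"


@dataclass(frozen=True)
class BiomassSolution:
    """Produced biomass from the precursor model, with solver diagnostics."""

    delta_B: float
    m_utl: float
    branch: Branch
    discriminant: float = float("nan")
    root_used: RootUsed = RootUsed.LARGER

    def __post_init__(self) -> None:
        if self.delta_B < 0:
            raise ValueError(f"delta_B must be >= 0, got {self.delta_B}")
        if not (-1e-12 <= self.m_utl <= 1 + 1e-12):
            raise ValueError(f"m_utl must lie in [0, 1], got {self.m_utl}")
        object.__setattr__(self, "m_utl", min(1.0, max(0.0, self.m_utl)))


# ---------------------------------------------------------------------------
# single-nutrient and additive models


def overall_yield_single(
    params: EnergyParams,
    nutrient_id: str,
    m_utl: float | None = None,
) -> float:
    """Overall biomass yield on one degradable nutrient, g biomass / g nutrient.

    Without a precursor (``m_utl`` omitted) the yield is
    ``g_cat / (g_X + g_an)``.  When the anabolic reaction is decomposed into
    precursor biosynthesis plus the rest, an externally supplied precursor
    covering a fraction ``m_utl`` of the requirement relieves that share of
    the biosynthesis cost:

        Y = g_cat / (g_X + g_an_excl + g_bsyn·(1 − m_utl))

    so the yield rises monotonically with precursor availability.
    """
    g_cat = params.catabolic_energy(nutrient_id)
    if m_utl is None:
        denom = params.g_X + params.g_an
    else:
        u = _require_finite("m_utl", m_utl)
        if not 0.0 <= u <= 1.0:
            raise ValueError(f"m_utl must lie in [0, 1], got {u}")
        denom = params.g_X + params.g_an_excl + params.g_bsyn * (1.0 - u)
    if denom <= 0:
        raise ModelValidityError(f"non-positive energetic denominator {denom}")
    return g_cat / denom


def produced_biomass_linear(yield_Y: float, amount_N: float) -> float:
    """ΔB = Y·N — produced biomass proportional to the initial amount."""
    y = _require_nonneg("yield_Y", yield_Y)
    n = _require_nonneg("amount_N", amount_N)
    return y * n


def produced_biomass_additive(params: EnergyParams, doses: Mapping[str, float]) -> float:
    """Produced biomass as the independent sum Σ Y_i·N_i over all nutrients."""
    if not doses:
        raise ValueError("dose map is empty")
    total = 0.0
    for nutrient_id, amount in doses.items():
        total += produced_biomass_linear(
            overall_yield_single(params, nutrient_id), amount
        )
    return total


# ---------------------------------------------------------------------------
# two degradable nutrients with mutual effects


def produced_biomass_two_degradable(
    params: EnergyParams,
    effects: TwoDegradableEffects,
    n1: float,
    n2: float,
    nutrient_ids: tuple[str, str] = ("N1", "N2"),
) -> float:
    """Produced biomass for two degradable nutrients with mutual effects.

    The energy balance with linear mutual-effect factors on both catabolic
    terms and on the anabolic term yields

        ΔB = (g_cat1·N1 + g_cat2·N2 + Δm_CAT·N1·N2)
             / (g_X + g_an·(1 + m_an_1·N1 + m_an_2·N2))

    with the bilinear coupling Δm_CAT = g_cat1·m_cat_1 + g_cat2·m_cat_2.
    With all coefficients zero this reduces exactly to the additive sum.
    """
    n1 = _require_nonneg("n1", n1)
    n2 = _require_nonneg("n2", n2)
    g1 = params.catabolic_energy(nutrient_ids[0])
    g2 = params.catabolic_energy(nutrient_ids[1])
    f_an = effects.f_an(n1, n2)
    denom = params.g_X + params.g_an * f_an
    if denom <= 0:
        raise ModelValidityError(
            f"anabolic denominator g_X + g_an*f_an = {denom} <= 0 "
            f"at N1={n1}, N2={n2} (f_an={f_an})"
        )
    dm_cat = g1 * effects.m_cat_1 + g2 * effects.m_cat_2
    numer = g1 * n1 + g2 * n2 + dm_cat * n1 * n2
    if numer < 0:
        raise ModelValidityError(
            f"negative catabolic supply {numer} at N1={n1}, N2={n2}"
        )
    return numer / denom


# ---------------------------------------------------------------------------
# degradable nutrient + non-degradable biomass precursor


def m_utl_value(m_avail: float, spec: PrecursorSpec, delta_B: float) -> float:
    """Fraction of the precursor requirement covered externally, capped at 1.

    ``M_utl = min(1, M / (q_req·ΔB))``.  At ΔB = 0 there is no requirement,
    so any supply covers it: the value is defined as 1 when M > 0 and 0 for
    M = 0.
    """
    m = _require_nonneg("m_avail", m_avail)
    db = _require_nonneg("delta_B", delta_B)
    if m == 0.0:
        return 0.0
    if db == 0.0:
        return 1.0
    return min(1.0, m / (spec.q_req * db))


def _precursor_GA(params: EnergyParams, effects: PrecursorEffects, n: float) -> float:
    """Effective per-biomass energetic cost G_A of the precursor model."""
    return (
        params.g_X
        + params.g_an_excl * (1.0 + effects.m_an_N * n)
        + params.g_bsyn * (1.0 + effects.m_bsyn * n)
    )


def produced_biomass_precursor(
    params: EnergyParams,
    effects: PrecursorEffects,
    spec: PrecursorSpec,
    n: float,
    m: float,
    nutrient_id: str = "N",
    closure: str = "cap",
) -> BiomassSolution:
    """Produced biomass on a degradable nutrient N plus precursor amount M.

    The self-consistency between the produced biomass and the precursor
    utilization fraction (M_utl depends on ΔB, which depends on M_utl) turns
    the energy balance into a quadratic in ΔB on the *unsaturated* branch
    (M_utl = M′/ΔB < 1, with M′ = M/q_req the biomass covered by the supply):

        G_A·ΔB² − ΔB·[N·g_cat − g_an_excl·m_an_M·M′
                      + g_bsyn·(1 + m_bsyn·N)·M′] − N·g_cat·m_cat·M′ = 0

    where G_A = g_X + g_an_excl·(1 + m_an_N·N) + g_bsyn·(1 + m_bsyn·N).
    The root continuous with the M → 0 limit (roots {0, N·g_cat/G_A}) is the
    larger one.  If the implied M_utl exceeds 1 the precursor is in excess
    and, under the default ``closure="cap"``, the saturated branch applies:
    M_utl = 1, the biosynthesis term vanishes, and ΔB is linear in N.

    ``closure="supply_limited"`` instead keeps M′ = M/q_req at every dose —
    the supplied precursor is treated as fully incorporated even past the
    point where it covers the requirement, so the utilization ratio is not
    capped at 1.  This is the closure under which the quadratic's solution
    set exhibits the qualitative dose-response regimes used for
    solution-space exploration (including a fold with a no-real-solution
    gap and a recovering branch beyond it); the capped closure, by
    contrast, is monotone in M up to a flat saturated tail.
    """
    if closure not in ("cap", "supply_limited"):
        raise ValueError(f"unknown closure {closure!r}")
    n = _require_nonneg("n", n)
    m = _require_nonneg("m", m)
    g_cat = params.catabolic_energy(nutrient_id)
    ga = _precursor_GA(params, effects, n)
    if ga <= 0:
        raise ModelValidityError(f"G_A = {ga} <= 0 at N={n}: model invalid")

    if n == 0.0:
        # no catabolic supply: the precursor alone cannot drive growth
        return BiomassSolution(
            delta_B=0.0, m_utl=m_utl_value(m, spec, 0.0),
            branch=Branch.SATURATED if m > 0 else Branch.UNSATURATED,
            discriminant=float("nan"), root_used=RootUsed.LINEAR,
        )
    if m == 0.0:
        db = n * g_cat / ga
        return BiomassSolution(
            delta_B=db, m_utl=0.0, branch=Branch.UNSATURATED,
            discriminant=(n * g_cat) ** 2, root_used=RootUsed.LARGER,
        )

    # -- unsaturated branch: M' = M/q_req fixed, M_utl = M'/dB
    m_prime = m / spec.q_req
    b_lin = (
        n * g_cat
        - params.g_an_excl * effects.m_an_M * m_prime
        + params.g_bsyn * (1.0 + effects.m_bsyn * n) * m_prime
    )
    c_const = n * g_cat * effects.m_cat * m_prime
    # ga*dB^2 - b_lin*dB - c_const = 0
    disc = b_lin * b_lin + 4.0 * ga * c_const
    if closure == "supply_limited":
        if disc < 0:
            raise ModelValidityError(
                f"negative discriminant {disc} at N={n}, M={m}: the "
                "supply-limited closure has no real solution here (fold gap)"
            )
        root = (b_lin + math.sqrt(disc)) / (2.0 * ga)
        if root <= 0:
            raise ModelValidityError(
                f"no positive root at N={n}, M={m} (larger root {root})"
            )
        implied_utl = m_prime / root
        return BiomassSolution(
            delta_B=root, m_utl=min(1.0, implied_utl),
            branch=Branch.UNSATURATED if implied_utl <= 1.0 else Branch.SATURATED,
            discriminant=disc, root_used=RootUsed.LARGER,
        )
    if disc >= 0:
        root = (b_lin + math.sqrt(disc)) / (2.0 * ga)
        if root > 0:
            implied_utl = m_prime / root
            if implied_utl <= 1.0:
                return BiomassSolution(
                    delta_B=root, m_utl=implied_utl, branch=Branch.UNSATURATED,
                    discriminant=disc, root_used=RootUsed.LARGER,
                )
    # fall through: the unsaturated solution either does not exist (negative
    # discriminant: the catabolic penalty of partial utilization admits no
    # self-consistent partial solution), has no positive root, or implies
    # M_utl > 1 (precursor in excess) -- try the saturated branch.

    # -- saturated branch: M_utl = 1, biosynthesis cost fully alleviated
    f_cat = 1.0 + effects.m_cat
    f_an = 1.0 + effects.m_an_N * n + effects.m_an_M
    denom = params.g_X + params.g_an_excl * f_an
    if denom <= 0:
        raise ModelValidityError(
            f"saturated-branch denominator {denom} <= 0 at N={n}"
        )
    supply = n * g_cat * f_cat
    if supply < 0:
        raise ModelValidityError(f"negative catabolic supply at N={n}, M={m}")
    db = supply / denom
    if m_prime < db * (1.0 - 1e-12):
        # saturated branch inconsistent too (supply below requirement):
        # the model has no self-consistent solution at these coefficients
        raise ModelValidityError(
            f"no real solution at N={n}, M={m}: unsaturated discriminant "
            f"{disc} and saturated branch implies M_utl < 1"
        )
    return BiomassSolution(
        delta_B=db, m_utl=1.0, branch=Branch.SATURATED,
        discriminant=disc if disc < 0 else float("nan"), root_used=RootUsed.LINEAR,
    )


def solve_energy_balance_numeric(
    params: EnergyParams,
    effects: PrecursorEffects,
    spec: PrecursorSpec,
    n: float,
    m: float,
    nutrient_id: str = "N",
    rtol: float = 1e-12,
    max_iter: int = 200,
) -> float:
    """Independent numeric solution of the precursor energy balance.

    Solves the implicit balance

        N·g_cat·f_cat(M_utl) = ΔB·[g_X + g_an_excl·f_an(N, M_utl)
                                    + g_bsyn·f_bsyn(N)·(1 − M_utl)]

    with M_utl = min(1, M/(q_req·ΔB)), by bisection on ΔB.  Deliberately
    avoids the closed-form quadratic so it can act as an oracle for it.
    """
    n = _require_nonneg("n", n)
    m = _require_nonneg("m", m)
    g_cat = params.catabolic_energy(nutrient_id)
    if _precursor_GA(params, effects, n) <= 0:
        raise ModelValidityError(f"G_A <= 0 at N={n}: model invalid")
    if n == 0.0:
        return 0.0

    def residual(db: float) -> float:
        utl = m_utl_value(m, spec, db)
        supply = n * g_cat * (1.0 + effects.m_cat * utl)
        cost = db * (
            params.g_X
            + params.g_an_excl * (1.0 + effects.m_an_N * n + effects.m_an_M * utl)
            + params.g_bsyn * (1.0 + effects.m_bsyn * n) * (1.0 - utl)
        )
        return supply - cost

    # residual is positive at db -> 0+ (supply bounded below away from 0)
    # and eventually negative once the linear cost dominates.  With a
    # negative catabolic coupling it can cross zero more than once; the
    # physically continuous solution (the M -> 0 limit) is the LARGEST root,
    # so scan a fine grid for the last +/- sign change and refine there.
    lo = 1e-12
    if residual(lo) <= 0:
        raise ModelValidityError(
            f"energy balance has no positive solution at N={n}, M={m}"
        )
    hi = max(1.0, 4.0 * n * g_cat / params.g_X, 4.0 * m / spec.q_req)
    it = 0
    while residual(hi) > 0:
        hi *= 2.0
        it += 1
        if it > 100:
            raise ModelValidityError(
                f"failed to bracket energy balance at N={n}, M={m}"
            )
    n_grid = 1024
    grid = [lo + (hi - lo) * k / n_grid for k in range(n_grid + 1)]
    signs = [residual(x) > 0 for x in grid]
    bracket = None
    for k in range(n_grid, 0, -1):
        if signs[k - 1] and not signs[k]:
            bracket = (grid[k - 1], grid[k])
            break
    if bracket is None:
        raise ModelValidityError(
            f"no sign change located on [{lo}, {hi}] at N={n}, M={m}"
        )
    lo, hi = bracket
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= rtol * hi:
            break
    else:
        raise ModelValidityError(
            f"bisection did not converge within {max_iter} iterations "
            f"at N={n}, M={m} (bracket [{lo}, {hi}])"
        )
    return 0.5 * (lo + hi)
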