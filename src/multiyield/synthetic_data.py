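"""Synthetic batch-culture data whose endpoints obey the black-box models.

Generates the three kinds of inputs the analysis pipeline consumes:

* endpoint tables — produced biomass ΔB at each (measured amount, base
  amount) condition, drawn from the additive, two-degradable or precursor
  model with multiplicative replicate noise;
* diauxic plate-reader time series — two exponential growth phases separated
  by a lag, constructed so each well's endpoint matches its model ΔB, then
  converted back to OD with the calibration model and sampled every 10 min
  like a microplate reader;
* acetate-assay datasets — (OD600, acetate concentration) points with a
  programmed secretion rate.

Every generator is deterministic under a fixed seed.  Noise is
multiplicative Gaussian (plate-reader error scales with signal), truncated
at −90% to preserve positivity.  The kinetic construction is deliberately
phenomenological — two exponentials and a plateau — because the black-box
models constrain only the endpoint, not the trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    EnergyParams,
    PrecursorEffects,
    PrecursorSpec,
    TwoDegradableEffects,
    produced_biomass_additive,
    produced_biomass_precursor,
    produced_biomass_two_degradable,
)
from .curve_processing import CalibrationModel, Condition, WellTimeSeries

__all__ = [
    "EndpointDesign",
    "KineticParams",
    "ModelSpec",
    "diauxic_phase_times",
    "generate_endpoint_table",
    "generate_diauxic_plate",
    "generate_acetate_dataset",
]


@dataclass(frozen=True)
class EndpointDesign:
    """Dose design of a titration experiment.

    Defaults emulate a microplate titration: the measured nutrient varied
    over 0–240 µg per well, the base nutrient fixed per series at 0–160 µg,
    biological triplicates, and ~2% multiplicative endpoint noise.
    """

    measured_amounts: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0, 160.0, 200.0, 240.0)
    base_amounts: tuple[float, ...] = (0.0, 40.0, 80.0, 160.0)
    n_reps: int = 3
    noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.measured_amounts + self.base_amounts):
            raise ValueError("amounts must be >= 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        object.__setattr__(self, "measured_amounts", tuple(float(a) for a in self.measured_amounts))
        object.__setattr__(self, "base_amounts", tuple(float(a) for a in self.base_amounts))

    def conditions(self) -> Iterator[tuple[float, float]]:
        for b in self.base_amounts:
            for a in self.measured_amounts:
                yield a, b


@dataclass(frozen=True)
class KineticParams:
    """Phenomenological diauxic kinetics used to dress endpoints as curves.

    Two exponential phases at ``mu1`` and ``mu2`` (1/h) separated by a
    ``lag2_h`` plateau; ``phase_split`` is the fraction of the total ΔB
    accrued in the first phase (1.0 = single-phase growth).  The inoculum
    ``b0_ug`` defaults to ~4 µg dry weight (OD600 ≈ 0.05 in a 200 µl well);
    sampling every 10 min like a plate reader.
    """

    mu1: float = 0.9
    mu2: float = 0.3
    lag2_h: float = 3.0
    phase_split: float = 0.7
    b0_ug: float = 4.0
    sample_interval_min: float = 10.0
    horizon_h: float = 24.0

    def __post_init__(self) -> None:
        if self.mu1 <= 0 or self.mu2 <= 0:
            raise ValueError("growth rates must be > 0")
        if not 0 < self.phase_split <= 1:
            raise ValueError("phase_split must be in (0, 1]")
        if self.b0_ug <= 0 or self.sample_interval_min <= 0 or self.horizon_h <= 0:
            raise ValueError("b0_ug, sample_interval_min, horizon_h must be > 0")
        if self.lag2_h < 0:
            raise ValueError("lag2_h must be >= 0")


@dataclass(frozen=True)
class ModelSpec:
    """Which endpoint model generates ΔB, with its coefficients.

    ``kind`` is ``"additive"``, ``"two_degradable"`` or ``"precursor"``.
    For the two-degradable model the measured amount is nutrient 1 and the
    base amount nutrient 2; for the precursor model the measured amount is
    the precursor M and the base amount the degradable nutrient N.
    """

    kind: str
    params: EnergyParams
    effects: TwoDegradableEffects | PrecursorEffects | None = None
    precursor_spec: PrecursorSpec | None = None
    nutrient_ids: tuple[str, str] = ("N1", "N2")

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "two_degradable", "precursor"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "two_degradable" and not isinstance(
            self.effects, (TwoDegradableEffects, type(None))
        ):
            raise TypeError("two_degradable model needs TwoDegradableEffects")
        if self.kind == "precursor":
            if not isinstance(self.effects, (PrecursorEffects, type(None))):
                raise TypeError("precursor model needs PrecursorEffects")
            if self.precursor_spec is None:
                raise ValueError("precursor model needs a PrecursorSpec (q_req)")

    def delta_b(self, measured_amount: float, base_amount: float) -> float:
        """Noise-free model ΔB at one condition."""
        if self.kind == "additive":
            doses = {self.nutrient_ids[0]: measured_amount,
                     self.nutrient_ids[1]: base_amount}
            doses = {k: v for k, v in doses.items() if v > 0} or {
                self.nutrient_ids[0]: 0.0
            }
            return produced_biomass_additive(self.params, doses)
        if self.kind == "two_degradable":
            eff = self.effects or TwoDegradableEffects()
            return produced_biomass_two_degradable(
                self.params, eff, measured_amount, base_amount, self.nutrient_ids
            )
        eff = self.effects or PrecursorEffects()
        assert self.precursor_spec is not None
        return produced_biomass_precursor(
            self.params, eff, self.precursor_spec,
            base_amount, measured_amount, self.nutrient_ids[0],
        ).delta_B


def _multiplicative_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """1 + Normal(0, cv), truncated below at 0.1 to keep signals positive."""
    if cv == 0:
        return np.ones(size)
    return np.maximum(1.0 + rng.normal(0.0, cv, size=size), 0.1)


def generate_endpoint_table(
    model: ModelSpec, design: EndpointDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-replicate endpoints and their replicate-averaged table.

    Returns ``(per_well, table)``: per-well rows in the same shape
    ``curve_processing.extract_endpoints`` produces, and the averaged
    endpoint table the fitting stages consume.
    """
    from .yield_pipeline import average_replicates

    rng = np.random.default_rng(design.seed)
    rows = []
    well = 0
    for measured, base in design.conditions():
        db_true = model.delta_b(measured, base)
        noise = _multiplicative_noise(rng, design.noise_cv, design.n_reps)
        for rep in range(design.n_reps):
            rows.append(
                {
                    "well": f"W{well:03d}",
                    "measured_nutrient": model.nutrient_ids[1 if model.kind == "precursor" else 0],
                    "measured_amount_ug": measured,
                    "base_nutrient": model.nutrient_ids[0 if model.kind == "precursor" else 1],
                    "base_amount_ug": base,
                    "replicate": rep,
                    "delta_B_ug": db_true * noise[rep],
                    "delta_B_true_ug": db_true,
                }
            )
            well += 1
    per_well = pd.DataFrame(rows)
    table = average_replicates(per_well)
    return per_well, table


def diauxic_phase_times(db_target: float, kin: KineticParams) -> tuple[float, float, float]:
    """(end of phase 1, start of phase 2, end of phase 2) in hours."""
    b0 = kin.b0_ug
    b1_end = b0 + kin.phase_split * db_target
    b2_end = b0 + db_target
    t1 = math.log(b1_end / b0) / kin.mu1 if db_target > 0 else 0.0
    if kin.phase_split >= 1.0 or db_target <= 0:
        return t1, t1, t1
    t2_start = t1 + kin.lag2_h
    t2_end = t2_start + math.log(b2_end / b1_end) / kin.mu2
    return t1, t2_start, t2_end


def _diauxic_biomass(t: np.ndarray, db_target: float, kin: KineticParams) -> np.ndarray:
    """Noise-free two-phase biomass trajectory hitting b0 + db_target."""
    b0 = kin.b0_ug
    b1_end = b0 + kin.phase_split * db_target
    b2_end = b0 + db_target
    t1, t2_start, t2_end = diauxic_phase_times(db_target, kin)
    if t2_end + 5.0 > kin.horizon_h:
        raise ValueError(
            f"horizon {kin.horizon_h} h too short: growth ends at "
            f"{t2_end:.2f} h and the endpoint window needs ~5 h more"
        )
    b = np.empty_like(t)
    for i, ti in enumerate(t):
        if ti < t1:
            b[i] = b0 * math.exp(kin.mu1 * ti)
        elif ti < t2_start:
            b[i] = b1_end
        elif ti < t2_end:
            b[i] = b1_end * math.exp(kin.mu2 * (ti - t2_start))
        else:
            b[i] = b2_end
    return b


def generate_diauxic_plate(
    model: ModelSpec,
    design: EndpointDesign,
    kin: KineticParams | None = None,
    cal: CalibrationModel | None = None,
    od_noise_cv: float = 0.0,
) -> tuple[dict[str, WellTimeSeries], dict[str, Condition]]:
    """Simulate a full plate of diauxic growth curves.

    Each well's endpoint target ΔB comes from ``generate_endpoint_table``
    (so replicate noise acts on the endpoint); the trajectory is the
    two-exponential construction, converted to OD through the inverse
    calibration and sampled on the plate reader's grid.  ``od_noise_cv``
    adds optional multiplicative observation noise per sample.
    """
    kin = kin or KineticParams()
    cal = cal or CalibrationModel()
    per_well, _ = generate_endpoint_table(model, design)
    rng = np.random.default_rng(design.seed + 1)

    n_samples = int(kin.horizon_h * 60.0 / kin.sample_interval_min) + 1
    t = np.arange(n_samples) * kin.sample_interval_min / 60.0

    series: dict[str, WellTimeSeries] = {}
    layout: dict[str, Condition] = {}
    for row in per_well.itertuples():
        b = _diauxic_biomass(t, float(row.delta_B_ug), kin)
        od = cal.ug_to_od(b)
        od = od * _multiplicative_noise(rng, od_noise_cv, od.size)
        cond = Condition(
            measured_nutrient_id=str(row.measured_nutrient),
            measured_amount_ug=float(row.measured_amount_ug),
            base_nutrient_id=str(row.base_nutrient),
            base_amount_ug=float(row.base_amount_ug),
            replicate_index=int(row.replicate),
        )
        wid = str(row.well)
        series[wid] = WellTimeSeries(well_id=wid, times=t, od_raw=od, condition=cond)
        layout[wid] = cond
    return series, layout


def generate_acetate_dataset(
    true_rate: float,
    mu: float,
    od_grid: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.8, 1.0),
    noise_cv: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """(OD600, acetate mM) points with a programmed secretion rate.

    During exponential growth, secreted acetate accumulates in proportion to
    the biomass formed, so acetate vs OD is linear with slope
    ``true_rate / mu``; the analysis multiplies the fitted slope back by µ.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    rng = np.random.default_rng(seed)
    od = np.asarray(od_grid, dtype=float)
    od0 = od[0]
    acetate = (true_rate / mu) * (od - od0)
    acetate = acetate * _multiplicative_noise(rng, noise_cv, acetate.size)
    return list(zip(od.tolist(), acetate.tolist()))
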