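#!/usr/bin/env python
"""Simulate a diauxic plate and run the curve-processing stage on it.

Builds a noise-free plate of two-phase growth curves whose endpoints follow
the additive two-nutrient model, converts OD to dry weight, extracts the
produced biomass per well, estimates first-phase growth rates, and segments
the diauxic phases of the richest well.  Writes the per-well endpoint table
and a segmentation summary under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from multiyield import (
    CalibrationModel,
    EndpointDesign,
    EnergyParams,
    KineticParams,
    ModelSpec,
    TwoDegradableEffects,
    estimate_growth_rate,
    extract_endpoints,
    od_to_biomass,
    segment_diauxic_phases,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    OUT.mkdir(exist_ok=True)

    params = EnergyParams(g_X=300.0, g_cat={"N1": 100.0, "N2": 100.0}, g_an=100.0)
    spec = ModelSpec("two_degradable", params, TwoDegradableEffects())
    design = EndpointDesign(
        measured_amounts=(0.0, 40.0, 80.0, 120.0, 160.0),
        base_amounts=(80.0,), n_reps=3, noise_cv=0.0, seed=args.seed,
    )
    kin = KineticParams(mu1=0.9, mu2=0.3, lag2_h=3.0, phase_split=0.7,
                        horizon_h=30.0)
    from multiyield import generate_diauxic_plate

    series, layout = generate_diauxic_plate(spec, design, kin)
    endpoints = extract_endpoints(series, layout)
    endpoints.to_csv(OUT / "plate_endpoints.csv", index=False)
    print(f"extracted {len(endpoints)} per-well endpoints "
          f"(dB {endpoints['delta_B_ug'].min():.1f}-"
          f"{endpoints['delta_B_ug'].max():.1f} ug)")

    cal = CalibrationModel()
    rows = []
    for wid, s in sorted(series.items()):
        traj = od_to_biomass(s, cal)
        mu = estimate_growth_rate(traj)
        seg = segment_diauxic_phases(traj)
        rows.append(
            {
                "well": wid,
                "measured_amount_ug": layout[wid].measured_amount_ug,
                "mu1_per_h": mu.mu_per_h,
                "single_phase": seg.single_phase,
                "phase1_end_h": seg.phase1.t_end,
                "phase2_start_h": None if seg.phase2 is None else seg.phase2.t_start,
                "lag2_h": seg.lag2_h,
                "phase1_gain_ug": seg.phase1.gain_ug,
                "phase2_gain_ug": None if seg.phase2 is None else seg.phase2.gain_ug,
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "plate_segmentation.csv", index=False)
    two_phase = (~summary["single_phase"]).sum()
    print(f"segmentation: {two_phase}/{len(summary)} wells show two phases; "
          f"mean first-phase rate {summary['mu1_per_h'].mean():.2f} /h "
          f"(programmed 0.90)")


if __name__ == "__main__":
    main()
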