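#!/usr/bin/env python
"""Map the qualitative solution space of the mutual-effect models.

Sweeps the measured-nutrient amount at a fixed base amount across grids of
coupling coefficients and labels each cell by its dose-response regime:
additive, yield increase, yield decrease, or non-monotone
(dip-then-recovery, which for the precursor model lives on the
supply-limited closure of the quadratic).  Writes the regime tables under
results/.
"""

import argparse
from pathlib import Path

import numpy as np

from multiyield import EnergyParams, PrecursorSpec, map_solution_space

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)  # deterministic sweep
    ap.parse_args()
    OUT.mkdir(exist_ok=True)

    p2 = EnergyParams(g_X=300.0, g_cat={"N1": 150.0, "N2": 100.0}, g_an=100.0)
    grid2 = (
        [{"m_cat_1": v, "m_an_1": 0.0} for v in
         (-0.0008, -0.0004, 0.0, 0.001, 0.002, 0.004)]
        + [{"m_cat_1": 0.0, "m_an_1": v} for v in (-0.001, 0.001, 0.002)]
    )
    rm2 = map_solution_space(
        p2, "two_degradable", grid2, np.linspace(0, 240, 49), 160.0
    )
    rm2.entries.to_csv(OUT / "regimes_two_degradable.csv", index=False)
    counts2 = rm2.entries["regime"].value_counts().to_dict()
    print(f"two-degradable grid ({len(grid2)} cells): {counts2}")

    pp = EnergyParams(g_X=300.0, g_cat={"N": 200.0}, g_an=150.0,
                      g_an_excl=100.0, g_bsyn=50.0)
    sweep = np.concatenate([[0.0], np.geomspace(1e-4, 4.0, 120)])
    gridp = [{"m_cat": mc, "m_bsyn": mb}
             for mc in (-0.8, -0.5, 0.0, 0.5) for mb in (0.0, 0.05, 0.1)]
    rmp = map_solution_space(
        pp, "precursor", gridp, sweep, 1.0,
        spec=PrecursorSpec(q_req=0.02), nutrient_ids=("N", "M"),
    )
    rmp.entries.to_csv(OUT / "regimes_precursor.csv", index=False)
    countsp = rmp.entries["regime"].value_counts().to_dict()
    print(f"precursor grid ({len(gridp)} cells): {countsp}")
    nonmono = rmp.entries.query("regime == 'non_monotone'")
    print(f"non-monotone cells all have m_cat < 0: "
          f"{bool((nonmono['m_cat'] < 0).all())}")


if __name__ == "__main__":
    main()
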