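"""Black-box model equations: yields, additive sums, mutual effects, quadratic."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from multiyield import (
    Branch,
    EnergyParams,
    ModelValidityError,
    PrecursorEffects,
    PrecursorSpec,
    TwoDegradableEffects,
    m_utl_value,
    overall_yield_single,
    produced_biomass_additive,
    produced_biomass_linear,
    produced_biomass_precursor,
    produced_biomass_two_degradable,
    solve_energy_balance_numeric,
)
from conftest import random_valid_precursor_draw


class TestEnergyParams:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            EnergyParams(g_X=0.0, g_cat={"N": 1.0}, g_an=1.0)
        with pytest.raises(ValueError):
            EnergyParams(g_X=1.0, g_cat={"N": 0.0}, g_an=1.0)
        with pytest.raises(ValueError):
            EnergyParams(g_X=1.0, g_cat={"N": 1.0}, g_an=1.0, g_an_excl=2.0)

    def test_unknown_nutrient_rejected(self, simple_params):
        with pytest.raises(KeyError, match="unknown nutrient"):
            overall_yield_single(simple_params, "xylose")


class TestOverallYieldSingle:
    def test_basic_yield(self, simple_params):
        assert overall_yield_single(simple_params, "N") == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "m_utl, expected",
        [(0.0, 200.0 / 450.0), (1.0, 0.5), (0.5, 200.0 / 425.0)],
    )
    def test_precursor_decomposition(self, precursor_params, m_utl, expected):
        # supplying the precursor externally alleviates its biosynthesis cost
        assert overall_yield_single(precursor_params, "N", m_utl) == pytest.approx(expected)

    def test_yield_increases_with_utilization(self, precursor_params):
        ys = [overall_yield_single(precursor_params, "N", u) for u in (0, 0.5, 1)]
        assert ys[0] < ys[1] < ys[2]

    def test_m_utl_out_of_range_rejected(self, precursor_params):
        with pytest.raises(ValueError):
            overall_yield_single(precursor_params, "N", 1.5)


class TestProducedBiomassLinear:
    @pytest.mark.parametrize("y, n, expected", [(0.5, 10, 5.0), (0.5, 0, 0.0)])
    def test_proportionality(self, y, n, expected):
        assert produced_biomass_linear(y, n) == expected

    def test_composition_with_yield(self, simple_params):
        y = overall_yield_single(simple_params, "N")
        assert produced_biomass_linear(y, 4.0) == pytest.approx(2.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            produced_biomass_linear(-0.1, 1.0)
        with pytest.raises(ValueError):
            produced_biomass_linear(0.1, -1.0)


class TestProducedBiomassAdditive:
    def test_two_nutrient_sum(self):
        p = EnergyParams(g_X=300, g_cat={"A": 200.0, "B": 160.0}, g_an=100.0)
        # Y_A = 0.5 at 10 µg, Y_B = 0.4 at 5 µg
        assert produced_biomass_additive(p, {"A": 10, "B": 5}) == pytest.approx(7.0)

    def test_single_entry_reduces_to_linear(self, simple_params):
        assert produced_biomass_additive(simple_params, {"N": 10}) == pytest.approx(5.0)

    def test_order_invariance(self):
        p = EnergyParams(g_X=300, g_cat={"A": 200.0, "B": 160.0}, g_an=100.0)
        assert produced_biomass_additive(p, {"A": 10, "B": 5}) == produced_biomass_additive(
            p, {"B": 5, "A": 10}
        )

    def test_empty_doses_rejected(self, simple_params):
        with pytest.raises(ValueError):
            produced_biomass_additive(simple_params, {})


class TestTwoDegradable:
    def test_additive_reduction(self, two_nutrient_params):
        db = produced_biomass_two_degradable(
            two_nutrient_params, TwoDegradableEffects(), 1.0, 1.0
        )
        assert db == pytest.approx(0.5)

    def test_positive_catabolic_effect(self, two_nutrient_params):
        db = produced_biomass_two_degradable(
            two_nutrient_params, TwoDegradableEffects(m_cat_1=0.1, m_cat_2=0.1), 1.0, 1.0
        )
        assert db == pytest.approx(0.55)

    def test_anabolic_cost_inflation(self, two_nutrient_params):
        db = produced_biomass_two_degradable(
            two_nutrient_params, TwoDegradableEffects(m_an_1=1.0), 1.0, 0.0
        )
        assert db == pytest.approx(0.2)

    def test_invalid_denominator_raises(self, two_nutrient_params):
        with pytest.raises(ModelValidityError):
            produced_biomass_two_degradable(
                two_nutrient_params, TwoDegradableEffects(m_an_1=-2.0), 3.0, 0.0
            )

    @given(
        n1=st.floats(0, 100), n2=st.floats(0, 100),
        g1=st.floats(10, 500), g2=st.floats(10, 500),
        gx=st.floats(10, 500), gan=st.floats(0, 300),
    )
    def test_zero_coefficients_equal_additive_sum(self, n1, n2, g1, g2, gx, gan):
        """With no mutual effects the model is exactly the additive sum."""
        p = EnergyParams(g_X=gx, g_cat={"N1": g1, "N2": g2}, g_an=gan)
        db = produced_biomass_two_degradable(p, TwoDegradableEffects(), n1, n2)
        expected = (g1 * n1 + g2 * n2) / (gx + gan)
        assert db == pytest.approx(expected, rel=1e-12, abs=1e-300)

    def test_delta_b_increasing_in_m_cat(self, two_nutrient_params):
        dbs = [
            produced_biomass_two_degradable(
                two_nutrient_params, TwoDegradableEffects(m_cat_1=m), 2.0, 3.0
            )
            for m in (0.0, 0.05, 0.1, 0.2)
        ]
        assert all(a < b for a, b in zip(dbs, dbs[1:]))

    def test_yield_slope_linear_in_base_amount(self, two_nutrient_params):
        """∂ΔB/∂N1 at m_an = 0 equals (g_cat1 + Δm_CAT·N2)/(g_X + g_an)."""
        eff = TwoDegradableEffects(m_cat_1=0.01, m_cat_2=0.02)
        g1 = g2 = 100.0
        dm = g1 * 0.01 + g2 * 0.02
        for n2 in (0.0, 50.0, 100.0):
            h = 1e-5
            fd = (
                produced_biomass_two_degradable(two_nutrient_params, eff, 10 + h, n2)
                - produced_biomass_two_degradable(two_nutrient_params, eff, 10 - h, n2)
            ) / (2 * h)
            analytic = (g1 + dm * n2) / (300.0 + 100.0)
            assert fd == pytest.approx(analytic, rel=1e-6)


class TestMUtl:
    @pytest.mark.parametrize(
        "m, q, db, expected",
        [(2, 1, 5, 0.4), (10, 1, 5, 1.0), (0, 1, 5, 0.0), (1, 1, 0, 1.0)],
    )
    def test_value(self, m, q, db, expected):
        assert m_utl_value(m, PrecursorSpec(q_req=q), db) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            m_utl_value(-1, PrecursorSpec(q_req=1), 1)


class TestPrecursorModel:
    def test_no_precursor_matches_yield_formula(self, precursor_params, q_spec):
        sol = produced_biomass_precursor(
            precursor_params, PrecursorEffects(), q_spec, 1.0, 0.0
        )
        assert sol.delta_B == pytest.approx(200.0 / 450.0, rel=1e-14)
        assert sol.branch is Branch.UNSATURATED
        assert sol.m_utl == 0.0
        # agrees with the single-nutrient precursor-decomposed yield
        y0 = overall_yield_single(precursor_params, "N", m_utl=0.0)
        assert sol.delta_B == pytest.approx(y0 * 1.0)

    def test_zero_coupling_closed_form(self, precursor_params, q_spec):
        # with m_cat = m_an_M = 0 the quadratic's constant term vanishes:
        # ΔB = (N·g_cat + g_bsyn·M')/G_A
        sol = produced_biomass_precursor(
            precursor_params, PrecursorEffects(), q_spec, 1.0, 0.004
        )
        assert sol.delta_B == pytest.approx((200.0 + 50.0 * 0.2) / 450.0)
        assert sol.m_utl == pytest.approx(0.2 / sol.delta_B)
        assert sol.branch is Branch.UNSATURATED

    def test_saturated_branch_flat_in_m(self, precursor_params, q_spec):
        eff = PrecursorEffects()
        sols = [
            produced_biomass_precursor(precursor_params, eff, q_spec, 1.0, m)
            for m in (0.05, 0.1, 0.5)
        ]
        assert all(s.branch is Branch.SATURATED for s in sols)
        assert all(s.m_utl == 1.0 for s in sols)
        vals = [s.delta_B for s in sols]
        assert max(vals) - min(vals) < 1e-12

    def test_precursor_benefit_monotone(self, precursor_params, q_spec):
        """With no couplings, ΔB is non-decreasing in M and flat once saturated."""
        eff = PrecursorEffects()
        ms = np.linspace(0, 0.05, 40)
        dbs = [
            produced_biomass_precursor(precursor_params, eff, q_spec, 1.0, m).delta_B
            for m in ms
        ]
        assert all(b - a >= -1e-12 for a, b in zip(dbs, dbs[1:]))

    def test_negative_catabolic_sweep_matches_oracle(self, precursor_params, q_spec):
        """Capped solution with m_cat < 0: decreasing to a saturated plateau,

        every point agreeing with the independent energy-balance solver.
        """
        eff = PrecursorEffects(m_cat=-0.8)
        ms = np.linspace(0, 0.01, 21)
        dbs = []
        for m in ms:
            sol = produced_biomass_precursor(precursor_params, eff, q_spec, 1.0, m)
            num = solve_energy_balance_numeric(precursor_params, eff, q_spec, 1.0, m)
            assert sol.delta_B == pytest.approx(num, rel=1e-8)
            dbs.append(sol.delta_B)
        assert all(b - a <= 1e-12 for a, b in zip(dbs, dbs[1:]))  # non-increasing

    def test_supply_limited_closure_has_fold_and_recovery(
        self, precursor_params, q_spec
    ):
        """Supply-limited exploration: dip, no-solution gap, rising branch."""
        eff = PrecursorEffects(m_cat=-0.8, m_bsyn=0.1)
        lo = [
            produced_biomass_precursor(
                precursor_params, eff, q_spec, 1.0, m, closure="supply_limited"
            ).delta_B
            for m in (0.0, 0.001, 0.002)
        ]
        assert lo[0] > lo[1] > lo[2]
        with pytest.raises(ModelValidityError, match="fold gap|no real"):
            produced_biomass_precursor(
                precursor_params, eff, q_spec, 1.0, 0.01, closure="supply_limited"
            )
        hi = [
            produced_biomass_precursor(
                precursor_params, eff, q_spec, 1.0, m, closure="supply_limited"
            ).delta_B
            for m in (3.0, 4.0)
        ]
        assert hi[1] > hi[0]

    def test_zero_nutrient_gives_zero_biomass(self, precursor_params, q_spec):
        sol = produced_biomass_precursor(
            precursor_params, PrecursorEffects(), q_spec, 0.0, 1.0
        )
        assert sol.delta_B == 0.0

    def test_invalid_ga_raises(self, q_spec):
        p = EnergyParams(g_X=10.0, g_cat={"N": 100.0}, g_an=200.0,
                         g_an_excl=200.0, g_bsyn=0.0)
        with pytest.raises(ModelValidityError):
            produced_biomass_precursor(
                p, PrecursorEffects(m_an_N=-2.0), q_spec, 2.0, 0.0
            )


class TestOracleEquivalence:
    def test_known_points(self, precursor_params, q_spec):
        for m, expected in [(0.0, 200.0 / 450.0), (0.004, 210.0 / 450.0)]:
            num = solve_energy_balance_numeric(
                precursor_params, PrecursorEffects(), q_spec, 1.0, m
            )
            assert num == pytest.approx(expected, rel=1e-9)

    def test_random_draws_agree(self):
        """Closed-form quadratic vs independent bisection on the energy balance."""
        rng = np.random.default_rng(2024)
        checked = 0
        worst = 0.0
        while checked < 200:
            params, effects, spec, n, m = random_valid_precursor_draw(rng)
            try:
                quad = produced_biomass_precursor(params, effects, spec, n, m).delta_B
                num = solve_energy_balance_numeric(params, effects, spec, n, m)
            except ModelValidityError:
                continue
            rel = abs(num - quad) / quad
            worst = max(worst, rel)
            checked += 1
        assert worst < 1e-6
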