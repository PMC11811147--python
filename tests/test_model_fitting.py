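"""Coefficient recovery, effect classification, and the regime map."""

import numpy as np
import pandas as pd
import pytest

from multiyield import (
    EffectSign,
    EndpointDesign,
    EnergyParams,
    IdentifiabilityError,
    ModelSpec,
    PrecursorEffects,
    PrecursorSpec,
    RegimeLabel,
    TwoDegradableEffects,
    classify_mutual_effect,
    fit_precursor_effects,
    fit_two_degradable_effects,
    generate_endpoint_table,
    map_solution_space,
    produced_biomass_precursor,
)
from multiyield.model_fitting import (
    TwoDegradableFitResult,
    reduced_precursor_delta_b,
    reduced_two_degradable_delta_b,
)


def reduced_table(y1, y2, delta, a1, a2, measured, bases, noise_cv=0.0, seed=0):
    """Endpoint table straight from the reduced two-degradable form."""
    rng = np.random.default_rng(seed)
    rows = []
    for b in bases:
        for m in measured:
            db = reduced_two_degradable_delta_b(
                np.array([y1, y2, delta, a1, a2]), np.array([m]), np.array([b])
            )[0]
            if noise_cv:
                db = float(np.mean(db * (1 + rng.normal(0, noise_cv, 3))))
            rows.append(
                {"measured_amount_ug": m, "base_amount_ug": b,
                 "delta_B_mean_ug": db, "delta_B_se_ug": 0.0, "n_reps": 3}
            )
    return pd.DataFrame(rows)


MEASURED = [0.0, 30.0, 60.0, 90.0, 120.0, 160.0]
BASES = [0.0, 80.0, 160.0]


class TestFitTwoDegradable:
    def test_noiseless_exact_recovery(self):
        tbl = reduced_table(0.5, 0.3, 0.002, 0.0, 0.0, MEASURED, BASES)
        fit = fit_two_degradable_effects(tbl, seed=1)
        assert fit.Y1 == pytest.approx(0.5, rel=1e-6)
        assert fit.Y2 == pytest.approx(0.3, rel=1e-6)
        assert fit.delta == pytest.approx(0.002, rel=1e-4)
        assert fit.residual_sse < 1e-12

    def test_noisy_recovery_within_ten_percent(self):
        tbl = reduced_table(
            0.5, 0.3, 0.002, 0.0, 0.0, MEASURED, BASES, noise_cv=0.02, seed=42
        )
        fit = fit_two_degradable_effects(tbl, fit_alphas=False, seed=42)
        assert fit.Y1 == pytest.approx(0.5, rel=0.10)
        assert fit.Y2 == pytest.approx(0.3, rel=0.10)
        assert fit.delta == pytest.approx(0.002, rel=0.10)

    def test_additive_data_gives_null_interaction(self):
        tbl = reduced_table(
            0.5, 0.3, 0.0, 0.0, 0.0, MEASURED, BASES, noise_cv=0.02, seed=7
        )
        fit = fit_two_degradable_effects(tbl, fit_alphas=False, seed=7)
        assert abs(fit.delta) <= 2 * fit.ses["delta"]

    def test_anabolic_coefficients_recovered(self):
        tbl = reduced_table(0.5, 0.3, 0.001, 0.002, 0.001, MEASURED, BASES)
        fit = fit_two_degradable_effects(tbl, seed=3)
        assert fit.alpha1 == pytest.approx(0.002, rel=0.01)
        assert fit.alpha2 == pytest.approx(0.001, rel=0.01)

    def test_single_base_amount_refused(self):
        tbl = reduced_table(
            0.5, 0.3, 0.002, 0.0, 0.0, list(np.linspace(0, 160, 9)), [80.0]
        )
        with pytest.raises(IdentifiabilityError):
            fit_two_degradable_effects(tbl)

    def test_too_few_points_rejected(self):
        tbl = reduced_table(0.5, 0.3, 0.0, 0.0, 0.0, [0.0, 50.0], [0.0, 80.0])
        with pytest.raises(ValueError, match=">= 8"):
            fit_two_degradable_effects(tbl)


def precursor_table(params, effects, spec, ns, ms, noise_cv=0.0, seed=0,
                    closure="cap"):
    rng = np.random.default_rng(seed)
    rows = []
    for n in ns:
        for m in ms:
            db = produced_biomass_precursor(
                params, effects, spec, n, m, closure=closure
            ).delta_B
            if noise_cv:
                db = float(np.mean(db * (1 + rng.normal(0, noise_cv, 3))))
            rows.append(
                {"measured_amount_ug": m, "base_amount_ug": n,
                 "delta_B_mean_ug": db, "delta_B_se_ug": 0.0, "n_reps": 3}
            )
    return pd.DataFrame(rows)


class TestFitPrecursor:
    def setup_method(self):
        # reduced-scale truth: baseline cost 1, biosynthesis share 0.2
        self.spec = PrecursorSpec(q_req=0.02)
        self.params = EnergyParams(
            g_X=0.4, g_cat={"N": 0.5}, g_an=0.6, g_an_excl=0.4, g_bsyn=0.2
        )

    def test_noiseless_sign_and_value_recovery(self):
        effects = PrecursorEffects(m_cat=-0.8, m_bsyn=0.05)
        tbl = precursor_table(
            self.params, effects, self.spec,
            ns=[40.0, 80.0, 160.0], ms=[0.0, 0.2, 0.5, 1.0, 1.5, 2.0],
        )
        fit = fit_precursor_effects(tbl, self.spec, seed=2)
        assert fit.m_cat < 0
        assert fit.m_bsyn > 0
        assert fit.m_cat == pytest.approx(-0.8, rel=0.05)
        assert fit.m_bsyn == pytest.approx(0.05, rel=0.05)
        assert fit.y_base == pytest.approx(0.5, rel=0.05)
        assert fit.b_bsyn_gain == pytest.approx(0.2, rel=0.05)

    def test_null_effects_within_two_se(self):
        effects = PrecursorEffects()
        tbl = precursor_table(
            self.params, effects, self.spec,
            ns=[40.0, 80.0, 160.0], ms=[0.0, 0.2, 0.5, 1.0, 1.5, 2.0],
            noise_cv=0.02, seed=9,
        )
        fit = fit_precursor_effects(tbl, self.spec, seed=9)
        assert abs(fit.m_cat) <= 2 * fit.ses["m_cat"]
        assert abs(fit.m_bsyn) <= 2 * fit.ses["m_bsyn"]

    def test_single_base_amount_refused(self):
        tbl = precursor_table(
            self.params, PrecursorEffects(), self.spec,
            ns=[80.0], ms=np.linspace(0, 2, 12),
        )
        with pytest.raises(IdentifiabilityError):
            fit_precursor_effects(tbl, self.spec)


class TestClassification:
    def _fit(self, delta, se):
        ses = {"Y1": 0.01, "Y2": 0.01, "delta": se, "alpha1": 1.0, "alpha2": 1.0}
        return TwoDegradableFitResult(
            Y1=0.5, Y2=0.3, delta=delta, alpha1=0.0, alpha2=0.0, ses=ses,
            covariance=np.eye(5), residual_sse=0.0, n_points=18, alphas_fitted=True,
        )

    @pytest.mark.parametrize(
        "delta, se, expected",
        [
            (0.002, 0.0003, EffectSign.POSITIVE),
            (-0.002, 0.0003, EffectSign.NEGATIVE),
            (0.001, 0.002, EffectSign.NONE),
        ],
    )
    def test_two_se_rule(self, delta, se, expected):
        assert classify_mutual_effect(self._fit(delta, se)).catabolic is expected

    def test_missing_covariance_withholds_confidence(self):
        fit = TwoDegradableFitResult(
            Y1=0.5, Y2=0.3, delta=0.002, alpha1=0.0, alpha2=0.0,
            ses={}, covariance=None, residual_sse=0.0, n_points=18,
            alphas_fitted=True,
        )
        cls = classify_mutual_effect(fit)
        assert not cls.confidence_available
        assert cls.catabolic is EffectSign.NONE


class TestRegimeMap:
    def setup_method(self):
        self.p2 = EnergyParams(g_X=300, g_cat={"N1": 150, "N2": 100}, g_an=100)
        self.pp = EnergyParams(
            g_X=300, g_cat={"N": 200}, g_an=150, g_an_excl=100, g_bsyn=50
        )
        self.spec = PrecursorSpec(q_req=0.02)

    def test_two_degradable_regimes(self):
        grid = [{}, {"m_cat_1": 0.002}, {"m_cat_1": -0.0008},
                {"m_an_1": 0.002}, {"m_an_1": -0.001}]
        rm = map_solution_space(
            self.p2, "two_degradable", grid, np.linspace(0, 240, 25), 160.0
        )
        labels = rm.entries["regime"].tolist()
        assert labels == [
            "additive", "yield_increase", "yield_decrease",
            "yield_decrease", "yield_increase",
        ]

    def test_precursor_regimes(self):
        sweep = np.concatenate([[0.0], np.geomspace(1e-4, 4.0, 120)])
        grid = [{}, {"m_cat": -0.8, "m_bsyn": 0.1}, {"m_cat": 0.5}]
        rm = map_solution_space(
            self.pp, "precursor", grid, sweep, 1.0,
            spec=self.spec, nutrient_ids=("N", "M"),
        )
        labels = rm.entries["regime"].tolist()
        assert labels == ["additive", "non_monotone", "yield_increase"]

    def test_nutrient_relabel_symmetry(self):
        """Swapping nutrient roles with swapped coefficients mirrors the map."""
        psym = EnergyParams(g_X=300, g_cat={"N1": 150, "N2": 150}, g_an=100)
        sweep = np.linspace(0, 240, 25)
        rm_a = map_solution_space(
            psym, "two_degradable",
            [{"m_cat_1": 0.002, "m_cat_2": 0.0}], sweep, 160.0,
        )
        rm_b = map_solution_space(
            psym, "two_degradable",
            [{"m_cat_1": 0.0, "m_cat_2": 0.002}], sweep, 160.0,
            nutrient_ids=("N2", "N1"),
        )
        assert rm_a.entries["regime"].tolist() == rm_b.entries["regime"].tolist()

    def test_invalid_cell_labelled(self):
        rm = map_solution_space(
            self.p2, "two_degradable", [{"m_an_1": -0.02}],
            np.linspace(0, 240, 25), 160.0,
        )
        assert rm.entries["regime"].iloc[0] == "invalid"

    def test_yield_increases_with_base_amount_in_increase_cells(self):
        """Positive catabolic coupling: measured-nutrient yield grows with base."""
        eff = TwoDegradableEffects(m_cat_1=0.002)
        spec = ModelSpec("two_degradable", self.p2, eff)
        slopes = []
        for base in (0.0, 80.0, 160.0):
            design = EndpointDesign(
                measured_amounts=tuple(np.linspace(0, 240, 7)),
                base_amounts=(base,), n_reps=1, noise_cv=0.0, seed=0,
            )
            _, tbl = generate_endpoint_table(spec, design)
            slopes.append(np.polyfit(
                tbl["measured_amount_ug"], tbl["delta_B_mean_ug"], 1
            )[0])
        assert slopes[0] < slopes[1] < slopes[2]
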