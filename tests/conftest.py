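import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from multiyield import (
    CalibrationModel,
    EnergyParams,
    PrecursorEffects,
    PrecursorSpec,
    TwoDegradableEffects,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def simple_params() -> EnergyParams:
    """One degradable nutrient: Y = 200/(300+100) = 0.5 g/g."""
    return EnergyParams(g_X=300.0, g_cat={"N": 200.0}, g_an=100.0)


@pytest.fixture
def precursor_params() -> EnergyParams:
    """Degradable nutrient + precursor, biosynthesis cost split out."""
    return EnergyParams(
        g_X=300.0, g_cat={"N": 200.0}, g_an=150.0, g_an_excl=100.0, g_bsyn=50.0
    )


@pytest.fixture
def two_nutrient_params() -> EnergyParams:
    return EnergyParams(
        g_X=300.0, g_cat={"N1": 100.0, "N2": 100.0}, g_an=100.0
    )


@pytest.fixture
def q_spec() -> PrecursorSpec:
    return PrecursorSpec(q_req=0.02)


@pytest.fixture
def identity_cal() -> CalibrationModel:
    return CalibrationModel()


def random_valid_precursor_draw(rng: np.random.Generator):
    """One random parameter/dose draw inside the precursor-model validity region.

    Used by the oracle-equivalence checks: magnitudes within physiological
    orders, couplings small enough that G_A stays positive and f_cat positive
    over the whole utilization range.
    """
    g_x = rng.uniform(100.0, 600.0)
    g_cat = rng.uniform(50.0, 500.0)
    g_an_excl = rng.uniform(20.0, 200.0)
    g_bsyn = rng.uniform(5.0, 100.0)
    params = EnergyParams(
        g_X=g_x, g_cat={"N": g_cat}, g_an=g_an_excl + g_bsyn,
        g_an_excl=g_an_excl, g_bsyn=g_bsyn,
    )
    n = rng.uniform(0.1, 5.0)
    effects = PrecursorEffects(
        m_cat=rng.uniform(-0.9, 1.0),
        m_an_N=rng.uniform(-0.1 / n if n else -0.1, 0.3),
        m_an_M=rng.uniform(-0.5, 0.5),
        m_bsyn=rng.uniform(-0.1 / n if n else -0.1, 0.3),
    )
    spec = PrecursorSpec(q_req=rng.uniform(0.005, 0.1))
    m = rng.uniform(0.0, 0.05)
    return params, effects, spec, n, m
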