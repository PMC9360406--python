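import numpy as np
import pytest

from thrombodyn import (
    CohortConfig,
    ConversionShape,
    PlasmaFactors,
    RateModel,
    forward_simulate_tg,
    generate_cohort,
)


@pytest.fixture(scope="session")
def model():
    """Default rate model (stoichiometric depletion, fibrinogen-dependent)."""
    return RateModel()


@pytest.fixture(scope="session")
def excess_model():
    """Constant-inhibitor (excess) mode with no fibrinogen dependence:
    thrombin decay is exactly exponential, enabling closed-form checks."""
    return RateModel(stoichiometric_depletion=False, fib_form="constant")


@pytest.fixture(scope="session")
def median_factors():
    """Healthy-cohort median plasma factors."""
    return PlasmaFactors(at_pct=113.0, a2m_uM=2.6, fib_gL=2.9)


@pytest.fixture(scope="session")
def tdc065_setup():
    """Factors/model combination with TDC = 0.2e-3*2500 + 0.5e-4*3000
    = 0.5 + 0.15 = 0.65 min^-1 and no fibrinogen effect."""
    model = RateModel(
        k_at_ref=2e-4,
        k_a2m_ref=5e-5,
        fib_form="constant",
        at_nM_per_pct=25.0,
        stoichiometric_depletion=False,
    )
    factors = PlasmaFactors(at_pct=100.0, a2m_uM=3.0, fib_gL=2.9)
    return factors, model


@pytest.fixture(scope="session")
def grid40():
    """40-minute uniform grid at the default 0.05 min spacing."""
    return 0.05 * np.arange(801)


@pytest.fixture(scope="session")
def bleed_truth(model, median_factors, grid40):
    """Noise-free forward-simulated low-trigger curve with its ground
    truth (pulse + trajectory) for inverse-consistency checks."""
    shape = ConversionShape(pc_tot=902.0, delay=2.6, shape=4.0, scale=1.175)
    curve, traj = forward_simulate_tg(shape, median_factors, model, grid40)
    return curve, traj, shape


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 6-subject noise-free cohort for pipeline tests."""
    return generate_cohort(CohortConfig(n_subjects=6, seed=7, noise_sd=0.0))
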