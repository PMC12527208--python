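import numpy as np
import pytest

from headingci import ObserverParams, SensoryMeasurement, build_design, simulate_observer


@pytest.fixture
def unit_params() -> ObserverParams:
    """All-unit-SD contextual observer used by the worked examples."""
    return ObserverParams(
        model_id="cci",
        sigma_self=1.0,
        sigma_env=1.0,
        sigma_vest=1.0,
        w_vis=0.2,
        p_constant=0.5,
    )


@pytest.fixture
def unit_meas() -> SensoryMeasurement:
    return SensoryMeasurement(x_vest=1.0, x_vis=1.0, x_vis0=0.0)


@pytest.fixture
def unit_sds():
    return (1.0, 1.0, 1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_design():
    """2 velocities x 2 headings x 3 conditions x 2 reps = 24 trials."""
    return build_design(
        velocities=(-10.0, 10.0), headings=(-25.0, 25.0), reps=2, seed=11
    )


@pytest.fixture(scope="session")
def full_design():
    return build_design(seed=5)


@pytest.fixture(scope="session")
def moderate_cci_params() -> ObserverParams:
    """Representative observer in the regime human data exhibit.

    Moderate noise with a below-half prior on constant environmental
    motion: heading biases stay opposite to the visual motion in every
    condition (compensation incomplete even when the environment is
    constant), as in the behavioral data.
    """
    return ObserverParams(
        model_id="cci",
        sigma_self=5.0,
        sigma_env=5.0,
        sigma_vest=2.5,
        w_vis=0.2,
        p_constant=0.3,
    )


@pytest.fixture(scope="session")
def cci_dataset(full_design, moderate_cci_params):
    return simulate_observer("cci", moderate_cci_params, full_design, seed=99)


def random_observer_params(rng: np.random.Generator) -> ObserverParams:
    """Broad random parameter draw exercising all model fields."""
    return ObserverParams(
        model_id="cci",
        sigma_self=float(np.exp(rng.normal(1.0, 0.5))),
        sigma_env=float(np.exp(rng.normal(1.0, 0.5))),
        sigma_vest=float(np.exp(rng.normal(0.5, 0.5))),
        w_vis=float(np.exp(rng.normal(-2.0, 0.5))),
        p_constant=float(rng.uniform(0.05, 0.95)),
        rho=float(rng.uniform(0.0, 1.0)),
        p_common=float(rng.uniform(0.05, 0.95)),
    )


def random_measurement(rng: np.random.Generator, scale: float = 4.0) -> SensoryMeasurement:
    return SensoryMeasurement(
        x_vest=float(rng.normal(0, scale)),
        x_vis=float(rng.normal(0, scale)),
        x_vis0=float(rng.normal(0, scale)),
    )


def random_sds(rng: np.random.Generator, sigma_vest: float):
    return (sigma_vest, float(rng.uniform(0.3, 3.0)), float(rng.uniform(0.3, 3.0)))
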