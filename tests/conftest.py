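import numpy as np
import pytest

from hvhfit import (
    DEFAULT_TRUE_PARAMS,
    DEFAULT_DESIGN,
    DEFAULT_SCENARIO,
    FixedParams,
    HVHParams,
    InterferenceScenario,
    ObservationModel,
    derive_growth_table,
    generate_dataset,
    manufacture_consistent_census,
)


@pytest.fixture(scope="session")
def fx():
    return FixedParams(e=0.8, mu=0.1)


@pytest.fixture(scope="session")
def true_params():
    return DEFAULT_TRUE_PARAMS


@pytest.fixture(scope="session")
def design():
    return DEFAULT_DESIGN


@pytest.fixture(scope="session")
def noiseless_obs():
    return ObservationModel(fixed_volume=1.0, counted_volume=0.1, count_noise="none")


@pytest.fixture(scope="session")
def constant_m0():
    return InterferenceScenario(mode="constant", m_constant=0.0)


@pytest.fixture(scope="session")
def noiseless_census_m0(design, true_params, fx, constant_m0, noiseless_obs):
    """Noise-free census under purely exploitative (m = 0) dynamics."""
    return generate_dataset(design, true_params, fx, constant_m0, noiseless_obs, seed=11)


@pytest.fixture(scope="session")
def noiseless_growth_m0(noiseless_census_m0):
    return derive_growth_table(noiseless_census_m0)


@pytest.fixture(scope="session")
def shifting_census_noiseless(design, true_params, fx, noiseless_obs):
    """Noise-free census under the density-shifting interference scenario."""
    return generate_dataset(design, true_params, fx, DEFAULT_SCENARIO, noiseless_obs, seed=11)


@pytest.fixture(scope="session")
def consistent_census_shifting(design, true_params, fx):
    """Census exactly consistent with the instantaneous fitted model."""
    return manufacture_consistent_census(design, true_params, fx, DEFAULT_SCENARIO)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
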