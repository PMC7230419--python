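import pytest

from physupply import (
    ModelParameters,
    build_initial_state,
    reconstruct_age_distribution,
    run_scenario,
    scenario_1,
    scenario_2,
)
from physupply.synthetic import AgeConstraints


@pytest.fixture(scope="session")
def baseline_params():
    return ModelParameters()


@pytest.fixture(scope="session")
def baseline_ages():
    """Reconstructed baseline specialist age distribution (cached: the
    convex solve takes about a second)."""
    return reconstruct_age_distribution(9648.0, AgeConstraints())


@pytest.fixture(scope="session")
def baseline_state(baseline_params, baseline_ages):
    return build_initial_state(baseline_params, baseline_ages)


@pytest.fixture(scope="session")
def s1_trajectory(baseline_params, baseline_state):
    return run_scenario(scenario_1(), baseline_params, baseline_state)


@pytest.fixture(scope="session")
def s2_trajectory(baseline_params, baseline_state):
    return run_scenario(scenario_2(), baseline_params, baseline_state)
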