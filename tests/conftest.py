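import numpy as np
import pytest

from amparcycle.calibration import calibrate_all
from amparcycle.dynamics import Scenario, simulate, steady_state
from amparcycle.network import build_network
from amparcycle.parameters import ParameterSet
from amparcycle.protocols import run_scenario


@pytest.fixture(scope="session")
def default_params() -> ParameterSet:
    return ParameterSet.default()


@pytest.fixture(scope="session")
def network(default_params):
    return build_network(default_params)


@pytest.fixture(scope="session")
def calibrated_params(default_params) -> ParameterSet:
    """The shipped defaults pinned to the basal operating point (computed
    once per session; every calibration-dependent test shares it)."""
    return calibrate_all(default_params)


@pytest.fixture(scope="session")
def basal_state(calibrated_params):
    """Basal steady state (state vector, compiled network)."""
    return steady_state(calibrated_params, Scenario())


@pytest.fixture(scope="session")
def basal_traj(calibrated_params, basal_state):
    y0, _ = basal_state
    return simulate(calibrated_params, Scenario(t_end=3000.0), y0=y0)


@pytest.fixture(scope="session")
def ltd_traj(calibrated_params):
    traj, _ = run_scenario("ltd", calibrated_params)
    return traj


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160125)
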