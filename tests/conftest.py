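import numpy as np
import pytest

from monodsense import KineticParameters, default_scenario, simulate


@pytest.fixture(scope="session")
def params():
    return KineticParameters()


@pytest.fixture(scope="session")
def scenario():
    return default_scenario()


@pytest.fixture(scope="session")
def traj_default(scenario):
    """Default fed-batch ground truth (240 h, daily boluses from 72 h)."""
    return simulate(scenario.initial, scenario.params, feeds=scenario.feeds,
                    t_end=scenario.t_end, dt_out=scenario.dt_out)


@pytest.fixture(scope="session")
def traj_batch(scenario):
    """Batch (no-feed) growth phase of the default scenario."""
    return simulate(scenario.initial, scenario.params, feeds=(),
                    t_end=72.0, dt_out=0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
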