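import dataclasses

import numpy as np
import pytest

from coopnet import SimulationConfig, behavior_profile, run_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def null_params():
    return behavior_profile("null")


@pytest.fixture
def small_config(null_params):
    """A quick-to-run session: 10 agents, 6 rounds, two update phases."""
    return SimulationConfig(
        n_agents=10, density=0.4, n_rounds=6, update_interval=3, behavior=null_params, seed=7
    )


@pytest.fixture
def small_session(small_config):
    return run_session(small_config)


@pytest.fixture
def productivity_config(null_params):
    return SimulationConfig(
        n_agents=10,
        density=0.4,
        n_rounds=6,
        update_interval=3,
        baseline_inequality=True,
        wealth_productivity=True,
        behavior=null_params,
        seed=11,
    )


def null_session_config(seed: int, *, inequality: bool = False, productivity: bool = False,
                        n_agents: int = 27, n_rounds: int = 19) -> SimulationConfig:
    """Default-scale null-behavior session config, parameterized by condition."""
    return SimulationConfig(
        n_agents=n_agents,
        n_rounds=n_rounds,
        baseline_inequality=inequality,
        wealth_productivity=productivity,
        behavior=behavior_profile("null"),
        seed=seed,
    )


def replace(obj, **kwargs):
    return dataclasses.replace(obj, **kwargs)
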