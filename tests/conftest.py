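import dataclasses

import numpy as np
import pytest

from resplock import SimulationConfig, simulate_session

ZERO_GAIN = {c: 0.0 for c in SimulationConfig().channels}


def make_config(**overrides) -> SimulationConfig:
    """SimulationConfig factory with keyword overrides."""
    return dataclasses.replace(SimulationConfig(), **overrides)


def noiseless_config(**overrides) -> SimulationConfig:
    """Deterministic-signal config: no noise, no coupling, no artifacts."""
    base = dict(noise_sigma=0.0, coupling_effect=0.0, artifact_rate=0.0)
    base.update(overrides)
    return make_config(**base)


@pytest.fixture(scope="session")
def default_session():
    """One full-size session (300 trials) under study-default conditions."""
    return simulate_session(make_config(seed=2024))


@pytest.fixture(scope="session")
def small_noiseless_session():
    """A short noiseless, uncoupled, error-free session."""
    return simulate_session(noiseless_config(
        n_episodes=1, actions_per_episode=12, error_prob=0.0, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
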