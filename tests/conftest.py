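import numpy as np
import pytest

from heplpp.synth import SimConfig, simulate_subject

#: compact scalp subset covering all injected component channel sets
SMALL_CHANNELS = (
    "F5", "F3", "Fz", "F2", "F4", "F6",
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "Cz", "C4", "CP4", "CP6", "Pz",
)


@pytest.fixture(scope="session")
def small_channels():
    return SMALL_CHANNELS


@pytest.fixture(scope="session")
def small_config():
    """Study conditions at reduced problem size (channels / trials)."""
    return SimConfig(n_per_group=4, n_trials=30, channels=SMALL_CHANNELS)


@pytest.fixture(scope="session")
def sim_subject(small_config):
    """One simulated MDD-like subject shared across read-only tests."""
    return simulate_subject(small_config, "MDD", seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
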