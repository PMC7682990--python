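import numpy as np
import pytest

from pfitag import BehaviorParams, EEGParams, StimulusConfig
from pfitag.simulate import simulate_participant


@pytest.fixture(scope="session")
def small_config() -> StimulusConfig:
    return StimulusConfig(n_trials=4, trial_duration=30.0)


@pytest.fixture(scope="session")
def small_participant(small_config):
    """One simulated participant at reduced scale (4 x 30 s trials, 12
    channels), shared across tests that only read from it."""
    eeg = EEGParams(n_channels=12)
    return simulate_participant(small_config, BehaviorParams(), eeg, seed=12345)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
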