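import numpy as np
import pytest

from spade_eeg.geometry import random_spd
from spade_eeg.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spd_set(rng):
    """A dozen generic well-conditioned 5x5 SPD matrices."""
    return np.stack([random_spd(5, rng) for _ in range(12)])


@pytest.fixture
def quick_config():
    """A cheap simulation configuration for unit tests (few trials)."""
    return SimulationConfig(n_trials=5, mixing_seed=7, trial_seed=8)


@pytest.fixture
def zero_jitter_config():
    """Deterministic sources: no jitter, fixed phases."""
    return SimulationConfig(freq_jitter_hz=0.0, pulse_center_jitter_ms=0.0,
                            random_phase=False, n_trials=5,
                            mixing_seed=7, trial_seed=8)
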