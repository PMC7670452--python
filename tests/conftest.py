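import numpy as np
import pytest

from hdsemg import SimulationConfig, default_grids, simulate_recording


@pytest.fixture(scope="session")
def forearm_grid():
    return default_grids()[0]


@pytest.fixture(scope="session")
def biceps_grid():
    return default_grids()[1]


@pytest.fixture(scope="session")
def short_recording():
    """A 2 s noise-free-ish supination trial shared by map/feature tests."""
    cfg = SimulationConfig(seed=42, duration=2.0, task="supination",
                           effort=50, noise_rms=0.01, line_amp=0.0,
                           gain_jitter=0.0, amplitude_drift=0.0)
    return simulate_recording(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
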