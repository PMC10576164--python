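import numpy as np
import pytest

from odegp import RhythmDataset
from odegp.gp_regression import OptimizerConfig


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def sine_dataset():
    """Noiseless 24 h sine, 0..48 h every 3 h, three identical replicates."""
    t = np.arange(0, 49, 3.0)
    y = np.sin(2 * np.pi * t / 24.0)
    return RhythmDataset(times=t, values=np.tile(y[:, None], (1, 3)), label="sine24")


@pytest.fixture
def noise_dataset(rng):
    t = np.arange(0, 49, 3.0)
    return RhythmDataset(
        times=t, values=rng.normal(0, 1, (t.size, 3)), label="noise"
    )


@pytest.fixture
def fast_config():
    """Reduced-restart optimizer settings for unit tests."""
    return OptimizerConfig(n_restarts=3, seed=7, maxiter=80)
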