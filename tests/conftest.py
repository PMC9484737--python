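import numpy as np
import pytest

from eegensemble.detector import ArchitectureConfig


@pytest.fixture(scope="session")
def toy_arch():
    """Micro architecture for fast training tests (128-sample inputs)."""
    return ArchitectureConfig(
        conv_channels=(4, 8), kernel=5, pool=4, attention_hidden=4,
        input_samples=128,
    )


def make_rhythm_task(
    n: int,
    n_channels: int = 2,
    length: int = 128,
    f0_range: tuple[float, float] = (2.0, 6.0),
    amp: float = 2.0,
    seed: int = 0,
):
    """Separable toy task: colored noise vs noise + rhythmic burst.

    Returns (segments, labels).  Class 1 adds a sinusoidal discharge on one
    channel; the per-channel standardization inside the detector removes
    amplitude shortcuts, so the network must learn the rhythm.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, n_channels, length))
    # mild temporal correlation so class 0 is not pure white noise
    x[:, :, 1:] += 0.5 * x[:, :, :-1]
    y = (rng.uniform(size=n) < 0.5).astype(int)
    t = np.arange(length) / 32.0
    for i in np.flatnonzero(y):
        f0 = rng.uniform(*f0_range)
        ch = rng.integers(n_channels)
        x[i, ch] += amp * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
    return x, y


@pytest.fixture(scope="session")
def rhythm_task():
    return make_rhythm_task(n=240, seed=42)
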