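import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def seasonal_series(rng):
    """Noisy 26-week seasonal series at count scale, N=256."""
    t = np.arange(256)
    return 1000.0 + 80.0 * np.sin(2 * np.pi * t / 26) + 20.0 * rng.standard_normal(256)
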