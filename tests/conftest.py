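import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cosine_pair():
    """6-Hz cosine and its pi/4-lagged copy, 3.5 s at 500 Hz."""
    fs = 500.0
    t = np.arange(int(3.5 * fs)) / fs
    a = np.cos(2 * np.pi * 6.0 * t)
    b = np.cos(2 * np.pi * 6.0 * t - np.pi / 4)
    return a, b, fs
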