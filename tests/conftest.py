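import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_pair(rng):
    """Independent white-noise channel pair, 30 s at 500 Hz."""
    fs = 500.0
    n = int(30 * fs)
    return rng.standard_normal(n), rng.standard_normal(n), fs
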