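import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """A generic 16×16 8-bit test texture."""
    return rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
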