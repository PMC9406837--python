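import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_rgb(rng):
    """Factory for random RGB images with values in [0, 255]."""

    def make(h=16, w=16):
        return rng.uniform(0.0, 255.0, size=(h, w, 3))

    return make


@pytest.fixture
def random_gray(rng):
    def make(h=8, w=8):
        return rng.uniform(0.0, 255.0, size=(h, w))

    return make
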