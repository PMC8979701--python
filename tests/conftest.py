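import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_images(rng):
    """A batch of 6 random 16x16 RGB images in [0, 1]."""
    return rng.random((6, 16, 16, 3)).astype(np.float32)
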