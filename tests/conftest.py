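import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20230912)


@pytest.fixture
def random_image(rng):
    """A generic 64x64 float image on the display scale."""
    return rng.uniform(0.0, 255.0, size=(64, 64))
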