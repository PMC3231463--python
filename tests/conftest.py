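import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20090531)


@pytest.fixture
def random_masks(rng):
    """A batch of random small binary masks with varied densities."""

    def make(n=100, shape=(16, 16)):
        for _ in range(n):
            density = rng.uniform(0.1, 0.9)
            yield rng.random(shape) < density

    return make
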