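import numpy as np
import pytest

from fioseg import PhantomParams, generate_pair


@pytest.fixture
def rng():
    return np.random.default_rng(20210520)


@pytest.fixture(scope="session")
def small_phantoms():
    """Ten default-parameter phantoms with distinct seeds."""
    return [generate_pair(PhantomParams(seed=100 + i)) for i in range(10)]


def random_mask(rng, h, w, structured=False):
    """A random {1,2} mask; `structured` gives a blob instead of salt."""
    if structured:
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(1.0, max(h, w) / 2 + 1.0)
        return np.where((yy - cy) ** 2 + (xx - cx) ** 2 <= r**2, 2, 1)
    return rng.integers(1, 3, size=(h, w))
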