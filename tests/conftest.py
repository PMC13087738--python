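import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    """A (1, 1, 4, 5, 6) random hyperstack for slicing tests."""
    from termstack import FixtureSpec, make_hyperstack

    return make_hyperstack(
        FixtureSpec(shape=(1, 1, 4, 5, 6), pattern="random", dtype="uint8", seed=7)
    )


@pytest.fixture
def coord_volume():
    """Volume with value(z, y, x) = 100z + 10y + x for index bookkeeping."""
    from termstack import MultiDimImage

    z, y, x = np.indices((2, 3, 4))
    data = (100 * z + 10 * y + x).astype(np.uint16)[None, None]
    return MultiDimImage(data)
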