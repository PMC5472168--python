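import numpy as np
import pytest

from shadecorr.synthetic import simulate_collection, make_flatfield


@pytest.fixture(scope="session")
def small_scene():
    """A compact medium-density collection used by several test modules."""
    return simulate_collection(8, density_level="medium", shape=(64, 64), seed=11)


@pytest.fixture(scope="session")
def smooth_flatfield_64():
    return make_flatfield(64, 64, strength=0.3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
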