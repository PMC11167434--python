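import numpy as np
import pytest

from emomap.silhouette import make_body_template
from emomap.types import GridSpec, SEGMENTS


@pytest.fixture(scope="session")
def template():
    return make_body_template()


@pytest.fixture(scope="session")
def grid():
    return GridSpec()


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(shape=(16, 16, 12))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240518)


def random_binary_map(rng, shape, p=0.3):
    return (rng.random(shape) < p).astype(np.uint8)
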