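import numpy as np
import pytest

from glomopaint.fixtures import make_fixture_crops, make_fixture_slide


@pytest.fixture(scope="session")
def fixture_slide():
    return make_fixture_slide(512, 512, n_normal=3, n_sclerosed=3, seed=11)


@pytest.fixture(scope="session")
def fixture_crops_64():
    return make_fixture_crops(8, size=64, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
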