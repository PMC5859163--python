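import numpy as np
import pytest

from phaeotools import taxonomy
from phaeotools.simulate import desk_scale_scheme


@pytest.fixture(scope="session")
def scheme():
    return taxonomy.default_scheme()


@pytest.fixture(scope="session")
def small_scheme():
    """Ten sub-categories, two per group over five groups."""
    return desk_scale_scheme()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
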