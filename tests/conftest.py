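import numpy as np
import pytest

from sdi3d import SphereDomain


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def sphere30():
    """The synthetic benchmark domain: ball of radius 30 (voxel units)."""
    return SphereDomain(30.0)


@pytest.fixture(scope="session")
def sphere10():
    return SphereDomain(10.0)
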