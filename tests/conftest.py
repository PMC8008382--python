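import numpy as np
import pytest

from fieldqsar.fields import assemble_descriptor_matrix
from fieldqsar.fixtures import make_default_fixture


@pytest.fixture(scope="session")
def default_fixture():
    """The standard planted-signal study: 25 molecules, noise 0.1 log units."""
    return make_default_fixture(seed=0)


@pytest.fixture(scope="session")
def default_xy(default_fixture):
    fx = default_fixture
    dm = assemble_descriptor_matrix([fx.steric, fx.electrostatic], "Both")
    y = fx.ds.p_values()
    return dm, y


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
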