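import numpy as np
import pytest

import oculostop as oc
from oculostop import dcm_network as dcm


@pytest.fixture(scope="session")
def structure():
    return oc.build_structure()


@pytest.fixture(scope="session")
def base_params(structure):
    return oc.default_dcm_parameters(structure)


@pytest.fixture(scope="session")
def hemo():
    return dcm.HemodynamicParameters()


@pytest.fixture(scope="session")
def small_design():
    """Short single-run design used by the fast network unit tests."""
    return oc.make_design(80, dt=0.05, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
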