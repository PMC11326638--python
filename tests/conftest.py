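import numpy as np
import pytest

from iitbounds import SystemTPM, copy_system
from iitbounds.tpm import Mechanism, Purview


@pytest.fixture
def copy2():
    return copy_system(2)


@pytest.fixture
def copy3():
    return copy_system(3)


@pytest.fixture
def and_pair():
    """Two units, both computing A AND B."""
    return SystemTPM(np.array([[0., 0.], [0., 0.], [0., 0.], [1., 1.]]))


@pytest.fixture
def constant_on():
    """Two units: unit 0 is constantly ON, unit 1 copies itself."""
    probs = np.zeros((4, 2))
    probs[:, 0] = 1.0
    probs[:, 1] = [0, 0, 1, 1]
    return SystemTPM(probs)


def mech(units, state):
    return Mechanism(tuple(units), tuple(state))


def pv(units, state=None):
    return Purview(tuple(units), None if state is None else tuple(state))


@pytest.fixture
def rng():
    return np.random.default_rng(20240805)
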