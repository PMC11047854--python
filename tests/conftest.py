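import numpy as np
import pytest

import flapwing as fw


@pytest.fixture(scope="session")
def lattice():
    return fw.D3Q27


@pytest.fixture(scope="session")
def default_kinematics():
    return fw.WingKinematics()


@pytest.fixture(scope="session")
def default_wing():
    return fw.PhysicalWing()


@pytest.fixture
def rng():
    return np.random.default_rng(20240420)
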