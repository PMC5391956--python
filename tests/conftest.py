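import numpy as np
import pytest

from gaitrig import GaitCommand, simulate_gait, simulate_rig
from gaitrig.config import PipelineConfig
from gaitrig.simulate import default_marker_poses


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_rig():
    return simulate_rig()


@pytest.fixture(scope="session")
def marker_poses():
    return default_marker_poses()


@pytest.fixture(scope="session")
def default_cmd():
    return GaitCommand()


@pytest.fixture(scope="session")
def default_truth(default_cmd):
    return simulate_gait(default_cmd)


@pytest.fixture
def cfg():
    return PipelineConfig()
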