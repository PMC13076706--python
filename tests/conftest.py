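import numpy as np
import pytest

from mwibone.mapping import AcquisitionGeometry
from mwibone.probe_model import ProbeParams
from mwibone.sensitivity import DepthProfile, RadialKernel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def probe_params():
    return ProbeParams(c0=25e-15, cf=20e-15)


@pytest.fixture
def geometry():
    return AcquisitionGeometry()


@pytest.fixture
def kernel():
    return RadialKernel.gaussian(2.0)


@pytest.fixture
def depth_profile():
    # calibrated so the depth factor at the 8-mm hole depth is 0.16875
    return DepthProfile.from_depth_factor(0.16875, 8.0)


@pytest.fixture
def sweep_freqs():
    return np.linspace(2.25e9, 3.0e9, 101)
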