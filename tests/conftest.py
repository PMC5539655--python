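import numpy as np
import pytest

from tofbench import PendulumRig, ToFSensorSpec


@pytest.fixture
def noiseless_spec() -> ToFSensorSpec:
    """Sensor with no noise and no bias: pure quantization + gating."""
    return ToFSensorSpec(noise_sd_mm=0.0, bias_table_mm={0.0: 0.0})


@pytest.fixture
def default_spec() -> ToFSensorSpec:
    return ToFSensorSpec()


@pytest.fixture
def rig_aoi0() -> PendulumRig:
    return PendulumRig(imposed_distance_mm=100.0, aoi_deg=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
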