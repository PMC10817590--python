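import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oculotex.cohort import ParticipantRecord
from oculotex.config import VolumeConfig

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def participant():
    return ParticipantRecord("F001", "female", 43.0)


@pytest.fixture
def fast_vconfig():
    """Full en-face grid, shallow depth: quick to generate, still compatible
    with the 128x512 texture pipeline."""
    return VolumeConfig(
        n_depth=16,
        layer_mean_thickness=(1.0, 2.0, 1.0, 1.0, 1.0, 2.0),
        foveal_dip_depth=3.0,
        foveal_dip_radius=6.0,
    )


@pytest.fixture
def tiny_vconfig():
    """Small en-face grid for I/O and geometry tests (not texture-sized)."""
    return VolumeConfig(
        n_bscan=8, n_ascan=32, n_depth=16,
        layer_mean_thickness=(1.0, 2.0, 1.0, 1.0, 1.0, 2.0),
        foveal_dip_depth=3.0, foveal_dip_radius=2.0,
    )
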