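import numpy as np
import pytest

from roipower import CohortSpec, make_toy_forward_model


@pytest.fixture(scope="session")
def toy_model():
    """8 sensors, 20 sources, 4 ROIs of 5 sources each."""
    return make_toy_forward_model(8, 20, 4, seed=3)


@pytest.fixture(scope="session")
def roi_model():
    """One source per ROI, 12 ROIs — for bypass-level tests."""
    return make_toy_forward_model(8, 12, 12, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_spec():
    """Small, fast study conditions for generator-driven tests."""
    return CohortSpec(duration_s=5.0, fs_hz=200.0)
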