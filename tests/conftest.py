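import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eqctta import CTSlice, ROIMask

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_slice():
    """64x64 constant 50 HU slice at 0.7 mm spacing."""
    return CTSlice(np.full((64, 64), 50.0), (0.7, 0.7), "pre", "p1", "hepatic_porta")


@pytest.fixture
def random_slice(rng):
    pix = rng.uniform(-100.0, 200.0, (64, 64))
    return CTSlice(pix, (0.7, 0.7), "pre", "p1")


@pytest.fixture
def central_mask(flat_slice):
    m = np.zeros((64, 64), dtype=bool)
    m[8:56, 8:56] = True
    return ROIMask.from_slice(m, "whole_liver", flat_slice)
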