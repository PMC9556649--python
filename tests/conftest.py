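import numpy as np
import pytest
from hypothesis import settings

from hotspotkit import full_grid

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def grid10():
    """A fully masked 10×10 grid of 1-km cells."""
    return full_grid(10, 10, 1.0)


@pytest.fixture
def grid50():
    return full_grid(50, 50, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
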