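import numpy as np
import pytest

from lssnet import autograd


@pytest.fixture
def float64_engine():
    """Run the autograd engine in float64 (tight-tolerance oracle tests)."""
    autograd.set_default_dtype(np.float64)
    yield
    autograd.set_default_dtype(np.float32)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
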