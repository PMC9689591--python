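import numpy as np
import pytest

from mifnn.autodiff import default_dtype


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def float64():
    """Run the autodiff engine in float64 for tight numerical comparisons."""
    with default_dtype(np.float64):
        yield
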