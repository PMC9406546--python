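import numpy as np
import pytest

from mammodense.nn import tensor as _tensor_mod


@pytest.fixture
def float64_engine():
    """Run the autodiff engine in float64 (for finite-difference checks)."""
    old = _tensor_mod.get_default_dtype()
    _tensor_mod.set_default_dtype(np.float64)
    yield
    _tensor_mod.set_default_dtype(old)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
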