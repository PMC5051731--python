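import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_rwd_params():
    """Reduced-scale RWD configuration for fast unit tests."""
    from asterdrift.rwd import RwdParams
    return RwdParams(T=600.0, dt=0.1, N_p=20, seed=7)
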