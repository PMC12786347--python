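import numpy as np
import pytest

from wbsim import BEIParams, synthetic_connectome


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_connectome():
    """10-node synthetic connectome with tract lengths."""
    return synthetic_connectome(10, density=0.4, weight_scale=1.0,
                                length_range=(20.0, 120.0), seed=7)


@pytest.fixture
def bei_params():
    return BEIParams()
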