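import numpy as np
import pytest

from valenceloop.valence_ssm import ValenceParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    """Parameter set used throughout the recovery experiments."""
    return ValenceParams(alpha=0.3, beta=0.5, sigma_eps2=0.005,
                         sigma_omega2=0.01, gamma=-1.0, x0=0.0)
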