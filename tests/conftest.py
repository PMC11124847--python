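import numpy as np
import pytest
from hypothesis import settings

from otterlab.physics import MaterialProps, OpticalPair

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def material():
    return MaterialProps(D=1e-7)


@pytest.fixture(scope="session")
def optical():
    return OpticalPair(beta_w=2.5e5, beta_d=5e4)


@pytest.fixture(scope="session")
def grid():
    """A shared 0..20*tau grid for a 1 ms lifetime."""
    return np.linspace(0.0, 0.02, 256)
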