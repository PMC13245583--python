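import numpy as np
import pytest

from oxibold import (
    AcquisitionConfig,
    DEFAULT_CONSTANTS,
    make_digital_phantom,
    simulate_ausfide,
    simulate_pcasl,
    simulate_vsvsl,
)
from oxibold.priors import fit_all_priors


@pytest.fixture(scope="session")
def acq():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def constants():
    return DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def phantom():
    """Small full-label phantom shared by read-only tests."""
    return make_digital_phantom((16, 16, 16), seed=0)


@pytest.fixture(scope="session")
def noiseless_sims(phantom, acq):
    aus = simulate_ausfide(phantom, acq)
    vs = simulate_vsvsl(phantom, acq)
    pc = simulate_pcasl(phantom, acq)
    return aus, vs, pc


@pytest.fixture(scope="session")
def noiseless_priors(phantom, acq, noiseless_sims):
    aus, vs, pc = noiseless_sims
    return fit_all_priors(aus, vs, pc, acq, phantom.brain_mask)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
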