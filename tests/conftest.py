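import numpy as np
import pytest

import cstomo as ct


@pytest.fixture(scope="session")
def standard_fixture():
    """The pinned noisy missing-wedge phantom case (64^2, +/-60 deg, 3 deg)."""
    return ct.make_fixture("standard_noisy_phantom")


@pytest.fixture(scope="session")
def fixture_wbp(standard_fixture):
    _, ts, geom = standard_fixture
    return ct.wbp_reconstruct(ts, geom)


@pytest.fixture(scope="session")
def fixture_cstv2(standard_fixture):
    _, ts, geom = standard_fixture
    cfg = ct.SolverConfig(lam=ct.phantom.FIXTURE_LAMBDA, iterations=200)
    vol, state = ct.cstv2_reconstruct(ts, geom, cfg)
    return vol, state


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
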