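import numpy as np
import pytest

import quasiburst as qb


@pytest.fixture(scope="session")
def table1():
    """Canonical parameter set (gamma-band transient synchrony)."""
    return qb.DEFAULT_PARAMS


@pytest.fixture(scope="session")
def working_points():
    return qb.WORKING_POINTS


@pytest.fixture(scope="session")
def reduced_points():
    """Envelope-phase reduction at the four standard working points."""
    return {name: qb.reduce_params(p) for name, p in qb.WORKING_POINTS.items()}


@pytest.fixture(scope="session")
def point_b_sam():
    """A medium-length seeded envelope/LFP realisation at the intermediate
    working point, shared by burst and signal tests."""
    red = qb.reduce_params(qb.WORKING_POINTS["point_b"])
    sim = qb.simulate_sam(red, duration=120_500.0, dt=0.05, seed=2024)
    return red, sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
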