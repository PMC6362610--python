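import numpy as np
import pytest

from mered import ParameterSet, make_fixture


@pytest.fixture(scope="session")
def recovery_small():
    """Small constant-truth simulated dataset with its generative config."""
    return make_fixture("recovery_small")


@pytest.fixture(scope="session")
def perfect_detection():
    """Simulated dataset where every live animal is always detected."""
    return make_fixture("perfect_detection")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_params(rng, T, interior=False):
    """Random real-scale parameter set; ``interior`` keeps values off 0/1."""
    lo, hi = (0.05, 0.95) if interior else (0.0, 1.0)

    def draw():
        return rng.uniform(lo, hi, size=1)[0]

    return ParameterSet(
        T,
        phi_b=draw(), phi_nb=draw(), psi_bb=draw(), psi_nbb=draw(),
        m_b=draw(), m_nb=draw(), p_u=draw(), b_e=draw(),
    )
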