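import numpy as np
import pytest

from vestib_design import (
    DesignSpace,
    NOMINAL_THETA,
    PhysicalConstants,
    d_optimal_continuous,
    d_optimal_finite,
)


@pytest.fixture(scope="session")
def constants():
    return PhysicalConstants()


@pytest.fixture(scope="session")
def theta():
    return NOMINAL_THETA


@pytest.fixture(scope="session")
def finite_space():
    return DesignSpace()


@pytest.fixture(scope="session")
def cont_space():
    return DesignSpace("continuous")


@pytest.fixture(scope="session")
def xi1(finite_space, theta, constants):
    """Discrete D-optimal design at nominal parameters (shared: deterministic)."""
    return d_optimal_finite(finite_space, theta, constants)


@pytest.fixture(scope="session")
def xi2(cont_space, theta, constants):
    """Continuous D-optimal design at nominal parameters."""
    return d_optimal_continuous(cont_space, theta, constants)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20130319)
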