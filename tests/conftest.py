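import numpy as np
import pytest

from ierl import build_design, simulate_agent


@pytest.fixture(scope="session")
def m22():
    return build_design("M22")


@pytest.fixture(scope="session")
def b21_cci():
    return build_design("B21", "CCI")


@pytest.fixture(scope="session")
def b18_partial():
    return build_design("B18", "1")


@pytest.fixture(scope="session")
def g12():
    return build_design("G12")


@pytest.fixture(scope="session")
def m22_records(m22):
    """One moderately greedy intrinsic-model agent on the M22 task."""
    params = {
        "alpha_c": 0.3,
        "alpha_u": 0.25,
        "beta_learn": 6.0,
        "beta_test": 6.0,
        "omega_learn": 0.7,
    }
    return simulate_agent("intrinsic", params, m22, seed=1234)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
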