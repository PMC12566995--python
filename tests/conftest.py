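import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import extopt as e
from extopt.reference import EQ_BRANCHES_TPC, EQ_LEAVES_DPPH, FACTORS_LEAVES

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ccrd3():
    """The study design: 3 factors, 8 factorial + 6 axial + 3 center runs."""
    return e.make_ccrd(3, n_center=3, alpha_mode="rotatable")


@pytest.fixture(scope="session")
def leaves_factors():
    return FACTORS_LEAVES


@pytest.fixture(scope="session")
def eq1_model():
    """Published reduced model for leaves DPPH (printed 2-dp coefficients)."""
    return e.QuadraticModel.from_coefficients(EQ_LEAVES_DPPH, 3, response_name="DPPH")


@pytest.fixture(scope="session")
def eq2_model():
    """Published reduced model for thin-branch TPC."""
    return e.QuadraticModel.from_coefficients(EQ_BRANCHES_TPC, 3, response_name="TPC")


@pytest.fixture()
def noisy_leaves_study(ccrd3):
    """Synthetic responses from the published leaves surface at the
    pure-error noise level, fixed seed."""
    cfg = e.SyntheticConfig(EQ_LEAVES_DPPH, ccrd3, noise_sd=1.79, seed=42)
    return ccrd3, e.generate_responses(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
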