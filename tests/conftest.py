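import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import srnafb as sf

settings.register_profile(
    "ci", max_examples=25, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cal_params() -> sf.CircuitParams:
    """Calibrated default ground truth (92% knockdown at saturating u2)."""
    return sf.calibrate_defaults()


@pytest.fixture(scope="session")
def closed_params() -> sf.CircuitParams:
    return sf.default_params(sf.CLOSED_LOOP_INDUCIBLE)


@pytest.fixture(scope="session")
def linear_params(cal_params) -> sf.CircuitParams:
    """No repression (K_R huge), no sRNA binding: fully linear kinetics."""
    return cal_params.with_updates(K_R=1e12, k=0.0, b1=0.0)


def random_params(rng: np.random.Generator) -> sf.CircuitParams:
    """A random valid parameter set for property tests."""
    return sf.CircuitParams(
        a0=rng.uniform(0, 0.1), a1=rng.uniform(0.1, 5),
        K_R=rng.uniform(10, 1000), n_R=rng.uniform(1, 4),
        K_A=rng.uniform(10, 1000), n_A=rng.uniform(1, 4),
        theta1=rng.uniform(1, 100), n1=rng.uniform(1, 4),
        theta2=10 ** rng.uniform(-5, -3), n2=rng.uniform(1, 4),
        theta3=rng.uniform(0.05, 1), n3=rng.uniform(1, 3),
        b0=rng.uniform(0, 0.1), b1=rng.uniform(0.1, 300),
        kappa=rng.uniform(1, 30), k=10 ** rng.uniform(-3, 0),
        delta_m=rng.uniform(0.05, 1), delta_s=rng.uniform(0.05, 1),
        delta_c=rng.uniform(0.05, 1), delta_p=rng.uniform(0.005, 0.1),
        omega=rng.uniform(0.5, 20),
    )
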