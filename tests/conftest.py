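import numpy as np
import pytest

from nessland.simulate import analytic_sample_set
from nessland.systems import DynamicalSystem, make_rotational_toy, twelve_dim_gmm


@pytest.fixture(scope="session")
def ou_1d():
    """1D Ornstein-Uhlenbeck system dx = -x dt + sqrt(2D) dw."""
    return DynamicalSystem(
        dim=1,
        drift=lambda x: -np.atleast_2d(x).astype(float),
        drift_divergence=lambda x: -np.ones(len(np.atleast_2d(x))),
        analytic_potential=lambda x: 0.5 * np.atleast_2d(x)[:, 0] ** 2,
        analytic_sampler=lambda n, D, rng: np.sqrt(D) * rng.standard_normal((n, 1)),
        name="ou1d")


@pytest.fixture(scope="session")
def toy_c1():
    """2D rotational toy, quadratic well, rotation strength c = 1."""
    return make_rotational_toy("quadratic", c=1.0)


@pytest.fixture(scope="session")
def gmm12():
    return twelve_dim_gmm(D=0.1)


@pytest.fixture(scope="session")
def toy_samples_exact(toy_c1):
    """Exact steady samples of the rotational toy at D = 0.1."""
    return analytic_sample_set(toy_c1, D=0.1, n=20000, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
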