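import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rgmnet as rg

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_truth():
    """One fixed p=5 benchmark scenario, reused across read-only tests."""
    return rg.simulate(rg.SimulationDesign(p=5, n=2000, seed=11))


@pytest.fixture(scope="session")
def small_fit(small_truth):
    """A short fit on the fixed scenario (1200 iterations)."""
    cfg = rg.SamplerConfig(nIter=1200, nBurnin=400, seed=5)
    return rg.run_mcmc(small_truth.data, small_truth.D, cfg)


def random_structural(rng, p, k, max_effect=0.3):
    """Random valid structural parameters for likelihood tests."""
    while True:
        A = rng.normal(0.0, max_effect, (p, p))
        np.fill_diagonal(A, 0.0)
        if abs(np.linalg.det(np.eye(p) - A)) > 1e-6:
            break
    B = rng.normal(0.0, 0.5, (p, k))
    sigma2 = rng.uniform(0.3, 2.0, p)
    return rg.StructuralParameters(A=A, B=B, sigma2=sigma2)


def individual_loglik_oracle(theta, X, Y):
    """Brute-force per-observation Gaussian log-likelihood of the
    structural residuals e_t = (I - A) y_t - B x_t, plus the Jacobian."""
    n, p = Y.shape
    M = np.eye(p) - theta.A
    E = Y @ M.T - X @ theta.B.T
    ld = np.linalg.slogdet(M)[1]
    return (
        n * ld
        - 0.5 * n * np.sum(np.log(2 * np.pi * theta.sigma2))
        - 0.5 * np.sum(E**2 / theta.sigma2)
    )
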