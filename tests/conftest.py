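import numpy as np
import pytest

from mr2.data import StandardizedData, SummaryData
from mr2.simulate import ScenarioConfig, extract_summary, simulate_individual


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_summary():
    """3 variants, 2 exposures, 2 outcomes with hand-set values."""
    return SummaryData(
        variant_ids=["rs1", "rs2", "rs3"],
        exposure_names=["X1", "X2"],
        outcome_names=["Y1", "Y2"],
        beta_x=[[0.1, -0.2], [0.3, 0.05], [-0.15, 0.4]],
        se_x=[[0.01, 0.02], [0.015, 0.01], [0.02, 0.03]],
        beta_y=[[0.05, 0.02], [-0.01, 0.1], [0.2, -0.3]],
        se_y=[[0.05, 0.04], [0.06, 0.05], [0.04, 0.06]])


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size scenario for unit tests (fast to simulate)."""
    return ScenarioConfig(scenario="II_confounding", n_variants=40,
                          n_exposures=6, n_outcomes=3,
                          n_individuals=20_000, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    ind = simulate_individual(small_config)
    return ind, extract_summary(ind, small_config)


def make_standardized(rng, n=30, p=2, q=1, theta=None, sigma=None):
    """Plain Gaussian regression data wrapped as StandardizedData."""
    X = rng.normal(size=(n, p))
    theta = np.zeros((q, p)) if theta is None else np.atleast_2d(theta)
    sigma = np.eye(q) if sigma is None else np.atleast_2d(sigma)
    E = rng.normal(size=(n, q)) @ np.linalg.cholesky(sigma).T
    Y = X @ theta.T + E
    return StandardizedData(X, Y, np.ones(n), "none")
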