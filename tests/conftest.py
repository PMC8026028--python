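import numpy as np
import pytest

from fixopt import ModelParams, Theta, UCBConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


#: Group-level fitted means of the joint binary/trinary fits; used as the
#: reference parameterization throughout the behavioral checks.
PAPER_THETA = Theta(
    sigma_x=2.60, gamma_sample=0.00373, gamma_switch=0.00995,
    beta=364.0, alpha=0.581,
)

#: Small search budget used wherever a policy ensemble is needed in tests.
SMALL_UCB = UCBConfig(
    n_boxes_per_dim=6, n_baseline=16, top_k=8, n_refine=8, n_iterations=40
)


@pytest.fixture(scope="session")
def paper_theta():
    return PAPER_THETA


@pytest.fixture(scope="session")
def small_ucb_config():
    return SMALL_UCB


def random_beliefs(rng, n, n_items, mu_scale=2.0, lam_max=60.0):
    """Random belief arrays (mu, lam) used by property tests."""
    mu = rng.normal(0.0, mu_scale, (n, n_items))
    lam = 1.0 + rng.random((n, n_items)) * (lam_max - 1.0)
    return mu, lam
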