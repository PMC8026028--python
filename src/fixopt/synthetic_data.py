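"""Synthetic rating pools, trial tables and model-generated datasets.

The source experiments had participants rate 70 snack items on an
integer -10..10 liking scale and then make 100 choices among items they
had rated positively, while fixations were tracked.  This module emulates
those study conditions without any download: rating pools are integer
draws from a discretized truncated normal whose post-truncation moments
match the published empirical moments (binary arm 3.492 +/- 2.631,
trinary arm 4.295 +/- 2.524), trials sample distinct positively rated
items, and "human-like" datasets are produced by simulating one episode
per trial from a near-optimal policy ensemble at a known parameter vector
(the ground truth for parameter-recovery exercises).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import norm

from ._ucb import UCBConfig
from .fitting import Theta
from .policy_opt import PolicySet, ucb_policy_search
from .simulate import (
    ObservedTrial,
    PriorSpec,
    Trial,
    simulate_dataset,
)

__all__ = [
    "RatingMoments",
    "BINARY_MOMENTS",
    "TRINARY_MOMENTS",
    "SyntheticConfig",
    "generate_rating_pool",
    "generate_trials",
    "generate_human_like_dataset",
]

RATING_MIN, RATING_MAX = -10, 10


@dataclass(frozen=True)
class RatingMoments:
    """Published mean/SD of a dataset's liking-rating distribution."""

    mean: float
    sd: float


BINARY_MOMENTS = RatingMoments(mean=3.492, sd=2.631)
TRINARY_MOMENTS = RatingMoments(mean=4.295, sd=2.524)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset arm."""

    arm: str = "binary"  # "binary" or "trinary"
    n_trials: int = 100
    rating_mean: float = BINARY_MOMENTS.mean
    rating_sd: float = BINARY_MOMENTS.sd
    positive_only: bool = True
    n_pool_items: int = 70

    def __post_init__(self) -> None:
        if self.arm not in ("binary", "trinary"):
            raise ValueError("arm must be 'binary' or 'trinary'")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not self.rating_sd > 0:
            raise ValueError("rating_sd must be positive")

    @property
    def n_items(self) -> int:
        return 2 if self.arm == "binary" else 3

    @classmethod
    def for_arm(cls, arm: str, **kw) -> "SyntheticConfig":
        mom = BINARY_MOMENTS if arm == "binary" else TRINARY_MOMENTS
        return cls(arm=arm, rating_mean=mom.mean, rating_sd=mom.sd, **kw)


def _discrete_pmf(mu: float, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """PMF of round(truncated Normal(mu, sigma)) on the integer scale."""
    k = np.arange(RATING_MIN, RATING_MAX + 1, dtype=float)
    upper = np.minimum(k + 0.5, RATING_MAX + 0.5)
    lower = np.maximum(k - 0.5, RATING_MIN - 0.5)
    p = norm.cdf(upper, mu, sigma) - norm.cdf(lower, mu, sigma)
    total = p.sum()
    if total <= 0:
        raise ValueError("degenerate latent distribution")
    return k, p / total


def _pmf_moments(mu: float, sigma: float) -> tuple[float, float]:
    k, p = _discrete_pmf(mu, sigma)
    m = float(p @ k)
    sd = float(np.sqrt(p @ (k - m) ** 2))
    return m, sd


def generate_rating_pool(
    n_items: int = 70,
    mean: float = BINARY_MOMENTS.mean,
    sd: float = BINARY_MOMENTS.sd,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Integer liking ratings whose distribution matches target moments.

    The latent normal's (mu, sigma) are tuned so that after discretizing
    to the -10..10 scale the distribution's mean and SD land within 0.15
    of the targets; pool entries are then iid draws from that PMF.
    Raises if the targets are infeasible on this support.
    """
    if not sd > 0:
        raise ValueError("sd must be positive")
    rng = rng or np.random.default_rng()

    def resid(x):
        m, s = _pmf_moments(x[0], x[1])
        return [m - mean, s - sd]

    sol = least_squares(
        resid, x0=[mean, sd], bounds=([RATING_MIN - 5, 0.1], [RATING_MAX + 5, 15.0])
    )
    m, s = _pmf_moments(*sol.x)
    if abs(m - mean) > 0.15 or abs(s - sd) > 0.15:
        raise ValueError(
            f"targets ({mean}, {sd}) infeasible on the integer -10..10 scale"
        )
    k, p = _discrete_pmf(*sol.x)
    return rng.choice(k.astype(int), size=n_items, p=p)


def generate_trials(
    pool: np.ndarray,
    arm: str,
    n_trials: int = 100,
    positive_only: bool = True,
    rng: np.random.Generator | None = None,
) -> list[Trial]:
    """Choice trials of N distinct pool items with randomized positions."""
    rng = rng or np.random.default_rng()
    n = 2 if arm == "binary" else 3
    pool = np.asarray(pool)
    eligible = pool[pool > 0] if positive_only else pool
    if eligible.size < n:
        raise ValueError("pool does not contain enough eligible items")
    idx_pool = np.arange(eligible.size)
    trials = []
    for t in range(n_trials):
        picks = rng.choice(idx_pool, size=n, replace=False)
        trials.append(Trial(trial_id=t, ratings=tuple(int(eligible[i]) for i in picks)))
    return trials


def generate_human_like_dataset(
    theta_star: Theta,
    trials: list[Trial],
    rng: np.random.Generator | None = None,
    ucb_config: UCBConfig | None = None,
    policy_set: PolicySet | None = None,
    max_samples: int = 2000,
) -> tuple[list[ObservedTrial], dict]:
    """Simulate one episode per trial at a known parameter vector.

    Optimizes a policy ensemble at ``theta_star`` (unless one is passed
    in), standardizes ratings through the trials' own pooled empirical
    moments, and simulates each trial once with a policy drawn uniformly
    from the ensemble -- the aggregate-of-near-optimal-policies reading of
    behavior.  Returns the observed-format trials plus a ground-truth
    record (parameters, prior moments, seeds) for recovery exercises.
    """
    if not trials:
        raise ValueError("need at least one trial")
    rng = rng or np.random.default_rng()
    n_items = trials[0].n_items
    params = theta_star.model_params(n_items, max_samples=max_samples)
    if policy_set is None:
        policy_set = ucb_policy_search(
            params, theta_star.beta, ucb_config, rng
        )
    pooled = np.concatenate([np.asarray(t.ratings, float) for t in trials])
    prior = PriorSpec(
        alpha=theta_star.alpha,
        rating_mean=float(pooled.mean()),
        rating_sd=float(pooled.std(ddof=1)),
    )
    sims = simulate_dataset(policy_set, trials, prior, n_sims_per_policy=1, rng=rng)
    # keep one episode per trial, from a uniformly drawn ensemble member
    by_trial: dict[int, list] = {}
    for s in sims:
        by_trial.setdefault(s.trial_id, []).append(s)
    observed = []
    for t in trials:
        pick = by_trial[t.trial_id][int(rng.integers(len(policy_set)))]
        observed.append(
            ObservedTrial(
                trial_id=t.trial_id,
                ratings=t.ratings,
                fixations=pick.fixations,
                choice=pick.choice,
            )
        )
    truth = {
        "theta_star": asdict(theta_star),
        "prior": asdict(prior),
        "n_trials": len(trials),
        "n_items": n_items,
        "n_policies": len(policy_set),
    }
    return observed, truth
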