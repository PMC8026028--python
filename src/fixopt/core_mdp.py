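"""Metalevel MDP for value-based choice with attention-gated sampling.

The decision maker (DM) holds an independent Gaussian belief about each
item's subjective value, and at each time step either draws a noisy value
sample from the currently attended item or terminates and chooses the item
with the highest posterior mean.  Sampling costs ``gamma_sample`` per
sample, plus ``gamma_switch`` whenever attention moves to a different item
(the first fixation of a trial is exempt).

All quantities live in *standardized value units*: the prior over true
values is the standard normal, so one unit equals one prior standard
deviation of value.  Item ratings on their native scale are mapped into
this space by :func:`fixopt.simulate.standardize_ratings`.

Computations are plain integers: ``0..n_items-1`` means "sample item i"
and the module constant :data:`TERMINATE` (== -1) means "stop sampling and
choose".  Items are indexed from 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TERMINATE",
    "ModelParams",
    "BeliefState",
    "TrueValues",
    "initial_belief",
    "draw_sample",
    "update_belief",
    "computation_cost",
    "termination_reward",
    "choose_item",
    "trial_payoff",
]

#: Sentinel computation: stop sampling and choose the argmax-mean item.
TERMINATE: int = -1

#: Sentinel for "no item attended yet" in :attr:`BeliefState.last`.
NO_LAST: int = -1


@dataclass(frozen=True)
class ModelParams:
    """Free parameters and fixed constants of the sampling model.

    Parameters are expressed in standardized value units (prior SD = 1).
    Defaults are the group-level fitted means reported for the joint
    binary/trinary food-choice fits.

    Attributes
    ----------
    n_items : int
        Number of items in the choice set (N >= 2).
    sigma_x : float
        Standard deviation of the value-sample noise.
    gamma_sample : float
        Cost per sample.
    gamma_switch : float
        Additional cost paid when attention switches to a different item.
        Not paid for the first fixation of a trial.
    sample_duration_ms : float
        Wall-clock duration attributed to one sample (default 100 ms).
    max_samples : int
        Hard cap on samples per episode; a guard against non-terminating
        parameterizations, not part of the model proper.  Episodes that hit
        the cap are flagged as truncated and choose by current argmax.
    """

    n_items: int = 2
    sigma_x: float = 2.60
    gamma_sample: float = 0.00373
    gamma_switch: float = 0.00995
    sample_duration_ms: float = 100.0
    max_samples: int = 5000

    def __post_init__(self) -> None:
        if self.n_items < 2:
            raise ValueError("n_items must be >= 2")
        if not self.sigma_x > 0:
            raise ValueError("sigma_x must be positive")
        if self.gamma_sample < 0 or self.gamma_switch < 0:
            raise ValueError("costs must be nonnegative")
        if not self.sample_duration_ms > 0:
            raise ValueError("sample_duration_ms must be positive")

    @property
    def tau(self) -> float:
        """Precision of a single value sample, ``sigma_x ** -2``."""
        return self.sigma_x ** -2

    def with_items(self, n_items: int) -> "ModelParams":
        return replace(self, n_items=n_items)


@dataclass(frozen=True)
class TrueValues:
    """True item values ``u`` in standardized units."""

    u: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "u", np.asarray(self.u, dtype=float))
        if not np.all(np.isfinite(self.u)):
            raise ValueError("true values must be finite")


@dataclass(frozen=True)
class BeliefState:
    """Gaussian belief over item values plus the last attended item.

    ``mu[i]`` and ``lam[i]`` are the posterior mean and precision for item
    i; ``last`` is the index of the last-sampled item, or :data:`NO_LAST`
    at trial onset.  Precisions start at 1 and only increase.
    """

    mu: np.ndarray
    lam: np.ndarray
    last: int = NO_LAST

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "lam", np.asarray(self.lam, dtype=float))
        if self.mu.shape != self.lam.shape:
            raise ValueError("mu and lam must have matching shapes")
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.lam))):
            raise ValueError("belief entries must be finite")
        if np.any(self.lam < 1.0 - 1e-12):
            raise ValueError("precisions must be >= 1 (prior precision)")
        if not (self.last == NO_LAST or 0 <= self.last < self.mu.size):
            raise ValueError("last must be NO_LAST or a valid item index")

    @property
    def n_items(self) -> int:
        return self.mu.size


def initial_belief(params: ModelParams) -> BeliefState:
    """Prior belief in the standardized space: mu=0, lam=1, nothing fixated."""
    n = params.n_items
    return BeliefState(mu=np.zeros(n), lam=np.ones(n), last=NO_LAST)


def draw_sample(
    u: TrueValues, item: int, sigma_x: float, rng: np.random.Generator
) -> float:
    """Draw one noisy value sample ``x ~ Normal(u[item], sigma_x**2)``."""
    vals = u.u
    if not 0 <= item < vals.size:
        raise IndexError(f"item index {item} out of range for {vals.size} items")
    return float(vals[item] + sigma_x * rng.standard_normal())


def update_belief(b: BeliefState, item: int, x: float, sigma_x: float) -> BeliefState:
    """Conjugate-normal update of item ``item`` after observing sample ``x``.

    The sampled item's precision increases by ``sigma_x**-2`` and its mean
    moves to the precision-weighted average of the old mean and the sample;
    all other items are untouched.  ``last`` becomes ``item``.
    """
    if not np.isfinite(x):
        raise ValueError("sample value must be finite")
    if not 0 <= item < b.n_items:
        raise IndexError("invalid item index")
    tau = sigma_x ** -2
    lam = b.lam.copy()
    mu = b.mu.copy()
    lam_new = lam[item] + tau
    mu[item] = (tau * x + lam[item] * mu[item]) / lam_new
    lam[item] = lam_new
    return BeliefState(mu=mu, lam=lam, last=item)


def computation_cost(b: BeliefState, c: int, params: ModelParams) -> float:
    """Cost of executing sampling computation ``c`` in belief ``b``.

    ``gamma_sample`` always; plus ``gamma_switch`` if attention moves to a
    different item than the last one sampled.  The first fixation of a
    trial (``b.last == NO_LAST``) never pays the switch cost.  Termination
    is free and is not a valid argument here.
    """
    if c == TERMINATE:
        raise ValueError("termination has zero cost; pass a sampling computation")
    if not 0 <= c < b.n_items:
        raise IndexError("invalid item index")
    cost = params.gamma_sample
    if b.last != NO_LAST and c != b.last:
        cost += params.gamma_switch
    return cost


def termination_reward(b: BeliefState) -> float:
    """Expected utility of choosing now: the maximum posterior mean."""
    return float(np.max(b.mu))


def choose_item(b: BeliefState, rng: np.random.Generator) -> int:
    """Choose the argmax-mean item; exact ties are broken uniformly."""
    mu = b.mu
    best = np.flatnonzero(mu == mu.max())
    if best.size == 1:
        return int(best[0])
    return int(rng.choice(best))


def trial_payoff(u: TrueValues, chosen: int, total_cost: float) -> float:
    """Realized payoff of a trial: true value of the chosen item minus costs."""
    if total_cost < 0:
        raise ValueError("total_cost must be nonnegative")
    return float(u.u[chosen]) - total_cost
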