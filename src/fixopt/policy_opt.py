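"""Softmax computation-selection policy and UCB search for near-optimal weights.

A :class:`Policy` selects computations with probability proportional to
``exp(beta * voc_hat)``; the termination computation always has proxy
value 0, so sampling stops (stochastically) once every sampling
computation's estimated value of computation falls below zero.

Because wide plateaus of weight space achieve near-identical expected
return while inducing distinct fixation behavior, the search returns an
*ensemble* -- the :class:`PolicySet` of the best-performing weight
vectors -- rather than a single optimum.  Candidates tile the weight
space with one uniform draw per box of a cubic grid: the first two
coordinates, sorted, give a uniform draw from the 3-simplex for
``w1..w3``; the third scales the future-cost offset ``w4`` between zero
and the largest per-sample cost at which sampling would still look
worthwhile in the prior belief.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from ._engine import simulate_episodes
from ._ucb import UCBConfig, ucb_refine
from .core_mdp import TERMINATE, BeliefState, ModelParams
from .voi_features import (
    VOCWeights,
    voi_full_arr,
    voi_item_arr,
    voi_myopic_arr,
)

__all__ = [
    "Policy",
    "PolicyRecord",
    "PolicySet",
    "UCBConfig",
    "policy_probabilities",
    "sample_weight_vectors",
    "max_cost",
    "evaluate_policy",
    "ucb_policy_search",
    "policy_set_pair",
]


@dataclass(frozen=True)
class Policy:
    """A softmax computation-selection policy: weights + inverse temperature."""

    weights: VOCWeights
    beta: float
    params: ModelParams

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")


@dataclass
class PolicyRecord:
    """A policy with its empirical return statistics from the search."""

    policy: Policy
    n_episodes: int
    mean_return: float
    sd_return: float
    candidate_index: int = -1

    def __post_init__(self) -> None:
        if self.n_episodes < 1:
            raise ValueError("n_episodes must be >= 1")
        if self.sd_return < 0:
            raise ValueError("sd_return must be nonnegative")


@dataclass
class PolicySet:
    """Ordered ensemble of near-optimal policies (best mean return first)."""

    records: list[PolicyRecord]
    seed: int | None = None
    config: UCBConfig | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def params(self) -> ModelParams:
        return self.records[0].policy.params

    @property
    def beta(self) -> float:
        return self.records[0].policy.beta

    def weight_matrix(self) -> np.ndarray:
        """(K, 4) array of the ensemble's feature weights."""
        return np.array([r.policy.weights.as_array() for r in self.records])

    def to_dict(self) -> dict:
        p = self.params
        return {
            "params": asdict(p),
            "beta": self.beta,
            "seed": self.seed,
            "config": asdict(self.config) if self.config else None,
            "records": [
                {
                    "weights": list(r.policy.weights.as_array()),
                    "n_episodes": r.n_episodes,
                    "mean_return": r.mean_return,
                    "sd_return": r.sd_return,
                    "candidate_index": r.candidate_index,
                }
                for r in self.records
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolicySet":
        params = ModelParams(**d["params"])
        beta = d["beta"]
        records = [
            PolicyRecord(
                policy=Policy(
                    weights=VOCWeights(*r["weights"]), beta=beta, params=params
                ),
                n_episodes=r["n_episodes"],
                mean_return=r["mean_return"],
                sd_return=r["sd_return"],
                candidate_index=r.get("candidate_index", -1),
            )
            for r in d["records"]
        ]
        config = UCBConfig(**d["config"]) if d.get("config") else None
        return cls(records=records, seed=d.get("seed"), config=config)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "PolicySet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def policy_probabilities(b: BeliefState, policy: Policy) -> np.ndarray:
    """Softmax distribution over [sample 0, ..., sample N-1, TERMINATE]."""
    params = policy.params
    n = b.n_items
    mu, lam = b.mu[None, :], b.lam[None, :]
    w = policy.weights
    gain = (
        w.w1 * voi_myopic_arr(mu, lam, params.sigma_x)[0]
        + w.w2 * voi_item_arr(mu, lam)[0]
        + w.w3 * voi_full_arr(mu, lam)[0]
    )
    switch = (b.last != -1) & (np.arange(n) != b.last)
    cost = params.gamma_sample + params.gamma_switch * switch
    voc = np.append(gain - cost - w.w4, 0.0)
    z = policy.beta * voc
    z -= z.max()
    p = np.exp(z)
    return p / p.sum()


def _initial_features(params: ModelParams) -> np.ndarray:
    """(3,) VOI features of any item at the symmetric initial belief."""
    mu = np.zeros((1, params.n_items))
    lam = np.ones((1, params.n_items))
    return np.array(
        [
            voi_myopic_arr(mu, lam, params.sigma_x)[0, 0],
            voi_item_arr(mu, lam)[0, 0],
            voi_full_arr(mu, lam)[0],
        ]
    )


def max_cost(
    params: ModelParams, w1_3: Sequence[float], method: str = "analytic"
) -> float:
    """Largest per-sample cost at which sampling still looks worthwhile.

    At the initial belief with ``w4 = 0``, ``voc_hat`` for any item equals
    ``w . (VOI features) - cost``; the break-even cost is therefore the
    weighted feature value itself.  ``method="bisect"`` retains a
    root-bisection (tolerance 1e-6) as an independent cross-check.
    """
    w1_3 = np.asarray(w1_3, dtype=float)
    if abs(w1_3.sum() - 1.0) > 1e-9 or np.any(w1_3 < 0):
        raise ValueError("w1_3 must lie on the simplex")
    feats = _initial_features(params)
    analytic = float(w1_3 @ feats)
    if method == "analytic":
        return analytic
    if method != "bisect":
        raise ValueError("method must be 'analytic' or 'bisect'")
    lo, hi = 0.0, max(2.0 * analytic, 1e-6)
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if analytic - mid > 0:  # voc still positive at this cost
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def sample_weight_vectors(
    params: ModelParams | None = None,
    n_boxes_per_dim: int = 20,
    rng: np.random.Generator | None = None,
    max_cost_fn: Callable[[np.ndarray], float] | None = None,
) -> list[VOCWeights]:
    """One candidate weight vector per box of the unit-cube grid.

    The cube is split into ``n_boxes_per_dim**3`` equal boxes and one
    point drawn uniformly from each.  Sorting the first two coordinates
    maps them to a uniform draw from the 3-simplex (``w1..w3``); the third
    coordinate scales ``w4`` between 0 and the break-even sampling cost
    for that simplex point.
    """
    if rng is None:
        rng = np.random.default_rng()
    if max_cost_fn is None:
        if params is None:
            raise ValueError("provide either params or max_cost_fn")
        feats = _initial_features(params)
        max_cost_fn = lambda w13: float(w13 @ feats)  # noqa: E731
    n = n_boxes_per_dim
    grid = np.stack(
        np.meshgrid(np.arange(n), np.arange(n), np.arange(n), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    x = (grid + rng.random(grid.shape)) / n
    out = []
    for x1, x2, x3 in x:
        lo, hi = (x1, x2) if x1 <= x2 else (x2, x1)
        w13 = np.array([lo, hi - lo, 1.0 - hi])
        out.append(VOCWeights(w13[0], w13[1], w13[2], x3 * max_cost_fn(w13)))
    return out


def evaluate_policy(
    policy: Policy, n_episodes: int, rng: np.random.Generator
) -> np.ndarray:
    """Metalevel returns of ``n_episodes`` episodes with u ~ iid Normal(0, 1).

    The return of an episode is the termination reward (maximum posterior
    mean) minus the accumulated sampling costs; its expectation equals the
    expected realized payoff, with lower variance.
    """
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    params = policy.params
    u = rng.standard_normal((n_episodes, params.n_items))
    batch = simulate_episodes(
        u, policy.weights.as_array(), policy.beta, params, rng
    )
    return batch.meta_return


def ucb_policy_search(
    params: ModelParams,
    beta: float,
    config: UCBConfig | None = None,
    rng: np.random.Generator | None = None,
) -> PolicySet:
    """Identify the ensemble of near-optimal feature weights by UCB search.

    Candidates are scored on episodes with true values drawn iid from the
    standard normal prior; the top ``config.top_k`` candidates by mean
    return are returned, sorted descending (ties broken by candidate
    index).
    """
    config = config or UCBConfig()
    if rng is None:
        rng = np.random.default_rng()
    candidates = sample_weight_vectors(params, config.n_boxes_per_dim, rng)
    wmat = np.array([c.as_array() for c in candidates])

    def eval_batch(cand_idx: np.ndarray, r: np.random.Generator) -> np.ndarray:
        u = r.standard_normal((cand_idx.size, params.n_items))
        return simulate_episodes(u, wmat[cand_idx], beta, params, r).meta_return

    stats = ucb_refine(len(candidates), eval_batch, config, rng)
    top_k = min(config.top_k, len(candidates))
    order = np.lexsort((np.arange(len(candidates)), -stats.mean))[:top_k]
    sd = stats.sd()
    records = [
        PolicyRecord(
            policy=Policy(weights=candidates[i], beta=beta, params=params),
            n_episodes=int(stats.n[i]),
            mean_return=float(stats.mean[i]),
            sd_return=float(sd[i]) if np.isfinite(sd[i]) else 0.0,
            candidate_index=int(i),
        )
        for i in order
    ]
    return PolicySet(records=records, config=config)


def policy_set_pair(
    params: ModelParams,
    beta: float,
    config: UCBConfig | None = None,
    seed: int | None = None,
) -> tuple[PolicySet, PolicySet]:
    """Two independently optimized ensembles for the same parameters.

    One set is intended for likelihood estimation and the other for
    generating predictions, so that optimization noise cannot be fit; the
    second search uses a seed offset by a fixed constant.
    """
    s0 = 0 if seed is None else seed
    fit_set = ucb_policy_search(params, beta, config, np.random.default_rng(s0))
    pred_set = ucb_policy_search(
        params, beta, config, np.random.default_rng(s0 + 7919)
    )
    fit_set.seed, pred_set.seed = s0, s0 + 7919
    return fit_set, pred_set
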