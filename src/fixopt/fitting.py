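"""Approximate maximum-likelihood fitting via binned summary statistics.

The model has no analytic likelihood, so each trial is collapsed into
four summary statistics -- the rating rank of the chosen item, the number
of fixations, the total fixation time, and the proportion of fixation
time per rating rank -- and the likelihood of a trial is read off a
normalized histogram of the same statistics in simulated trials with the
same (unordered) set of ratings.

Binning: the chosen rank contributes N cells; fixation counts are capped
into bins {1, 2, 3, 4, 5+} (zero-fixation trials join the one-fixation
bin); total time and N-1 of the fixation-time proportions (ranks 1..N-1;
the last is redundant since proportions sum to one) are binned into
quintiles whose edges come from the reference (experimental) data, with
out-of-range values in the corresponding tail bin.  The histogram
therefore has C = N * 5**(N+1) cells: 250 for binary, 1875 for trinary
choice.

The likelihood of a dataset mixes the simulated histogram with a uniform
distribution over cells (weight epsilon, chosen in [0, 0.5] to maximize
the likelihood -- equivalent to add-n smoothing).  The outer search over
model parameters uses Sobol low-discrepancy points over a box in
(sigma_x, gamma_sample, gamma_switch, beta), with the prior-bias alpha
profiled on a small grid per point because the optimal policy does not
depend on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import qmc

from ._engine import EpisodeBatch, simulate_episodes
from ._ucb import UCBConfig
from .core_mdp import ModelParams
from .policy_opt import PolicySet, ucb_policy_search
from .simulate import Fixation, ObservedTrial, PriorSpec, standardize_ratings

__all__ = [
    "SummaryStats",
    "BinEdges",
    "SummaryHistogram",
    "Theta",
    "THETA_BOX",
    "n_cells",
    "rating_ranks",
    "summarize_trial",
    "compute_bin_edges",
    "bin_summary",
    "build_histogram",
    "trial_likelihood",
    "dataset_log_likelihood",
    "sobol_search",
    "FitResult",
]

#: Promising region of parameter space searched by default.
THETA_BOX: dict[str, tuple[float, float]] = {
    "sigma_x": (1.0, 5.0),
    "gamma_sample": (0.001, 0.01),
    "gamma_switch": (0.003, 0.03),
    "beta": (100.0, 500.0),
    "alpha": (0.0, 1.0),
}


@dataclass(frozen=True)
class Theta:
    """A full model parameterization (the five free parameters)."""

    sigma_x: float
    gamma_sample: float
    gamma_switch: float
    beta: float
    alpha: float

    def model_params(self, n_items: int, max_samples: int = 5000) -> ModelParams:
        return ModelParams(
            n_items=n_items,
            sigma_x=self.sigma_x,
            gamma_sample=self.gamma_sample,
            gamma_switch=self.gamma_switch,
            max_samples=max_samples,
        )


@dataclass(frozen=True)
class SummaryStats:
    """The four per-trial summary statistics used by the likelihood."""

    choice_rank: int
    n_fixations: int
    total_time_ms: float
    prop_by_rank: tuple | None  # None for zero-fixation trials


@dataclass(frozen=True)
class BinEdges:
    """Quintile cut points (20/40/60/80th percentiles) per continuous stat."""

    n_items: int
    time_edges: np.ndarray           # (4,)
    prop_edges: np.ndarray           # (N-1, 4), proportions for ranks 0..N-2

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time_edges) < 0) or np.any(
            np.diff(self.prop_edges, axis=1) < 0
        ):
            raise ValueError("bin edges must be nondecreasing")


@dataclass
class SummaryHistogram:
    """Normalized cell weights conditional on an unordered rating set."""

    key: tuple
    weights: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to one")


def n_cells(n_items: int) -> int:
    """Histogram size C = N * 5**(N+1)."""
    return n_items * 5 ** (n_items + 1)


def rating_key(ratings: Sequence[float]) -> tuple:
    """Canonical (descending-sorted) key for an unordered rating set."""
    return tuple(sorted(ratings, reverse=True))


def rating_ranks(ratings: Sequence[float]) -> np.ndarray:
    """Rank (0 = highest rating) per spatial position; ties go to the
    earlier position."""
    r = np.asarray(ratings, dtype=float)
    order = np.lexsort((np.arange(r.size), -r))
    ranks = np.empty(r.size, dtype=int)
    ranks[order] = np.arange(r.size)
    return ranks


def summarize_trial(
    fixations: Sequence[Fixation], choice: int, ratings: Sequence[float]
) -> SummaryStats:
    """Collapse one trial into the four summary statistics.

    Fixation-time proportions are indexed by rating rank, not spatial
    position; zero-fixation trials leave them undefined.
    """
    ranks = rating_ranks(ratings)
    n = len(ratings)
    time_by_rank = np.zeros(n)
    for f in fixations:
        time_by_rank[ranks[f.item]] += f.duration_ms
    total = float(time_by_rank.sum())
    props = tuple(time_by_rank / total) if total > 0 else None
    return SummaryStats(
        choice_rank=int(ranks[choice]),
        n_fixations=len(fixations),
        total_time_ms=total,
        prop_by_rank=props,
    )


def compute_bin_edges(
    summaries: Sequence[SummaryStats], n_items: int
) -> BinEdges:
    """Quintile edges of the continuous statistics in a reference dataset.

    Uses linearly interpolated percentiles.  A degenerate (constant)
    statistic collapses its bins with a warning.
    """
    if len(summaries) < 5:
        raise ValueError("need at least 5 reference trials for quintiles")
    qs = [20, 40, 60, 80]
    times = np.array([s.total_time_ms for s in summaries])
    time_edges = np.percentile(times, qs)
    prop_edges = np.empty((n_items - 1, 4))
    with_fix = [s for s in summaries if s.prop_by_rank is not None]
    for k in range(n_items - 1):
        vals = np.array([s.prop_by_rank[k] for s in with_fix])
        prop_edges[k] = np.percentile(vals, qs)
    for name, edges in [("total time", time_edges)] + [
        (f"proportion rank {k}", prop_edges[k]) for k in range(n_items - 1)
    ]:
        if np.allclose(edges, edges[0]):
            warnings.warn(
                f"degenerate reference distribution for {name}: "
                "quintile bins collapse",
                stacklevel=2,
            )
    return BinEdges(n_items=n_items, time_edges=time_edges, prop_edges=prop_edges)


def _fixation_bin(n_fixations) -> np.ndarray:
    """Bins {1,2,3,4,5+} -> 0..4, with 0 fixations mapped into the 1 bin."""
    return np.clip(np.asarray(n_fixations), 1, 5) - 1


def bin_summary(stats: SummaryStats, edges: BinEdges, n_items: int) -> int:
    """Flat histogram cell index in 0..C-1 (row-major: choice rank,
    fixation bin, time quintile, proportion quintiles for ranks 0..N-2)."""
    cell = stats.choice_rank
    cell = cell * 5 + int(_fixation_bin(stats.n_fixations))
    cell = cell * 5 + int(np.digitize(stats.total_time_ms, edges.time_edges))
    for k in range(n_items - 1):
        if stats.prop_by_rank is None:
            b = 0  # zero-fixation trials inherit the lowest proportion bin
        else:
            b = int(np.digitize(stats.prop_by_rank[k], edges.prop_edges[k]))
        cell = cell * 5 + b
    return cell


def _cells_from_batch(
    batch: EpisodeBatch, params: ModelParams, edges: BinEdges
) -> np.ndarray:
    """Vectorized cell indices for engine output simulated on rank-sorted
    ratings (spatial position == rating rank)."""
    total = batch.total_samples.astype(float) * params.sample_duration_ms
    cells = batch.choice.astype(np.int64)
    cells = cells * 5 + _fixation_bin(batch.n_fixations)
    cells = cells * 5 + np.digitize(total, edges.time_edges)
    nz = batch.total_samples > 0
    for k in range(params.n_items - 1):
        prop = np.zeros(len(total))
        prop[nz] = batch.n_samples[nz, k] / batch.total_samples[nz]
        b = np.where(nz, np.digitize(prop, edges.prop_edges[k]), 0)
        cells = cells * 5 + b
    return cells


def _histograms_for_keys(
    keys: Sequence[tuple],
    policy_set: PolicySet,
    prior: PriorSpec,
    edges: BinEdges,
    n_sims: int,
    rng: np.random.Generator,
) -> dict[tuple, np.ndarray]:
    """Simulate all rating sets in one engine call and bin the outcomes."""
    params = policy_set.params
    wmat = policy_set.weight_matrix()
    per_key = len(policy_set) * n_sims
    u_rows = np.concatenate(
        [
            np.broadcast_to(
                standardize_ratings(list(key), prior).u, (per_key, params.n_items)
            )
            for key in keys
        ]
    )
    w_rows = np.tile(np.repeat(wmat, n_sims, axis=0), (len(keys), 1))
    batch = simulate_episodes(u_rows, w_rows, policy_set.beta, params, rng)
    cells = _cells_from_batch(batch, params, edges)
    C = n_cells(params.n_items)
    out = {}
    for i, key in enumerate(keys):
        sl = cells[i * per_key : (i + 1) * per_key]
        out[key] = np.bincount(sl, minlength=C) / per_key
    return out


def build_histogram(
    rating_set: Sequence[float],
    policy_set: PolicySet,
    prior: PriorSpec,
    edges: BinEdges,
    n_sims: int = 625,
    rng: np.random.Generator | None = None,
) -> SummaryHistogram:
    """Simulated summary-statistic histogram for one unordered rating set.

    Simulates ``n_sims`` episodes per ensemble policy (the full-scale
    budget is 625 x 80 = 50,000) with items placed in rating-rank order,
    which makes the histogram invariant to the spatial permutation of the
    ratings by construction.
    """
    if len(rating_set) == 0:
        raise ValueError("rating set must be nonempty")
    if rng is None:
        rng = np.random.default_rng()
    key = rating_key(rating_set)
    weights = _histograms_for_keys([key], policy_set, prior, edges, n_sims, rng)[key]
    return SummaryHistogram(key=key, weights=weights)


def trial_likelihood(
    stats: SummaryStats,
    histogram: SummaryHistogram,
    epsilon: float,
    edges: BinEdges,
) -> float:
    """epsilon-mixture likelihood of one trial's summary statistics."""
    if not 0.0 <= epsilon <= 0.5:
        raise ValueError("epsilon must lie in [0, 0.5]")
    n_items = edges.n_items
    C = n_cells(n_items)
    p = histogram.weights[bin_summary(stats, edges, n_items)]
    return epsilon / C + (1.0 - epsilon) * p


def _optimize_epsilon(p: np.ndarray, C: np.ndarray) -> tuple[float, float]:
    """Maximize sum(log(eps/C + (1-eps) p)) over eps in [0, 0.5]."""

    def negll(eps: float) -> float:
        with np.errstate(divide="ignore"):
            return -float(np.sum(np.log(eps / C + (1.0 - eps) * p)))

    res = minimize_scalar(
        negll, bounds=(0.0, 0.5), method="bounded", options={"xatol": 1e-4}
    )
    cands = [(negll(0.0), 0.0), (negll(0.5), 0.5), (res.fun, float(res.x))]
    best = min(cands, key=lambda t: t[0])
    return -best[0], best[1]


def _prepare_arm(trials: Sequence[ObservedTrial], edges: BinEdges):
    """Per-trial cached (rating key, cell index) pairs."""
    keys, cells = [], []
    for t in trials:
        stats = summarize_trial(t.fixations, t.choice, t.ratings)
        keys.append(rating_key(t.ratings))
        cells.append(bin_summary(stats, edges, edges.n_items))
    return keys, np.asarray(cells)


def _pvector(
    keys, cells, policy_set, prior, edges, n_sims, rng
) -> np.ndarray:
    hists = _histograms_for_keys(
        sorted(set(keys)), policy_set, prior, edges, n_sims, rng
    )
    return np.array([hists[k][c] for k, c in zip(keys, cells)])


def dataset_log_likelihood(
    trials: Sequence[ObservedTrial],
    theta: Theta,
    policy_set: PolicySet,
    edges: BinEdges,
    rating_mean: float | None = None,
    rating_sd: float | None = None,
    n_sims: int = 625,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Maximized epsilon-mixture log likelihood of one dataset arm.

    Histograms are built once per distinct rating multiset.  Returns
    ``(log_likelihood, epsilon_star)``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if rating_mean is None or rating_sd is None:
        pooled = np.concatenate([np.asarray(t.ratings, float) for t in trials])
        rating_mean = float(pooled.mean())
        rating_sd = float(pooled.std(ddof=1))
    prior = PriorSpec(theta.alpha, rating_mean, rating_sd)
    keys, cells = _prepare_arm(trials, edges)
    p = _pvector(keys, cells, policy_set, prior, edges, n_sims, rng)
    C = np.full(p.size, float(n_cells(edges.n_items)))
    return _optimize_epsilon(p, C)


@dataclass
class FitResult:
    theta: Theta
    log_likelihood: float
    epsilon: float
    source: str = "sobol"


def _alpha_grid(size: int, rng: np.random.Generator) -> np.ndarray:
    """{0, 1} plus evenly spaced interior values with a random offset."""
    k = size - 2
    offset = rng.uniform(0.0, 1.0 / k)
    return np.concatenate([[0.0, 1.0], offset + np.arange(k) / k])


def sobol_search(
    data_binary: Sequence[ObservedTrial] | None,
    data_trinary: Sequence[ObservedTrial] | None,
    box: dict | None = None,
    n_points: int = 10_000,
    alpha_grid_size: int = 7,
    rng: np.random.Generator | None = None,
    *,
    ucb_config: UCBConfig | None = None,
    n_sims: int = 625,
    even_trials_only: bool = True,
    index_base: int = 0,
    max_samples: int = 1000,
    extra_points: Sequence[tuple] | None = None,
) -> list[FitResult]:
    """Quasi-random search for the joint maximum-likelihood parameters.

    Each Sobol point fixes (sigma_x, gamma_sample, gamma_switch, beta);
    near-optimal policy ensembles are found for each arm, then the
    likelihood is evaluated on an alpha grid containing 0, 1 and evenly
    spaced offset values, jointly (a single epsilon) across both arms.
    By default only even-indexed trials enter the likelihood, reserving
    odd trials for out-of-sample prediction checks; ``index_base``
    controls whether the first trial counts as even.

    ``extra_points`` are additional (sigma_x, gamma_sample, gamma_switch,
    beta) probes scored identically and tagged ``source="extra"``.
    Returns all scored configurations sorted by log likelihood, best
    first; the top thirty are conventionally used for prediction
    ensembles.
    """
    if n_points < 1 and not extra_points:
        raise ValueError("search budget must include at least one point")
    box = box or THETA_BOX
    rng = rng or np.random.default_rng()
    ucb_config = ucb_config or UCBConfig()

    arms = []
    for n_items, data in ((2, data_binary), (3, data_trinary)):
        if data is None:
            continue
        pooled = np.concatenate([np.asarray(t.ratings, float) for t in data])
        mean, sd = float(pooled.mean()), float(pooled.std(ddof=1))
        summaries = [
            summarize_trial(t.fixations, t.choice, t.ratings) for t in data
        ]
        edges = compute_bin_edges(summaries, n_items)
        fit_trials = [
            t for i, t in enumerate(data)
            if (not even_trials_only) or ((i + index_base) % 2 == 0)
        ]
        keys, cells = _prepare_arm(fit_trials, edges)
        arms.append(
            {"n_items": n_items, "mean": mean, "sd": sd, "edges": edges,
             "keys": keys, "cells": cells}
        )
    if not arms:
        raise ValueError("at least one dataset arm is required")

    lows = np.array([box[k][0] for k in
                     ("sigma_x", "gamma_sample", "gamma_switch", "beta")])
    highs = np.array([box[k][1] for k in
                      ("sigma_x", "gamma_sample", "gamma_switch", "beta")])
    points = []
    if n_points >= 1:
        sobol = qmc.Sobol(d=4, scramble=True, seed=int(rng.integers(2**31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            unit = sobol.random(n_points)
        points = [("sobol", tuple(qmc.scale(unit, lows, highs)[i]))
                  for i in range(n_points)]
    for pt in extra_points or ():
        points.append(("extra", tuple(pt)))

    alpha_grid = _alpha_grid(alpha_grid_size, rng)
    results: list[FitResult] = []
    for source, (sigma_x, g_sample, g_switch, beta) in points:
        arm_policy = {}
        for arm in arms:
            params = ModelParams(
                n_items=arm["n_items"], sigma_x=sigma_x,
                gamma_sample=g_sample, gamma_switch=g_switch,
                max_samples=max_samples,
            )
            arm_policy[arm["n_items"]] = ucb_policy_search(
                params, beta, ucb_config, rng
            )
        for alpha in alpha_grid:
            ps, Cs = [], []
            for arm in arms:
                prior = PriorSpec(float(alpha), arm["mean"], arm["sd"])
                p = _pvector(
                    arm["keys"], arm["cells"], arm_policy[arm["n_items"]],
                    prior, arm["edges"], n_sims, rng,
                )
                ps.append(p)
                Cs.append(np.full(p.size, float(n_cells(arm["n_items"]))))
            logl, eps = _optimize_epsilon(np.concatenate(ps), np.concatenate(Cs))
            results.append(
                FitResult(
                    theta=Theta(sigma_x, g_sample, g_switch, beta, float(alpha)),
                    log_likelihood=logl,
                    epsilon=eps,
                    source=source,
                )
            )
    results.sort(key=lambda r: -r.log_likelihood)
    return results


def save_fit(results: Sequence[FitResult], path: str | Path, **meta) -> None:
    """Write ranked fit results (plus provenance metadata) to JSON."""
    import json

    payload = {
        "meta": meta,
        "results": [
            {
                "theta": vars(r.theta) | {},
                "log_likelihood": r.log_likelihood,
                "epsilon": r.epsilon,
                "source": r.source,
            }
            for r in results
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=float))
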