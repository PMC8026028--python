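"""Upper-confidence-bound refinement loop shared by the policy searches.

A fixed pool of candidate policies is first given a baseline number of
evaluation episodes each; then, for a number of iterations, the
top-scoring candidates (score = mean + exploration bonus) receive a few
additional episodes and their running statistics are updated.  The caller
supplies a batched evaluation function, so the same loop drives both the
Gaussian-belief and the Bernoulli-belief searches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["UCBConfig", "RunningStats", "ucb_refine"]


@dataclass(frozen=True)
class UCBConfig:
    """Budget of the UCB policy search.

    Defaults follow the full-scale search (8000 candidates from a
    20x20x20 box grid, 100 baseline episodes, top 1% refined with 10
    episodes per iteration for 5000 iterations).  Reduced-budget runs
    shrink these numbers, not the search logic.

    ``exploration`` selects the bonus: ``"sem"`` (default) uses three
    standard errors, which tightens as a candidate accrues episodes;
    ``"sd"`` uses three raw return standard deviations, a bound that never
    shrinks with experience and is kept for comparison.
    """

    n_boxes_per_dim: int = 20
    n_baseline: int = 100
    top_k: int = 80
    n_refine: int = 10
    n_iterations: int = 5000
    exploration: str = "sem"

    def __post_init__(self) -> None:
        if min(self.n_boxes_per_dim, self.n_baseline, self.top_k,
               self.n_refine, self.n_iterations) < 1:
            raise ValueError("all UCB budget values must be >= 1")
        if self.exploration not in ("sem", "sd"):
            raise ValueError("exploration must be 'sem' or 'sd'")

    @property
    def n_candidates(self) -> int:
        return self.n_boxes_per_dim ** 3


class RunningStats:
    """Per-candidate running return statistics (parallel Welford merges)."""

    def __init__(self, n_candidates: int):
        self.n = np.zeros(n_candidates, dtype=np.int64)
        self.mean = np.zeros(n_candidates)
        self.m2 = np.zeros(n_candidates)

    def update(self, cand_idx: np.ndarray, returns: np.ndarray) -> None:
        """Fold one return per row of ``cand_idx`` into the statistics."""
        order = np.argsort(cand_idx, kind="stable")
        cand_idx = cand_idx[order]
        returns = returns[order]
        uniq, starts = np.unique(cand_idx, return_index=True)
        for c, s, e in zip(uniq, starts, np.append(starts[1:], cand_idx.size)):
            batch = returns[s:e]
            m = batch.size
            bm = batch.mean()
            bm2 = np.sum((batch - bm) ** 2)
            n0, mu0 = self.n[c], self.mean[c]
            delta = bm - mu0
            n1 = n0 + m
            self.mean[c] = mu0 + delta * m / n1
            self.m2[c] += bm2 + delta ** 2 * n0 * m / n1
            self.n[c] = n1

    def sd(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.sqrt(self.m2 / np.maximum(self.n - 1, 1))
        out[self.n < 2] = np.inf
        return out

    def score(self, exploration: str) -> np.ndarray:
        bonus = self.sd()
        if exploration == "sem":
            bonus = bonus / np.sqrt(np.maximum(self.n, 1))
        return self.mean + 3.0 * bonus


def ucb_refine(
    n_candidates: int,
    eval_batch: Callable[[np.ndarray, np.random.Generator], np.ndarray],
    config: UCBConfig,
    rng: np.random.Generator,
) -> RunningStats:
    """Run the baseline + iterated-refinement loop and return the stats.

    ``eval_batch(cand_idx, rng)`` must return one metalevel return per
    entry of ``cand_idx`` (candidate indices may repeat).
    """
    stats = RunningStats(n_candidates)
    idx = np.repeat(np.arange(n_candidates), config.n_baseline)
    stats.update(idx, eval_batch(idx, rng))
    top_k = min(config.top_k, n_candidates)
    for _ in range(config.n_iterations):
        scores = stats.score(config.exploration)
        top = np.argpartition(-scores, top_k - 1)[:top_k]
        idx = np.repeat(top, config.n_refine)
        stats.update(idx, eval_batch(idx, rng))
    return stats
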