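"""Vectorized episode engine for the Gaussian-belief sampling MDP.

Runs a batch of independent episodes in lock-step, one numpy-vectorized
step at a time, with per-row true values, feature weights and softmax
temperatures.  This is the performance path behind policy evaluation,
dataset simulation and histogram construction; the scalar reference
implementation lives in :mod:`fixopt.simulate` and is cross-checked
against this engine in the test suite.

Numerical notes
---------------
* Posterior precisions are maintained as ``1 + n_samples * sigma_x**-2``
  (recomputed from the per-item sample count at every update), so the
  precision ledger holds to the last bit.
* Softmax sampling uses the Gumbel-max trick, which is overflow-free for
  any finite inverse temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_mdp import ModelParams
from .voi_features import voi_full_arr, voi_item_arr, voi_myopic_arr

__all__ = ["EpisodeBatch", "simulate_episodes"]


@dataclass
class EpisodeBatch:
    """Outcome arrays for a batch of simulated episodes (length B each)."""

    choice: np.ndarray          # chosen item per episode
    n_samples: np.ndarray       # (B, N) samples per item
    n_fixations: np.ndarray     # number of contiguous same-item runs
    cost: np.ndarray            # accumulated sampling + switching cost
    meta_return: np.ndarray     # max posterior mean - cost
    payoff: np.ndarray          # true value of chosen item - cost
    truncated: np.ndarray       # episodes stopped by the max_samples guard
    final_mu: np.ndarray        # (B, N) posterior means at termination
    actions: np.ndarray | None  # (T, B) sampled item per step, -1 = inactive

    @property
    def total_samples(self) -> np.ndarray:
        return self.n_samples.sum(axis=1)

    def total_fixation_time_ms(self, params: ModelParams) -> np.ndarray:
        return self.total_samples * params.sample_duration_ms


def simulate_episodes(
    u: np.ndarray,
    weights: np.ndarray,
    beta,
    params: ModelParams,
    rng: np.random.Generator,
    record_actions: bool = False,
) -> EpisodeBatch:
    """Run one episode per row of ``u`` under the softmax feature policy.

    Parameters
    ----------
    u : (B, N) array
        True item values (standardized units) per episode.
    weights : (4,) or (B, 4) array
        VOC feature weights ``w1..w4`` (shared or per-episode).
    beta : float or (B,) array
        Softmax inverse temperature.
    params : ModelParams
        Model constants; ``params.n_items`` must equal N.
    record_actions : bool
        If True, return the per-step sampled item (needed to reconstruct
        fixation sequences); costs O(T x B) memory.
    """
    u = np.asarray(u, dtype=float)
    B, N = u.shape
    if N != params.n_items:
        raise ValueError("u width must match params.n_items")
    weights = np.asarray(weights, dtype=float)
    if weights.ndim == 1:
        weights = np.broadcast_to(weights, (B, 4))
    beta = np.broadcast_to(np.asarray(beta, dtype=float), (B,))

    tau = params.tau
    sigma_x = params.sigma_x
    gs, gw = params.gamma_sample, params.gamma_switch

    mu = np.zeros((B, N))
    counts = np.zeros((B, N), dtype=np.int64)
    # weighted sum of samples: mu = tau * sumx / lam with lam = 1 + counts*tau
    sumx = np.zeros((B, N))
    last = np.full(B, -1, dtype=np.int64)
    cost = np.zeros(B)
    n_fix = np.zeros(B, dtype=np.int64)
    truncated = np.zeros(B, dtype=bool)

    active = np.arange(B)
    action_log: list[np.ndarray] = []

    for _step in range(params.max_samples):
        if active.size == 0:
            break
        mu_a = mu[active]
        lam_a = 1.0 + counts[active] * tau
        w = weights[active]

        vm = voi_myopic_arr(mu_a, lam_a, sigma_x)
        vi = voi_item_arr(mu_a, lam_a)
        vf = voi_full_arr(mu_a, lam_a)

        last_a = last[active]
        switch = (last_a[:, None] != -1) & (
            np.arange(N)[None, :] != last_a[:, None]
        )
        step_cost = gs + gw * switch
        voc = (
            w[:, 0:1] * vm
            + w[:, 1:2] * vi
            + w[:, 2:3] * vf[:, None]
            - step_cost
            - w[:, 3:4]
        )

        logits = np.concatenate(
            [beta[active, None] * voc, np.zeros((active.size, 1))], axis=1
        )
        gumbel = rng.gumbel(size=logits.shape)
        act = np.argmax(logits + gumbel, axis=1)

        sampling = act < N
        rows = active[sampling]
        items = act[sampling]
        if record_actions:
            step_actions = np.full(B, -1, dtype=np.int16)
            step_actions[rows] = items.astype(np.int16)
            action_log.append(step_actions)

        if rows.size:
            x = u[rows, items] + sigma_x * rng.standard_normal(rows.size)
            sumx[rows, items] += x
            counts[rows, items] += 1
            mu[rows, items] = (tau * sumx[rows, items]) / (
                1.0 + counts[rows, items] * tau
            )
            cost[rows] += step_cost[sampling, items]
            n_fix[rows] += (items != last[rows]).astype(np.int64)
            last[rows] = items

        active = rows
    else:
        truncated[active] = True

    # Choice: argmax posterior mean, exact ties broken uniformly.
    mx = mu.max(axis=1)
    ties = mu == mx[:, None]
    tie_rows = ties.sum(axis=1) > 1
    choice = np.argmax(mu, axis=1)
    if np.any(tie_rows):
        r = np.where(ties[tie_rows], rng.random(ties[tie_rows].shape), -1.0)
        choice[tie_rows] = np.argmax(r, axis=1)

    actions = np.array(action_log, dtype=np.int16) if record_actions else None
    return EpisodeBatch(
        choice=choice,
        n_samples=counts,
        n_fixations=n_fix,
        cost=cost,
        meta_return=mx - cost,
        payoff=u[np.arange(B), choice] - cost,
        truncated=truncated,
        final_mu=mu,
        actions=actions,
    )
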