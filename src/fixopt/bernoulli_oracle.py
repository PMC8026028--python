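"""Discrete (Bernoulli-sample) variant of the sampling MDP, solved exactly.

With Bernoulli samples and Beta(1, 1) priors the belief space is a finite
trellis of success/failure counts, so the optimal policy and its value
can be computed exactly by backward induction once a cap is placed on the
total number of samples.  This module provides that exact solution, a
Beta-belief analogue of the linear VOI-feature policy, and the machinery
to measure what fraction of the exact-optimal expected metalevel reward
the feature policy achieves across a grid of sampling/switching costs --
the validation that justifies using the feature approximation in the
(intractable) Gaussian case.

Conventions: two items, item values u_i ~ Uniform(0, 1) = Beta(1, 1);
sampling item i yields a Bernoulli(u_i) outcome; the posterior after a
successes and b failures (counting the prior pseudo-counts) is
Beta(a, b) with mean a / (a + b).  Rewards are in [0, 1]; the metalevel
return of an episode is the terminal maximum posterior mean minus the
accumulated sampling and switching costs (first fixation exempt from the
switch cost, as in the Gaussian model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from ._ucb import UCBConfig, ucb_refine
from .policy_opt import sample_weight_vectors
from .voi_features import VOCWeights

__all__ = [
    "BernoulliBelief",
    "BernoulliDP",
    "BetaVOITables",
    "exact_optimal_value",
    "bernoulli_initial_features",
    "evaluate_feature_policy",
    "optimize_feature_weights",
    "evaluate_exact_policy",
    "approximation_ratio",
    "DEFAULT_COST_GRID",
]

#: Cost grid used by the approximation-quality validation:
#: gamma_sample x gamma_switch.
DEFAULT_COST_GRID: tuple = (
    (0.001, 0.0),
    (0.001, 0.005),
    (0.001, 0.01),
    (0.002, 0.0),
    (0.002, 0.005),
    (0.002, 0.01),
    (0.005, 0.0),
    (0.005, 0.005),
    (0.005, 0.01),
)

_MAX_HORIZON = 60  # memory guard for the dense feature tables / DP trellis


@dataclass(frozen=True)
class BernoulliBelief:
    """Beta posterior counts per item plus attention bookkeeping."""

    a: tuple  # success counts incl. the Beta(1,1) prior pseudo-count
    b: tuple  # failure counts likewise
    last: int = -1

    def __post_init__(self) -> None:
        if min(self.a) < 1 or min(self.b) < 1:
            raise ValueError("counts include the prior and must be >= 1")

    @property
    def samples_used(self) -> int:
        return sum(self.a) + sum(self.b) - 2 * len(self.a)

    def mean(self, i: int) -> float:
        return self.a[i] / (self.a[i] + self.b[i])


class BernoulliDP:
    """Exact backward-induction solution of the two-item Bernoulli MDP."""

    #: greedy action codes
    SAMPLE_0, SAMPLE_1, TERMINATE = 0, 1, 2

    def __init__(self, horizon: int, gamma_sample: float, gamma_switch: float):
        if horizon > _MAX_HORIZON:
            raise ValueError(f"horizon must be <= {_MAX_HORIZON}")
        self.horizon = horizon
        self.gamma_sample = gamma_sample
        self.gamma_switch = gamma_switch
        # V[(s1, s2)][k1, k2, last] with s_i samples of item i, k_i successes,
        # last in {0, 1}; the last=none root state is handled separately.
        self.V: dict[tuple, np.ndarray] = {}
        self.A: dict[tuple, np.ndarray] = {}
        self._solve()

    @staticmethod
    def _means(s: int) -> np.ndarray:
        return (np.arange(s + 1) + 1.0) / (s + 2.0)

    def _solve(self) -> None:
        h, gs, gw = self.horizon, self.gamma_sample, self.gamma_switch
        switch_if_last1 = np.array([0.0, gw])  # cost of sampling item 0
        switch_if_last0 = np.array([gw, 0.0])  # cost of sampling item 1
        for t in range(h, -1, -1):
            for s1 in range(t + 1):
                s2 = t - s1
                m1 = self._means(s1)
                m2 = self._means(s2)
                vterm = np.maximum(m1[:, None], m2[None, :])
                if t == h:
                    V = np.broadcast_to(vterm[:, :, None], vterm.shape + (2,)).copy()
                    A = np.full(V.shape, self.TERMINATE, dtype=np.int8)
                else:
                    Vn1 = self.V[(s1 + 1, s2)]
                    Vn2 = self.V[(s1, s2 + 1)]
                    core1 = (
                        m1[:, None] * Vn1[1:, :, 0]
                        + (1.0 - m1[:, None]) * Vn1[:-1, :, 0]
                    )
                    core2 = (
                        m2[None, :] * Vn2[:, 1:, 1]
                        + (1.0 - m2[None, :]) * Vn2[:, :-1, 1]
                    )
                    q1 = core1[:, :, None] - gs - switch_if_last1[None, None, :]
                    q2 = core2[:, :, None] - gs - switch_if_last0[None, None, :]
                    stacked = np.stack(
                        [q1, q2, np.broadcast_to(vterm[:, :, None], q1.shape)]
                    )
                    A = np.argmax(stacked, axis=0).astype(np.int8)
                    V = np.max(stacked, axis=0)
                self.V[(s1, s2)] = V
                self.A[(s1, s2)] = A
        # Root: no item attended yet, first sample exempt from switch cost.
        if h == 0:
            q_root = -np.inf
        else:
            Vn = self.V[(1, 0)]
            q_root = -gs + 0.5 * Vn[1, 0, 0] + 0.5 * Vn[0, 0, 0]
        self.initial_value = float(max(0.5, q_root))
        self.initial_action = self.TERMINATE if 0.5 >= q_root else self.SAMPLE_0

    def value(self, belief: BernoulliBelief) -> float:
        a1, a2 = belief.a
        b1, b2 = belief.b
        s1, s2 = a1 + b1 - 2, a2 + b2 - 2
        if belief.last < 0:
            if s1 + s2 != 0:
                raise ValueError("last=none only valid at the root state")
            return self.initial_value
        return float(self.V[(s1, s2)][a1 - 1, a2 - 1, belief.last])

    def greedy_action(self, belief: BernoulliBelief) -> int:
        a1, a2 = belief.a
        b1, b2 = belief.b
        s1, s2 = a1 + b1 - 2, a2 + b2 - 2
        if belief.last < 0:
            return self.initial_action
        return int(self.A[(s1, s2)][a1 - 1, a2 - 1, belief.last])

    def q_values(self, belief: BernoulliBelief) -> np.ndarray:
        """One-step Bellman expansion [Q_sample0, Q_sample1, Q_terminate];
        used to spot-check the stored values against the recursion."""
        a, b = belief.a, belief.b
        s = (a[0] + b[0] - 2, a[1] + b[1] - 2)
        if sum(s) >= self.horizon:
            raise ValueError("no sampling allowed at the horizon")
        m = (a[0] / (a[0] + b[0]), a[1] / (a[1] + b[1]))
        out = np.empty(3)
        for i in (0, 1):
            sn = list(s)
            sn[i] += 1
            Vn = self.V[tuple(sn)]
            idx_succ = [a[0] - 1, a[1] - 1]
            idx_succ[i] += 1
            succ = Vn[idx_succ[0], idx_succ[1], i]
            fail = Vn[a[0] - 1, a[1] - 1, i]
            switch = self.gamma_switch if (belief.last >= 0 and belief.last != i) else 0.0
            out[i] = -self.gamma_sample - switch + m[i] * succ + (1 - m[i]) * fail
        out[2] = max(m)
        return out


def exact_optimal_value(
    horizon: int, gamma_sample: float, gamma_switch: float = 0.0, n_items: int = 2
) -> BernoulliDP:
    """Solve the capped Bernoulli MDP exactly by backward induction."""
    if n_items != 2:
        raise NotImplementedError("exact solution implemented for two items")
    return BernoulliDP(horizon, gamma_sample, gamma_switch)


class BetaVOITables:
    """Dense lookup tables of the three VOI features over Beta beliefs.

    Indexed ``[a1-1, b1-1, a2-1, b2-1]`` for the features of *item 1*;
    item 2's features are read through the swapped view.  The expected
    maximum of two independent Beta variables (for the full-revelation
    feature) is evaluated by a 64-node Gauss-Legendre rule on [0, 1]
    applied to the product of the CDFs.
    """

    def __init__(self, horizon: int):
        if horizon > _MAX_HORIZON:
            raise ValueError(f"horizon must be <= {_MAX_HORIZON}")
        self.horizon = horizon
        A = horizon + 1  # counts a, b range over 1..A
        av = np.arange(1, A + 1, dtype=float)
        m = av[:, None] / (av[:, None] + av[None, :])  # mean for (a, b)
        m1 = m[:, :, None, None]
        m2 = m[None, None, :, :]
        maxm = np.maximum(m1, m2)

        # Myopic: one more Bernoulli sample of item 1.
        n1 = av[:, None] + av[None, :]
        mp = ((av[:, None] + 1) / (n1 + 1))[:, :, None, None]
        mm = (av[:, None] / (n1 + 1))[:, :, None, None]
        vm = (
            m1 * np.maximum(mp, m2) + (1 - m1) * np.maximum(mm, m2) - maxm
        )
        self.vm = np.clip(vm, 0.0, None).astype(np.float32)

        # Perfect knowledge of item 1:
        # E[max(U1, c)] = c F_{a,b}(c) + m1 (1 - F_{a+1,b}(c)), c = m2.
        a4 = av[:, None, None, None]
        b4 = av[None, :, None, None]
        F = beta_dist.cdf(m2, a4, b4)
        F_shift = beta_dist.cdf(m2, a4 + 1, b4)
        vi = m2 * F + m1 * (1.0 - F_shift) - maxm
        self.vi = np.clip(vi, 0.0, None).astype(np.float32)

        # Full revelation: E[max(U1, U2)] = 1 - int_0^1 F1(t) F2(t) dt.
        nodes, wts = np.polynomial.legendre.leggauss(64)
        t = 0.5 * (nodes + 1.0)
        w = 0.5 * wts
        cdf_grid = beta_dist.cdf(
            t[None, None, :], av[:, None, None], av[None, :, None]
        )  # (A, A, K)
        flat = cdf_grid.reshape(A * A, -1)
        G = (flat * w) @ flat.T  # int F1 F2 over all (a1,b1) x (a2,b2)
        vf = 1.0 - G.reshape(A, A, A, A) - maxm
        self.vf = np.clip(vf, 0.0, None).astype(np.float32)

    def features(self, a1, b1, a2, b2):
        """Gather (vm1, vm2, vi1, vi2, vf) for integer count arrays."""
        i1, j1, i2, j2 = a1 - 1, b1 - 1, a2 - 1, b2 - 1
        return (
            self.vm[i1, j1, i2, j2],
            self.vm[i2, j2, i1, j1],
            self.vi[i1, j1, i2, j2],
            self.vi[i2, j2, i1, j1],
            self.vf[i1, j1, i2, j2],
        )


def bernoulli_initial_features() -> np.ndarray:
    """VOI features at the symmetric Beta(1, 1) root: (1/12, 1/8, 1/6)."""
    return np.array([1.0 / 12.0, 1.0 / 8.0, 1.0 / 6.0])


def _run_feature_episodes(
    wrows: np.ndarray,
    gamma_sample: float,
    gamma_switch: float,
    tables: BetaVOITables,
    rng: np.random.Generator,
    mode: str = "greedy",
) -> np.ndarray:
    """Vectorized belief-MDP episodes under the (greedy) feature policy.

    Sample outcomes are drawn from the posterior predictive (success with
    probability equal to the current posterior mean), which marginalizes
    the unknown item values exactly; the return is the terminal maximum
    posterior mean minus accrued costs.
    """
    B = wrows.shape[0]
    h = tables.horizon
    a1 = np.ones(B, dtype=np.int64)
    b1 = np.ones(B, dtype=np.int64)
    a2 = np.ones(B, dtype=np.int64)
    b2 = np.ones(B, dtype=np.int64)
    last = np.full(B, -1, dtype=np.int64)
    cost = np.zeros(B)
    returns = np.zeros(B)
    active = np.arange(B)
    for _ in range(h + 1):
        if active.size == 0:
            break
        A1, B1, A2, B2 = a1[active], b1[active], a2[active], b2[active]
        m1 = A1 / (A1 + B1)
        m2 = A2 / (A2 + B2)
        total = (A1 + B1 - 2) + (A2 + B2 - 2)
        la = last[active]
        if mode == "greedy":
            vm1, vm2, vi1, vi2, vf = tables.features(A1, B1, A2, B2)
            w = wrows[active]
            c1 = gamma_sample + gamma_switch * ((la != -1) & (la != 0))
            c2 = gamma_sample + gamma_switch * ((la != -1) & (la != 1))
            voc1 = w[:, 0] * vm1 + w[:, 1] * vi1 + w[:, 2] * vf - c1 - w[:, 3]
            voc2 = w[:, 0] * vm2 + w[:, 1] * vi2 + w[:, 2] * vf - c2 - w[:, 3]
            act = np.where(voc1 >= voc2, 0, 1)
            best = np.maximum(voc1, voc2)
            act = np.where(best <= 0.0, 2, act)
        elif mode == "random":
            act = rng.integers(0, 3, size=active.size)
        else:
            raise ValueError("mode must be 'greedy' or 'random'")
        act = np.where(total >= h, 2, act)

        stopping = act == 2
        rows_stop = active[stopping]
        returns[rows_stop] = np.maximum(m1[stopping], m2[stopping]) - cost[rows_stop]

        go = ~stopping
        rows = active[go]
        if rows.size:
            act_go = act[go]
            m_act = np.where(act_go == 0, m1[go], m2[go])
            la_go = la[go]
            step_cost = gamma_sample + gamma_switch * (
                (la_go != -1) & (la_go != act_go)
            )
            success = rng.random(rows.size) < m_act
            s0 = rows[(act_go == 0) & success]
            f0 = rows[(act_go == 0) & ~success]
            s1_ = rows[(act_go == 1) & success]
            f1_ = rows[(act_go == 1) & ~success]
            a1[s0] += 1
            b1[f0] += 1
            a2[s1_] += 1
            b2[f1_] += 1
            cost[rows] += step_cost
            last[rows] = act_go
        active = rows
    return returns


def evaluate_feature_policy(
    weights: VOCWeights,
    gamma_sample: float,
    gamma_switch: float,
    tables: BetaVOITables,
    n_episodes: int,
    rng: np.random.Generator,
    mode: str = "greedy",
) -> np.ndarray:
    """Metalevel returns of the feature policy over ``n_episodes`` episodes."""
    wrows = np.broadcast_to(weights.as_array(), (n_episodes, 4))
    return _run_feature_episodes(
        wrows, gamma_sample, gamma_switch, tables, rng, mode=mode
    )


def optimize_feature_weights(
    gamma_sample: float,
    gamma_switch: float,
    tables: BetaVOITables,
    config: UCBConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[VOCWeights, float]:
    """UCB search for feature weights in the Bernoulli MDP.

    Returns the best candidate's weights and its estimated mean return.
    """
    config = config or UCBConfig(
        n_boxes_per_dim=6, n_baseline=60, top_k=20, n_refine=20, n_iterations=30
    )
    rng = rng or np.random.default_rng()
    feats = bernoulli_initial_features()
    candidates = sample_weight_vectors(
        n_boxes_per_dim=config.n_boxes_per_dim,
        rng=rng,
        max_cost_fn=lambda w13: float(w13 @ feats),
    )
    wmat = np.array([c.as_array() for c in candidates])

    def eval_batch(idx: np.ndarray, r: np.random.Generator) -> np.ndarray:
        return _run_feature_episodes(
            wmat[idx], gamma_sample, gamma_switch, tables, r
        )

    stats = ucb_refine(len(candidates), eval_batch, config, rng)
    best = int(np.argmax(stats.mean))
    return candidates[best], float(stats.mean[best])


def evaluate_exact_policy(
    dp: BernoulliDP, n_episodes: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo returns of the exact greedy policy (scalar rollouts)."""
    out = np.empty(n_episodes)
    for e in range(n_episodes):
        belief = BernoulliBelief(a=(1, 1), b=(1, 1), last=-1)
        a = [1, 1]
        b = [1, 1]
        last = -1
        cost = 0.0
        while True:
            belief = BernoulliBelief(a=tuple(a), b=tuple(b), last=last)
            act = dp.greedy_action(belief)
            if act == BernoulliDP.TERMINATE:
                out[e] = max(a[0] / (a[0] + b[0]), a[1] / (a[1] + b[1])) - cost
                break
            cost += dp.gamma_sample + (
                dp.gamma_switch if (last >= 0 and last != act) else 0.0
            )
            m = a[act] / (a[act] + b[act])
            if rng.random() < m:
                a[act] += 1
            else:
                b[act] += 1
            last = act
    return out


@dataclass
class ApproximationResult:
    worst_ratio: float
    table: pd.DataFrame
    horizon: int


def approximation_ratio(
    cost_grid: Sequence = DEFAULT_COST_GRID,
    horizon: int = 50,
    search_config: UCBConfig | None = None,
    n_eval_episodes: int = 20_000,
    rng: np.random.Generator | None = None,
    tables: BetaVOITables | None = None,
) -> ApproximationResult:
    """Worst-case fraction of optimal reward achieved by the feature policy.

    For every (gamma_sample, gamma_switch) point: solve the MDP exactly,
    optimize feature weights by UCB search, estimate the feature policy's
    expected return by Monte Carlo, and form the ratio to the exact
    optimal value.  The result records the minimum ratio over the grid
    together with a per-point table (including the Monte-Carlo standard
    error of each ratio).
    """
    if not cost_grid:
        raise ValueError("cost grid must be nonempty")
    rng = rng or np.random.default_rng()
    if tables is None:
        tables = BetaVOITables(horizon)
    rows = []
    for gs, gw in cost_grid:
        dp = BernoulliDP(horizon, gs, gw)
        weights, _ = optimize_feature_weights(gs, gw, tables, search_config, rng)
        rets = evaluate_feature_policy(
            weights, gs, gw, tables, n_eval_episodes, rng
        )
        approx = float(rets.mean())
        se = float(rets.std(ddof=1) / np.sqrt(n_eval_episodes))
        rows.append(
            {
                "gamma_sample": gs,
                "gamma_switch": gw,
                "optimal": dp.initial_value,
                "approx": approx,
                "approx_se": se,
                "ratio": approx / dp.initial_value,
                "ratio_se": se / dp.initial_value,
            }
        )
    table = pd.DataFrame(rows)
    return ApproximationResult(
        worst_ratio=float(table["ratio"].min()), table=table, horizon=horizon
    )
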