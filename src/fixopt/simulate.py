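"""Trial simulation: episodes, fixation sequences, rating standardization, IO.

A trial presents N items with integer liking ratings (a -10..10 scale).
Ratings are mapped into the model's standardized value space through a
possibly *biased* prior:

    u_i = (r_i - alpha * mean(ratings)) / std(ratings),

where the mean and SD are empirical moments of the rating distribution
(pooled over a dataset) and ``alpha`` in [0, 1] controls the prior bias:
``alpha = 1`` is an unbiased prior centered on the empirical mean, while
``alpha = 0`` centers the prior at zero, a strong underestimate when most
ratings are positive.

A simulated fixation is a maximal run of contiguous samples of one item,
at ``sample_duration_ms`` (default 100 ms) per sample.  Observed data at
native eye-tracker resolution use the same containers with arbitrary
positive durations.

Dataset IO uses three plain CSV tables (trials / fixations / choices);
simulated datasets add ``policy_id`` and ``sim_index`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._engine import simulate_episodes
from .core_mdp import (
    TERMINATE,
    TrueValues,
    choose_item,
    computation_cost,
    draw_sample,
    initial_belief,
    trial_payoff,
    update_belief,
)
from .policy_opt import Policy, PolicySet, policy_probabilities

__all__ = [
    "PriorSpec",
    "Trial",
    "Fixation",
    "SimulatedTrial",
    "ObservedTrial",
    "standardize_ratings",
    "run_episode",
    "computations_to_fixations",
    "simulate_dataset",
    "write_dataset",
    "read_observed",
    "simulated_to_tables",
]


@dataclass(frozen=True)
class PriorSpec:
    """Prior-bias weight plus the empirical rating moments of a dataset."""

    alpha: float
    rating_mean: float
    rating_sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not self.rating_sd > 0:
            raise ValueError("rating_sd must be positive")


@dataclass(frozen=True)
class Trial:
    """One choice trial: item liking ratings in spatial-position order."""

    trial_id: int
    ratings: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratings", tuple(self.ratings))
        if len(self.ratings) < 2:
            raise ValueError("a trial needs at least two items")

    @property
    def n_items(self) -> int:
        return len(self.ratings)


@dataclass(frozen=True)
class Fixation:
    """A contiguous span of attention to one item (spatial position index)."""

    item: int
    duration_ms: float

    def __post_init__(self) -> None:
        if not self.duration_ms > 0:
            raise ValueError("fixation duration must be positive")


@dataclass
class SimulatedTrial:
    """One simulated episode on a trial's ratings."""

    trial_id: int
    ratings: tuple
    computations: list
    fixations: list
    choice: int
    total_fixation_time_ms: float
    payoff: float
    truncated: bool = False
    policy_id: int = 0
    sim_index: int = 0


@dataclass
class ObservedTrial:
    """An observed (or observed-format) trial: ratings, fixations, choice."""

    trial_id: int
    ratings: tuple
    fixations: list
    choice: int

    @property
    def total_fixation_time_ms(self) -> float:
        return float(sum(f.duration_ms for f in self.fixations))


def standardize_ratings(trial: Trial | Sequence[float], prior: PriorSpec) -> TrueValues:
    """Map raw ratings into standardized value units through the prior."""
    r = np.asarray(trial.ratings if isinstance(trial, Trial) else trial, dtype=float)
    u = (r - prior.alpha * prior.rating_mean) / prior.rating_sd
    return TrueValues(u=u)


def computations_to_fixations(
    computations: Iterable[int], sample_duration_ms: float = 100.0
) -> list[Fixation]:
    """Run-length encode a computation sequence into fixations.

    TERMINATE entries are stripped; each run of k contiguous samples of
    one item becomes a fixation of ``k * sample_duration_ms``.
    """
    samples = [c for c in computations if c != TERMINATE]
    return [
        Fixation(item=item, duration_ms=len(list(run)) * sample_duration_ms)
        for item, run in groupby(samples)
    ]


def run_episode(
    policy: Policy,
    u: TrueValues,
    rng: np.random.Generator,
    trial_id: int = 0,
    ratings: tuple = (),
) -> SimulatedTrial:
    """Run a single episode of the softmax policy (scalar reference path).

    Repeatedly samples a computation from the policy, draws and integrates
    value samples, and accrues costs until termination or the episode cap
    (in which case the trial is flagged as truncated and the current
    argmax-mean item is chosen).
    """
    params = policy.params
    b = initial_belief(params)
    computations: list[int] = []
    total_cost = 0.0
    truncated = False
    while True:
        if len(computations) >= params.max_samples:
            truncated = True
            break
        p = policy_probabilities(b, policy)
        c = int(rng.choice(params.n_items + 1, p=p))
        if c == params.n_items:  # terminate slot
            break
        total_cost += computation_cost(b, c, params)
        x = draw_sample(u, c, params.sigma_x, rng)
        b = update_belief(b, c, x, params.sigma_x)
        computations.append(c)
    choice = choose_item(b, rng)
    fixations = computations_to_fixations(computations, params.sample_duration_ms)
    return SimulatedTrial(
        trial_id=trial_id,
        ratings=tuple(ratings),
        computations=computations,
        fixations=fixations,
        choice=choice,
        total_fixation_time_ms=len(computations) * params.sample_duration_ms,
        payoff=trial_payoff(u, choice, total_cost),
        truncated=truncated,
    )


def simulate_dataset(
    policy_set: PolicySet,
    trials: Sequence[Trial],
    prior: PriorSpec,
    n_sims_per_policy: int = 1,
    rng: np.random.Generator | None = None,
) -> list[SimulatedTrial]:
    """Simulate every trial ``n_sims_per_policy`` times per ensemble policy.

    Ratings are standardized through ``prior``; episodes run on the
    vectorized engine.  Output order is trial-major, then policy, then
    simulation index; fully reproducible from the generator state.
    """
    if not trials or len(policy_set) == 0:
        raise ValueError("need at least one trial and one policy")
    if rng is None:
        rng = np.random.default_rng()
    params = policy_set.params
    wmat = policy_set.weight_matrix()
    n_pol = len(policy_set)
    rows_w = np.repeat(wmat, n_sims_per_policy, axis=0)
    out: list[SimulatedTrial] = []
    for trial in trials:
        if trial.n_items != params.n_items:
            raise ValueError(
                f"trial {trial.trial_id} has {trial.n_items} items, "
                f"policy set expects {params.n_items}"
            )
        u = standardize_ratings(trial, prior).u
        B = n_pol * n_sims_per_policy
        batch = simulate_episodes(
            np.broadcast_to(u, (B, params.n_items)),
            rows_w,
            policy_set.beta,
            params,
            rng,
            record_actions=True,
        )
        actions = batch.actions  # (T, B)
        for j in range(B):
            comp = actions[:, j] if actions is not None and actions.size else np.empty(0)
            comp = [int(c) for c in comp if c >= 0]
            out.append(
                SimulatedTrial(
                    trial_id=trial.trial_id,
                    ratings=trial.ratings,
                    computations=comp,
                    fixations=computations_to_fixations(
                        comp, params.sample_duration_ms
                    ),
                    choice=int(batch.choice[j]),
                    total_fixation_time_ms=float(
                        batch.total_samples[j] * params.sample_duration_ms
                    ),
                    payoff=float(batch.payoff[j]),
                    truncated=bool(batch.truncated[j]),
                    policy_id=j // n_sims_per_policy,
                    sim_index=j % n_sims_per_policy,
                )
            )
    return out


# ---------------------------------------------------------------------------
# CSV layout: trials / fixations / choices

def _trials_frame(trials: Sequence[Trial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        row = {"trial_id": t.trial_id, "n_items": t.n_items}
        for i in range(3):
            row[f"rating_{i + 1}"] = t.ratings[i] if i < t.n_items else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def simulated_to_tables(
    sims: Sequence[SimulatedTrial],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Three-table layout (trials, fixations, choices) for simulated data."""
    trials = _trials_frame(
        [Trial(s.trial_id, s.ratings) for s in
         {s.trial_id: s for s in sims}.values()]
    )
    fix_rows, choice_rows = [], []
    for s in sims:
        key = {"trial_id": s.trial_id, "policy_id": s.policy_id,
               "sim_index": s.sim_index}
        for k, f in enumerate(s.fixations):
            fix_rows.append(
                {**key, "fixation_index": k + 1, "item_position": f.item + 1,
                 "duration_ms": f.duration_ms}
            )
        choice_rows.append(
            {**key, "chosen_position": s.choice + 1,
             "total_fixation_time_ms": s.total_fixation_time_ms}
        )
    return trials, pd.DataFrame(fix_rows), pd.DataFrame(choice_rows)


def write_dataset(
    sims_or_observed: Sequence, out_dir: str | Path
) -> None:
    """Write a dataset to ``trials.csv`` / ``fixations.csv`` / ``choices.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    first = sims_or_observed[0]
    if isinstance(first, SimulatedTrial):
        trials, fixations, choices = simulated_to_tables(sims_or_observed)
    else:
        trials = _trials_frame(
            [Trial(t.trial_id, t.ratings) for t in sims_or_observed]
        )
        fix_rows, choice_rows = [], []
        for t in sims_or_observed:
            for k, f in enumerate(t.fixations):
                fix_rows.append(
                    {"trial_id": t.trial_id, "fixation_index": k + 1,
                     "item_position": f.item + 1, "duration_ms": f.duration_ms}
                )
            choice_rows.append(
                {"trial_id": t.trial_id, "chosen_position": t.choice + 1,
                 "total_fixation_time_ms": t.total_fixation_time_ms}
            )
        fixations, choices = pd.DataFrame(fix_rows), pd.DataFrame(choice_rows)
    trials.to_csv(out / "trials.csv", index=False)
    fixations.to_csv(out / "fixations.csv", index=False)
    choices.to_csv(out / "choices.csv", index=False)


def read_observed(data_dir: str | Path) -> list[ObservedTrial]:
    """Read an observed-format dataset from the three-table CSV layout."""
    d = Path(data_dir)
    trials = pd.read_csv(d / "trials.csv")
    fixations = pd.read_csv(d / "fixations.csv")
    choices = pd.read_csv(d / "choices.csv")
    fix_by_trial: dict[int, list[Fixation]] = {}
    for row in fixations.sort_values(["trial_id", "fixation_index"]).itertuples():
        fix_by_trial.setdefault(int(row.trial_id), []).append(
            Fixation(item=int(row.item_position) - 1,
                     duration_ms=float(row.duration_ms))
        )
    choice_by_trial = {
        int(r.trial_id): int(r.chosen_position) - 1 for r in choices.itertuples()
    }
    out = []
    for row in trials.itertuples():
        n = int(row.n_items)
        ratings = tuple(
            getattr(row, f"rating_{i + 1}") for i in range(n)
        )
        tid = int(row.trial_id)
        out.append(
            ObservedTrial(
                trial_id=tid,
                ratings=ratings,
                fixations=fix_by_trial.get(tid, []),
                choice=choice_by_trial[tid],
            )
        )
    return out
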