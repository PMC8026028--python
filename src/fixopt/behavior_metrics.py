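"""Choice/fixation summary statistics with bootstrap confidence intervals.

Every metric consumes a sequence of trial records -- any objects exposing
``ratings`` (tuple, spatial order), ``fixations`` (list of
:class:`~fixopt.simulate.Fixation`) and ``choice`` (position index) -- so
simulated and observed datasets run through identical code paths.

"Relative rating" of an item is its rating minus the mean rating of the
other item(s); "fixation advantage" is an item's cumulative fixation time
minus the mean cumulative fixation time of the other item(s), evaluated
at the onset of a new fixation.  Rating-difference x-axes are binned on
the integer rating scale by default; time axes use fixed-width bins
(configurable).  Estimates are bin means with percentile bootstrap 95%
confidence intervals from trial-level resampling.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import rating_ranks

__all__ = [
    "bootstrap_ci",
    "psychometrics",
    "fixation_properties",
    "uncertainty_metrics",
    "value_metrics",
    "bias_metrics",
    "fixation_advantage_values",
    "alternative_advantage_values",
    "all_metrics",
]


def bootstrap_ci(
    values: np.ndarray,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    stat=np.mean,
) -> tuple[float, float]:
    """Percentile 95% CI of ``stat`` under resampling with replacement."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values for a bootstrap CI")
    rng = rng or np.random.default_rng()
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    stats = stat(values[idx], axis=1)
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


def _binned(
    x: np.ndarray,
    y: np.ndarray,
    width: float,
    n_boot: int,
    rng: np.random.Generator,
    min_n: int = 2,
) -> pd.DataFrame:
    """Mean of y per fixed-width bin of x, with bootstrap CIs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    centers = np.round(x / width) * width
    rows = []
    for c in np.unique(centers):
        sel = centers == c
        vals = y[sel]
        if vals.size < min_n:
            continue
        lo, hi = bootstrap_ci(vals, n_boot, rng)
        rows.append(
            {"x": c, "estimate": float(vals.mean()), "ci_low": lo,
             "ci_high": hi, "n": int(vals.size)}
        )
    return pd.DataFrame(rows)


def _summary_frame(values: np.ndarray, n_boot: int, rng) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    rows = []
    for name, q in (("q25", 25), ("median", 50), ("q75", 75)):
        lo, hi = bootstrap_ci(
            values, n_boot, rng, stat=lambda v, axis: np.percentile(v, q, axis=axis)
        )
        rows.append(
            {"stat": name, "estimate": float(np.percentile(values, q)),
             "ci_low": lo, "ci_high": hi, "n": int(values.size)}
        )
    return pd.DataFrame(rows)


def _total_times(rec) -> np.ndarray:
    """Cumulative fixation time per item position at end of trial."""
    n = len(rec.ratings)
    out = np.zeros(n)
    for f in rec.fixations:
        out[f.item] += f.duration_ms
    return out


def _rel_rating(ratings, i: int) -> float:
    r = np.asarray(ratings, dtype=float)
    others = np.delete(r, i)
    return float(r[i] - others.mean())


def psychometrics(
    records: Sequence, n_boot: int = 1000, rng: np.random.Generator | None = None
) -> dict[str, pd.DataFrame]:
    """Choice curves and total-fixation-time patterns."""
    if not records:
        raise ValueError("empty dataset")
    rng = rng or np.random.default_rng()
    xs, ys = [], []
    bx, by, mx, my = [], [], [], []
    totals = []
    for rec in records:
        total = sum(f.duration_ms for f in rec.fixations)
        totals.append(total)
        r = np.asarray(rec.ratings, dtype=float)
        for i in range(len(r)):
            xs.append(_rel_rating(r, i))
            ys.append(rec.choice == i)
        best = int(np.argmax(r))
        bx.append(_rel_rating(r, best))
        by.append(total)
        mx.append(r.mean())
        my.append(total)
    totals = np.asarray(totals, dtype=float)
    return {
        "choice_rate_vs_relative_rating": _binned(
            np.array(xs), np.array(ys, dtype=float), 1.0, n_boot, rng
        ),
        "total_time_quartiles": _summary_frame(totals, n_boot, rng),
        "total_time_vs_best_relative_rating": _binned(
            np.array(bx), np.array(by), 1.0, n_boot, rng
        ),
        "total_time_vs_mean_rating": _binned(
            np.array(mx), np.array(my), 1.0, n_boot, rng
        ),
    }


def fixation_properties(
    records: Sequence, n_boot: int = 1000,
    rng: np.random.Generator | None = None, max_index: int = 5,
) -> dict[str, pd.DataFrame]:
    """Fixation counts and durations by position in the trial.

    The duration-by-index table keeps final fixations out of every
    indexed bin and reports them separately (``is_final`` flag), since
    final fixations are cut off by the choice.
    """
    rng = rng or np.random.default_rng()
    n_fix = np.array([len(r.fixations) for r in records])
    counts = pd.Series(n_fix).value_counts(normalize=True).sort_index()
    hist = pd.DataFrame(
        {"n_fixations": counts.index, "proportion": counts.values}
    )
    bx = [
        _rel_rating(r.ratings, int(np.argmax(r.ratings))) for r in records
    ]
    rows = []
    for idx in range(1, max_index + 1):
        durs = np.array(
            [
                r.fixations[idx - 1].duration_ms
                for r in records
                if len(r.fixations) > idx  # strictly: fixation idx is non-final
            ]
        )
        if durs.size >= 2:
            lo, hi = bootstrap_ci(durs, n_boot, rng)
            rows.append(
                {"fixation_index": idx, "is_final": False,
                 "estimate": durs.mean(), "ci_low": lo, "ci_high": hi,
                 "n": durs.size}
            )
    finals = np.array(
        [r.fixations[-1].duration_ms for r in records if r.fixations]
    )
    if finals.size >= 2:
        lo, hi = bootstrap_ci(finals, n_boot, rng)
        rows.append(
            {"fixation_index": -1, "is_final": True, "estimate": finals.mean(),
             "ci_low": lo, "ci_high": hi, "n": finals.size}
        )
    return {
        "n_fixations_hist": hist,
        "n_fixations_vs_best_relative_rating": _binned(
            np.array(bx), n_fix.astype(float), 1.0, n_boot, rng
        ),
        "fixation_duration_by_index": pd.DataFrame(rows),
    }


def fixation_advantage_values(records: Sequence) -> np.ndarray:
    """Fixation advantage of the newly fixated item at each fixation onset
    (first fixations excluded)."""
    vals = []
    for rec in records:
        n = len(rec.ratings)
        cum = np.zeros(n)
        for k, f in enumerate(rec.fixations):
            if k >= 1:
                others = np.delete(cum, f.item)
                vals.append(cum[f.item] - others.mean())
            cum[f.item] += f.duration_ms
    return np.asarray(vals)


def alternative_advantage_values(records: Sequence) -> np.ndarray:
    """Trinary: fixated-item minus could-have-been-fixated-item cumulative
    time at fixation onset (first and second fixations excluded)."""
    vals = []
    for rec in records:
        if len(rec.ratings) != 3:
            continue
        cum = np.zeros(3)
        prev = None
        for k, f in enumerate(rec.fixations):
            if k >= 2 and prev is not None:
                candidates = [i for i in range(3) if i != prev]
                if f.item in candidates:
                    other = candidates[0] if candidates[1] == f.item else candidates[1]
                    vals.append(cum[f.item] - cum[other])
            cum[f.item] += f.duration_ms
            prev = f.item
    return np.asarray(vals)


def uncertainty_metrics(
    records: Sequence, n_boot: int = 1000,
    rng: np.random.Generator | None = None, time_bin_ms: float = 200.0,
) -> dict[str, pd.DataFrame]:
    """Where new fixations land relative to accumulated fixation time."""
    rng = rng or np.random.default_rng()
    adv = fixation_advantage_values(records)
    alt = alternative_advantage_values(records)
    # P(fixate the higher-advantage alternative) vs the advantage gap.
    gap_x, gap_y = [], []
    for rec in records:
        if len(rec.ratings) != 3:
            continue
        cum = np.zeros(3)
        prev = None
        for k, f in enumerate(rec.fixations):
            if k >= 2 and prev is not None and f.item != prev:
                c1, c2 = [i for i in range(3) if i != prev]
                if cum[c1] != cum[c2]:
                    hi_item = c1 if cum[c1] > cum[c2] else c2
                    gap_x.append(abs(cum[c1] - cum[c2]))
                    gap_y.append(f.item == hi_item)
            cum[f.item] += f.duration_ms
            prev = f.item
    out = {}
    if adv.size >= 2:
        out["fixation_advantage_summary"] = _summary_frame(adv, n_boot, rng)
    if alt.size >= 2:
        out["alternative_advantage_summary"] = _summary_frame(alt, n_boot, rng)
    if len(gap_x) >= 2:
        out["p_fixate_higher_advantage"] = _binned(
            np.array(gap_x), np.array(gap_y, dtype=float),
            time_bin_ms, n_boot, rng,
        )
    return out


def value_metrics(
    records: Sequence, n_boot: int = 1000,
    rng: np.random.Generator | None = None, time_bin_ms: float = 500.0,
) -> dict[str, pd.DataFrame]:
    """Rating-driven fixation patterns (value-directed attention)."""
    rng = rng or np.random.default_rng()
    share_x, share_y = [], []
    ff_x, ff_y = [], []
    worst_x, worst_y = [], []
    f4_x, f4_y = [], []
    f3_x, f3_y = [], []
    for rec in records:
        r = np.asarray(rec.ratings, dtype=float)
        n = len(r)
        totals = _total_times(rec)
        total = totals.sum()
        if total > 0:
            share_x.append(_rel_rating(r, 0))
            share_y.append(totals[0] / total)
        if rec.fixations:
            first = rec.fixations[0]
            ff_x.append(r[first.item])
            ff_y.append(first.duration_ms)
        ranks = rating_ranks(r)
        worst_item = int(np.argmax(ranks))  # lowest-rated (ties -> later pos)
        elapsed = 0.0
        for f in rec.fixations:
            worst_x.append(elapsed)
            worst_y.append(f.item == worst_item)
            elapsed += f.duration_ms
        if n == 3 and len(rec.fixations) >= 4:
            seq = [f.item for f in rec.fixations[:4]]
            if len(set(seq[:3])) == 3:
                f4_x.append(r[seq[0]] - r[seq[1]])
                f4_y.append(seq[3] == seq[0])
        if n == 3 and len(rec.fixations) >= 3:
            seq = [f.item for f in rec.fixations[:3]]
            if seq[0] != seq[1]:
                f3_x.append(r[seq[0]])
                f3_y.append(seq[2] == seq[0])
    out = {
        "left_fixation_share_vs_relative_rating": _binned(
            np.array(share_x), np.array(share_y), 1.0, n_boot, rng
        ),
        "first_fixation_duration_vs_rating": _binned(
            np.array(ff_x), np.array(ff_y), 1.0, n_boot, rng
        ),
        "p_fixate_worst_vs_elapsed_time": _binned(
            np.array(worst_x), np.array(worst_y, dtype=float),
            time_bin_ms, n_boot, rng,
        ),
    }
    if len(f4_x) >= 2:
        out["p_fourth_to_first_vs_rating_diff"] = _binned(
            np.array(f4_x), np.array(f4_y, dtype=float), 1.0, n_boot, rng
        )
    if len(f3_x) >= 2:
        out["p_third_to_first_vs_rating"] = _binned(
            np.array(f3_x), np.array(f3_y, dtype=float), 1.0, n_boot, rng
        )
    return out


def bias_metrics(
    records: Sequence, n_boot: int = 1000,
    rng: np.random.Generator | None = None, time_bin_ms: float = 500.0,
) -> dict[str, pd.DataFrame]:
    """Attention-choice correlations (last-/first-fixation and gaze biases)."""
    rng = rng or np.random.default_rng()
    last_x, last_y = [], []
    left_x, left_y = [], []
    first_x, first_y = [], []
    for rec in records:
        r = np.asarray(rec.ratings, dtype=float)
        if rec.fixations:
            last = rec.fixations[-1].item
            last_x.append(_rel_rating(r, last))
            last_y.append(rec.choice == last)
            first = rec.fixations[0]
            first_x.append(first.duration_ms)
            first_y.append(rec.choice == first.item)
        totals = _total_times(rec)
        others = np.delete(totals, 0)
        left_x.append(totals[0] - others.mean())
        left_y.append(rec.choice == 0)
    return {
        "p_choose_last_vs_relative_rating": _binned(
            np.array(last_x), np.array(last_y, dtype=float), 1.0, n_boot, rng
        ),
        "p_choose_left_vs_final_advantage": _binned(
            np.array(left_x), np.array(left_y, dtype=float),
            time_bin_ms, n_boot, rng,
        ),
        "p_choose_first_vs_first_duration": _binned(
            np.array(first_x), np.array(first_y, dtype=float),
            200.0, n_boot, rng,
        ),
    }


def all_metrics(
    records: Sequence, n_boot: int = 1000, rng: np.random.Generator | None = None
) -> dict[str, pd.DataFrame]:
    """Every metric table, keyed ``family/metric``."""
    rng = rng or np.random.default_rng()
    out = {}
    for family, fn in (
        ("psychometrics", psychometrics),
        ("fixation_properties", fixation_properties),
        ("uncertainty", uncertainty_metrics),
        ("value", value_metrics),
        ("bias", bias_metrics),
    ):
        for name, df in fn(records, n_boot=n_boot, rng=rng).items():
            out[f"{family}/{name}"] = df
    return out
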