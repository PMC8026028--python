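import numpy as np
import pytest

from conftest import SMALL_UCB
from fixopt import (
    BinEdges,
    ModelParams,
    PriorSpec,
    SummaryHistogram,
    SummaryStats,
    Theta,
    bin_summary,
    build_histogram,
    compute_bin_edges,
    dataset_log_likelihood,
    n_cells,
    summarize_trial,
    trial_likelihood,
    ucb_policy_search,
)
from fixopt.fitting import _optimize_epsilon, rating_key, rating_ranks
from fixopt.simulate import Fixation, ObservedTrial


def _edges(n_items, tmax=2000.0):
    qs = np.array([0.2, 0.4, 0.6, 0.8])
    return BinEdges(
        n_items=n_items,
        time_edges=qs * tmax,
        prop_edges=np.tile(qs, (n_items - 1, 1)),
    )


class TestSummarize:
    def test_example(self):
        fx = [Fixation(0, 200.0), Fixation(1, 300.0)]
        s = summarize_trial(fx, choice=1, ratings=(4, 7))
        assert s.n_fixations == 2
        assert s.total_time_ms == 500.0
        # item at position 1 has the higher rating -> rank 0
        assert s.choice_rank == 0
        assert s.prop_by_rank[0] == pytest.approx(0.6)

    def test_zero_fixations(self):
        s = summarize_trial([], choice=0, ratings=(3, 5))
        assert s.n_fixations == 0 and s.total_time_ms == 0.0
        assert s.prop_by_rank is None

    def test_proportions_sum_to_one(self):
        fx = [Fixation(0, 100.0), Fixation(2, 400.0), Fixation(1, 500.0)]
        s = summarize_trial(fx, choice=2, ratings=(1, 2, 3))
        assert sum(s.prop_by_rank) == pytest.approx(1.0)

    def test_rank_ties_broken_by_position(self):
        assert list(rating_ranks((5, 5, 3))) == [0, 1, 2]


class TestBinEdges:
    def test_percentile_convention(self):
        summaries = [
            SummaryStats(0, 2, float(t), (t / 99.0, 1 - t / 99.0))
            for t in range(100)
        ]
        e = compute_bin_edges(summaries, 2)
        np.testing.assert_allclose(e.time_edges, [19.8, 39.6, 59.4, 79.2])

    def test_degenerate_reference_warns(self):
        summaries = [SummaryStats(0, 2, 500.0, (0.5, 0.5))] * 10
        with pytest.warns(UserWarning, match="degenerate"):
            compute_bin_edges(summaries, 2)

    def test_edges_nondecreasing(self, rng):
        summaries = [
            SummaryStats(0, 2, float(rng.uniform(0, 3000)),
                         (float(rng.random()), 0.0))
            for _ in range(50)
        ]
        e = compute_bin_edges(summaries, 2)
        assert np.all(np.diff(e.time_edges) >= 0)

    def test_too_few_reference_trials(self):
        with pytest.raises(ValueError):
            compute_bin_edges([SummaryStats(0, 1, 1.0, (1.0, 0.0))] * 4, 2)


class TestBinSummary:
    EDGES = _edges(2)

    def test_cell_count_binary_and_trinary(self):
        assert n_cells(2) == 250
        assert n_cells(3) == 1875

    def test_five_plus_fixations_share_a_bin(self):
        a = bin_summary(SummaryStats(0, 7, 100.0, (0.1, 0.9)), self.EDGES, 2)
        b = bin_summary(SummaryStats(0, 5, 100.0, (0.1, 0.9)), self.EDGES, 2)
        assert a == b

    def test_zero_fixations_join_one_fixation_bin(self):
        a = bin_summary(SummaryStats(0, 0, 0.0, None), self.EDGES, 2)
        b = bin_summary(SummaryStats(0, 1, 0.0, (0.0, 1.0)), self.EDGES, 2)
        assert a == b

    def test_out_of_range_goes_to_tail_bin(self):
        hi = bin_summary(SummaryStats(0, 2, 1e9, (0.5, 0.5)), self.EDGES, 2)
        top = bin_summary(SummaryStats(0, 2, 1900.0, (0.5, 0.5)), self.EDGES, 2)
        assert hi == top

    def test_all_cells_within_range(self, rng):
        for _ in range(200):
            s = SummaryStats(
                int(rng.integers(2)), int(rng.integers(0, 9)),
                float(rng.uniform(0, 4000)),
                tuple(rng.dirichlet([1, 1])),
            )
            assert 0 <= bin_summary(s, self.EDGES, 2) < 250


class TestTrialLikelihood:
    def test_epsilon_floor_on_empty_cell(self):
        weights = np.zeros(250)
        weights[0] = 1.0
        hist = SummaryHistogram(key=(5, 3), weights=weights)
        s = SummaryStats(1, 3, 1500.0, (0.2, 0.8))  # lands in an empty cell
        assert trial_likelihood(s, hist, 0.5, _edges(2)) == pytest.approx(0.002)
        assert trial_likelihood(s, hist, 0.0, _edges(2)) == 0.0
        for eps in (0.1, 0.3):
            assert trial_likelihood(s, hist, eps, _edges(2)) >= eps / 250


class TestEpsilonOptimization:
    def test_boundary_when_model_explains_nothing(self):
        p = np.zeros(50)
        logl, eps = _optimize_epsilon(p, np.full(50, 250.0))
        assert eps == pytest.approx(0.5, abs=1e-3)

    def test_near_zero_when_model_matches(self):
        # every observed cell already carries high simulated mass
        p = np.full(200, 0.2)
        logl, eps = _optimize_epsilon(p, np.full(200, 250.0))
        assert eps < 1e-3

    def test_optimizer_matches_grid_scan_and_concavity(self):
        rng = np.random.default_rng(0)
        p = rng.choice([0.0, 0.01, 0.1], size=80, p=[0.3, 0.4, 0.3])
        C = np.full(80, 250.0)
        logl, eps = _optimize_epsilon(p, C)
        grid = np.linspace(1e-6, 0.5, 2001)
        vals = [np.sum(np.log(e / C + (1 - e) * p)) for e in grid]
        assert logl >= max(vals) - 1e-6
        assert abs(eps - grid[int(np.argmax(vals))]) < 0.01
        d2 = np.diff(vals, 2)
        assert np.all(d2 < 1e-9)  # concave in epsilon


@pytest.fixture(scope="module")
def policy_set():
    params = ModelParams(n_items=2, max_samples=400)
    return ucb_policy_search(params, 300.0, SMALL_UCB, np.random.default_rng(7))


class TestHistogram:
    PRIOR = PriorSpec(alpha=0.5, rating_mean=4.0, rating_sd=2.5)

    def test_normalized(self, policy_set):
        h = build_histogram((5, 3), policy_set, self.PRIOR, _edges(2),
                            n_sims=30, rng=np.random.default_rng(1))
        assert h.weights.sum() == pytest.approx(1.0)
        assert np.all(h.weights >= 0)
        assert h.weights.size == 250

    def test_rating_permutation_invariance(self, policy_set):
        a = build_histogram((5, 3), policy_set, self.PRIOR, _edges(2),
                            n_sims=30, rng=np.random.default_rng(2))
        b = build_histogram((3, 5), policy_set, self.PRIOR, _edges(2),
                            n_sims=30, rng=np.random.default_rng(2))
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.key == b.key == (5, 3)

    def test_single_simulation_single_cell(self, policy_set):
        one = type(policy_set)(records=policy_set.records[:1])
        h = build_histogram((6, 2), one, self.PRIOR, _edges(2), n_sims=1,
                            rng=np.random.default_rng(3))
        assert np.count_nonzero(h.weights) == 1

    def test_budget_arithmetic(self, policy_set):
        per_key = len(policy_set) * 30
        h = build_histogram((5, 3), policy_set, self.PRIOR, _edges(2),
                            n_sims=30, rng=np.random.default_rng(4))
        counts = h.weights * per_key
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)
        assert counts.sum() == per_key


def test_dataset_log_likelihood_self_consistency(policy_set):
    """Data simulated from the model itself needs little uniform
    smoothing: epsilon* stays small."""
    from fixopt.simulate import simulate_dataset, Trial

    prior = PriorSpec(alpha=0.5, rating_mean=4.0, rating_sd=2.5)
    trials = [Trial(i, (5, 3)) for i in range(3)] + [Trial(3 + i, (6, 2)) for i in range(3)]
    rng = np.random.default_rng(11)
    sims = simulate_dataset(policy_set, trials, prior, 20, rng)
    data = [
        ObservedTrial(trial_id=k, ratings=s.ratings, fixations=s.fixations,
                      choice=s.choice)
        for k, s in enumerate(sims[::3])
    ]
    summaries = [summarize_trial(t.fixations, t.choice, t.ratings) for t in data]
    edges = compute_bin_edges(summaries, 2)
    theta = Theta(2.6, 0.00373, 0.00995, 300.0, 0.5)
    logl, eps = dataset_log_likelihood(
        data, theta, policy_set, edges, rating_mean=4.0, rating_sd=2.5,
        n_sims=150, rng=rng,
    )
    assert np.isfinite(logl)
    assert eps < 0.25
    # likelihood floor: logL >= n log(eps/C) for any eps > 0
    assert logl >= len(data) * np.log(1e-3 / 250)


def test_rating_key_is_order_free():
    assert rating_key((3, 7, 5)) == rating_key((7, 5, 3)) == (7, 5, 3)
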