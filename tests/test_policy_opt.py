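import numpy as np
import pytest
from scipy import stats

from conftest import SMALL_UCB, random_beliefs
from fixopt import (
    BeliefState,
    ModelParams,
    Policy,
    PolicySet,
    UCBConfig,
    VOCWeights,
    evaluate_policy,
    initial_belief,
    max_cost,
    policy_probabilities,
    sample_weight_vectors,
    ucb_policy_search,
)
from fixopt._ucb import RunningStats, ucb_refine

PARAMS2 = ModelParams(n_items=2, max_samples=500)
W = VOCWeights(0.4, 0.3, 0.3, 0.01)


class TestPolicyProbabilities:
    def test_uniform_at_zero_temperature(self):
        p = policy_probabilities(initial_belief(PARAMS2), Policy(W, 0.0, PARAMS2))
        np.testing.assert_allclose(p, np.full(3, 1 / 3))

    def test_proper_distribution(self, rng):
        mu, lam = random_beliefs(rng, 50, 3)
        params3 = ModelParams(n_items=3)
        for i in range(50):
            b = BeliefState(mu=mu[i], lam=lam[i], last=0)
            p = policy_probabilities(b, Policy(W, 150.0, params3))
            assert np.all(p >= 0)
            assert p.sum() == pytest.approx(1.0)

    def test_deterministic_at_high_temperature(self):
        b = BeliefState(mu=np.array([0.0, -3.0]), lam=np.array([1.0, 50.0]))
        p = policy_probabilities(b, Policy(W, 1e5, PARAMS2))
        assert p.max() > 0.999

    def test_symmetric_computations_equal_probability(self):
        b = initial_belief(PARAMS2)
        p = policy_probabilities(b, Policy(W, 300.0, PARAMS2))
        assert p[0] == pytest.approx(p[1])

    def test_no_overflow_at_extreme_beta(self):
        b = initial_belief(PARAMS2)
        p = policy_probabilities(b, Policy(W, 1e8, PARAMS2))
        assert np.all(np.isfinite(p))


class TestWeightSampling:
    def test_box_transform_example(self):
        # x = (0.2, 0.5, 0.1) -> w1:3 = [0.2, 0.3, 0.5], w4 = 0.1 * maxcost
        x1, x2, x3 = 0.2, 0.5, 0.1
        lo, hi = sorted((x1, x2))
        w13 = [lo, hi - lo, 1 - hi]
        assert w13 == pytest.approx([0.2, 0.3, 0.5])

    def test_one_point_per_box_on_simplex(self, rng):
        ws = sample_weight_vectors(PARAMS2, n_boxes_per_dim=5, rng=rng)
        assert len(ws) == 125
        for w in ws:
            assert abs(w.w1 + w.w2 + w.w3 - 1) < 1e-12
            assert min(w.w1, w.w2, w.w3, w.w4) >= 0

    def test_simplex_marginal_matches_dirichlet(self):
        """The sorted-coordinates trick yields a flat Dirichlet: the w1
        marginal is Beta(1, 2)."""
        rng = np.random.default_rng(8)
        ws = sample_weight_vectors(PARAMS2, n_boxes_per_dim=12, rng=rng)
        w1 = np.array([w.w1 for w in ws])
        res = stats.kstest(w1, stats.beta(1, 2).cdf)
        assert res.pvalue > 0.01


class TestMaxCost:
    def test_single_feature_weights_recover_feature_values(self):
        p = ModelParams(n_items=2, sigma_x=1.0)
        assert max_cost(p, [0, 1, 0]) == pytest.approx(0.3989423, abs=1e-6)
        assert max_cost(p, [0, 0, 1]) == pytest.approx(0.5641896, abs=1e-6)

    def test_bisection_agrees_with_analytic(self):
        p = ModelParams(n_items=3, sigma_x=2.0)
        w13 = [0.2, 0.5, 0.3]
        assert max_cost(p, w13, method="bisect") == pytest.approx(
            max_cost(p, w13), abs=1e-5
        )

    def test_nonnegative(self, rng):
        for _ in range(5):
            w = rng.dirichlet([1, 1, 1])
            assert max_cost(PARAMS2, w) >= 0


class TestEvaluatePolicy:
    def test_reproducible_returns(self):
        pol = Policy(W, 200.0, PARAMS2)
        a = evaluate_policy(pol, 50, np.random.default_rng(5))
        b = evaluate_policy(pol, 50, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_huge_sampling_cost_terminates_immediately(self):
        params = ModelParams(n_items=2, gamma_sample=5.0, max_samples=200)
        pol = Policy(VOCWeights(0.3, 0.3, 0.4, 0.0), 500.0, params)
        rets = evaluate_policy(pol, 300, np.random.default_rng(0))
        # immediate termination: zero cost, termination reward 0 at the prior
        assert np.all(rets == 0.0)

    def test_returns_bounded_by_payoff_identity(self):
        pol = Policy(W, 0.0, ModelParams(n_items=2, gamma_sample=0.0,
                                         gamma_switch=0.0, max_samples=50))
        rets = evaluate_policy(pol, 200, np.random.default_rng(1))
        # zero costs: the metalevel return is a posterior max-mean, finite
        assert np.all(np.isfinite(rets))


class TestUCBSearch:
    def test_refinement_bookkeeping(self):
        """Candidates never selected for refinement keep their baseline
        episode counts."""
        cfg = UCBConfig(n_boxes_per_dim=2, n_baseline=4, top_k=2,
                        n_refine=3, n_iterations=5)
        means = np.linspace(0, 1, 8)

        def eval_batch(idx, r):
            return means[idx] + 0.01 * r.standard_normal(idx.size)

        stats_ = ucb_refine(8, eval_batch, cfg, np.random.default_rng(0))
        assert stats_.n.max() == 4 + 3 * 5  # the consistently best candidate
        assert stats_.n.min() == 4

    def test_search_scores_best_above_median_candidate(self):
        """The refined search separates its best candidate from the median
        of the pool by more than twice the pooled standard error."""
        from fixopt._engine import simulate_episodes

        cfg = UCBConfig(n_boxes_per_dim=5, n_baseline=20, top_k=8,
                        n_refine=8, n_iterations=50)
        rng = np.random.default_rng(21)
        cands = sample_weight_vectors(PARAMS2, cfg.n_boxes_per_dim, rng)
        wmat = np.array([c.as_array() for c in cands])

        def eval_batch(idx, r):
            u = r.standard_normal((idx.size, 2))
            return simulate_episodes(u, wmat[idx], 364.0, PARAMS2, r).meta_return

        stats_ = ucb_refine(len(cands), eval_batch, cfg, rng)
        best = int(np.argmax(stats_.mean))
        med = float(np.median(stats_.mean))
        se_best = stats_.sd()[best] / np.sqrt(stats_.n[best])
        se_med = float(np.median(stats_.sd() / np.sqrt(stats_.n))) / np.sqrt(
            0.64 * len(cands)
        )
        assert stats_.mean[best] > med + 2 * np.hypot(se_best, se_med)

    def test_sorted_descending(self, small_ucb_config):
        pset = ucb_policy_search(PARAMS2, 300.0, small_ucb_config,
                                 np.random.default_rng(3))
        means = [r.mean_return for r in pset.records]
        assert means == sorted(means, reverse=True)
        assert len(pset) == small_ucb_config.top_k

    def test_json_roundtrip(self, tmp_path, small_ucb_config):
        pset = ucb_policy_search(PARAMS2, 250.0, small_ucb_config,
                                 np.random.default_rng(4))
        path = tmp_path / "pset.json"
        pset.to_json(path)
        again = PolicySet.from_json(path)
        assert again.to_dict() == pset.to_dict()
        np.testing.assert_array_equal(again.weight_matrix(), pset.weight_matrix())


class TestPolicyStructure:
    def test_higher_precision_never_attracts_sampling(self):
        """Raising an item's precision (all else fixed) cannot raise its
        sampling probability when w1 + w2 > 0: attention is
        uncertainty-directed."""
        rng = np.random.default_rng(13)
        params3 = ModelParams(n_items=3)
        for _ in range(40):
            w13 = rng.dirichlet([1, 1, 1])
            if w13[0] + w13[1] < 0.05:
                continue
            w = VOCWeights(*w13, w4=rng.random() * 0.05)
            pol = Policy(w, float(rng.uniform(50, 400)), params3)
            mu = rng.normal(0, 1, 3)
            lam = 1 + rng.random(3) * 10
            probs = []
            for lam0 in (lam[0], lam[0] + 2.0, lam[0] + 8.0):
                b = BeliefState(mu=mu, lam=np.array([lam0, lam[1], lam[2]]),
                                last=1)
                probs.append(policy_probabilities(b, pol)[0])
            assert probs[0] >= probs[1] - 1e-12 >= probs[2] - 2e-12

    def test_trinary_top_two_preference(self):
        """With equal precisions, the lowest-valued item is the least
        likely to be sampled."""
        rng = np.random.default_rng(17)
        params3 = ModelParams(n_items=3)
        w = VOCWeights(0.4, 0.3, 0.3, 0.005)
        pol = Policy(w, 250.0, params3)
        for _ in range(30):
            mu = np.sort(rng.normal(0, 1, 3))[::-1].copy()  # descending
            if mu[1] - mu[2] < 0.1:
                continue
            b = BeliefState(mu=mu, lam=np.full(3, 4.0), last=0)
            p = policy_probabilities(b, pol)[:3]
            # the worst-valued item is a (possibly tied) minimum
            assert p[2] <= p[0] + 1e-15 and p[2] <= p[1] + 1e-15
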