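import numpy as np
import pytest

from conftest import SMALL_UCB
from fixopt import (
    ModelParams,
    Policy,
    PriorSpec,
    Trial,
    TrueValues,
    VOCWeights,
    computations_to_fixations,
    run_episode,
    simulate_dataset,
    standardize_ratings,
    ucb_policy_search,
)
from fixopt._engine import simulate_episodes
from fixopt.simulate import Fixation, read_observed, write_dataset

PARAMS2 = ModelParams(n_items=2, max_samples=400)
W = VOCWeights(0.4, 0.3, 0.3, 0.01)


class TestStandardizeRatings:
    def test_unbiased_prior_centers_at_mean(self):
        prior = PriorSpec(alpha=1.0, rating_mean=3.492, rating_sd=2.631)
        u = standardize_ratings([3.492, 3.492], prior)
        np.testing.assert_allclose(u.u, 0.0, atol=1e-12)

    def test_zero_alpha_divides_by_sd(self):
        prior = PriorSpec(alpha=0.0, rating_mean=3.492, rating_sd=2.631)
        assert standardize_ratings([2.631, 0.0], prior).u[0] == pytest.approx(1.0)

    def test_fitted_alpha_arithmetic(self):
        prior = PriorSpec(alpha=0.581, rating_mean=3.492, rating_sd=2.631)
        u = standardize_ratings(Trial(0, (5, 5)), prior)
        assert u.u[0] == pytest.approx(1.129, abs=1e-3)

    def test_invalid_prior(self):
        with pytest.raises(ValueError):
            PriorSpec(alpha=0.5, rating_mean=0.0, rating_sd=0.0)
        with pytest.raises(ValueError):
            PriorSpec(alpha=1.5, rating_mean=0.0, rating_sd=1.0)


class TestRunLengthEncoding:
    def test_basic(self):
        fx = computations_to_fixations([0, 0, 1, 1, 1])
        assert [(f.item, f.duration_ms) for f in fx] == [(0, 200.0), (1, 300.0)]

    def test_empty(self):
        assert computations_to_fixations([]) == []

    def test_single(self):
        fx = computations_to_fixations([0])
        assert [(f.item, f.duration_ms) for f in fx] == [(0, 100.0)]

    def test_custom_duration(self):
        fx = computations_to_fixations([2, 2], sample_duration_ms=50.0)
        assert fx[0].duration_ms == 100.0


class TestRunEpisode:
    def test_deterministic_under_seed(self):
        pol = Policy(W, 200.0, PARAMS2)
        u = TrueValues(u=np.array([0.5, -0.2]))
        a = run_episode(pol, u, np.random.default_rng(3))
        b = run_episode(pol, u, np.random.default_rng(3))
        assert a.computations == b.computations and a.choice == b.choice

    def test_total_time_is_100ms_per_sample(self):
        pol = Policy(W, 200.0, PARAMS2)
        u = TrueValues(u=np.array([0.5, -0.2]))
        t = run_episode(pol, u, np.random.default_rng(6))
        assert t.total_fixation_time_ms == 100.0 * len(t.computations)
        assert sum(f.duration_ms for f in t.fixations) == t.total_fixation_time_ms

    def test_prohibitive_cost_terminates_immediately(self):
        params = ModelParams(n_items=2, gamma_sample=2.0, max_samples=100)
        pol = Policy(VOCWeights(0.3, 0.3, 0.4, 0.0), 500.0, params)
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = run_episode(pol, TrueValues(u=np.zeros(2)), rng)
            assert t.computations == []
            assert t.fixations == []

    def test_first_computation_uniform_over_items(self):
        """Symmetric initial beliefs give every item the same probability
        of receiving the first sample."""
        pol = Policy(W, 300.0, ModelParams(n_items=3, max_samples=2))
        rng = np.random.default_rng(8)
        firsts = []
        for _ in range(900):
            t = run_episode(pol, TrueValues(u=np.array([0.2, 0.0, -0.2])), rng)
            if t.computations:
                firsts.append(t.computations[0])
        freqs = np.bincount(firsts, minlength=3) / len(firsts)
        assert np.all(np.abs(freqs - 1 / 3) < 0.06)

    def test_noiseless_sampling_resolves_quickly(self):
        params = ModelParams(n_items=2, sigma_x=1e-3, gamma_sample=0.002,
                             gamma_switch=0.002, max_samples=400)
        pol = Policy(VOCWeights(0.5, 0.3, 0.2, 0.0), 1e4, params)
        rng = np.random.default_rng(10)
        u = TrueValues(u=np.array([0.8, -0.5]))
        t = run_episode(pol, u, rng)
        # near-perfect samples: a couple of fixations, then the best item
        assert len(t.computations) <= 10
        assert t.choice == 0


def test_engine_agrees_with_scalar_reference():
    """The vectorized engine and the scalar episode loop induce the same
    behavior distribution (means within 4 combined SEs)."""
    pol = Policy(W, 250.0, PARAMS2)
    u = np.array([0.6, -0.1])
    rng = np.random.default_rng(14)
    scal = [run_episode(pol, TrueValues(u=u), rng) for _ in range(400)]
    s_samples = np.array([len(t.computations) for t in scal])
    s_choice = np.array([t.choice for t in scal])
    batch = simulate_episodes(
        np.broadcast_to(u, (3000, 2)), W.as_array(), 250.0, PARAMS2,
        np.random.default_rng(15),
    )
    for a, b in ((s_samples, batch.total_samples), (s_choice == 0, batch.choice == 0)):
        se = np.hypot(a.std(ddof=1) / np.sqrt(a.size), b.std(ddof=1) / np.sqrt(b.size))
        assert abs(a.mean() - b.mean()) < 4 * se


@pytest.fixture(scope="module")
def policy_set():
    return ucb_policy_search(PARAMS2, 300.0, SMALL_UCB,
                             np.random.default_rng(2))


class TestSimulateDataset:
    PRIOR = PriorSpec(alpha=0.5, rating_mean=4.0, rating_sd=2.5)
    TRIALS = [Trial(0, (5, 3)), Trial(1, (2, 6))]

    def test_counts_and_invariants(self, policy_set):
        sims = simulate_dataset(policy_set, self.TRIALS, self.PRIOR,
                                n_sims_per_policy=2,
                                rng=np.random.default_rng(5))
        assert len(sims) == 2 * len(policy_set) * 2
        for s in sims:
            assert s.total_fixation_time_ms == 100.0 * len(s.computations)
            assert sum(f.duration_ms for f in s.fixations) == s.total_fixation_time_ms
            rle = computations_to_fixations(s.computations)
            assert [(f.item, f.duration_ms) for f in rle] == [
                (f.item, f.duration_ms) for f in s.fixations
            ]

    def test_reproducible(self, policy_set):
        a = simulate_dataset(policy_set, self.TRIALS, self.PRIOR, 1,
                             np.random.default_rng(9))
        b = simulate_dataset(policy_set, self.TRIALS, self.PRIOR, 1,
                             np.random.default_rng(9))
        assert [(s.choice, tuple(s.computations)) for s in a] == [
            (s.choice, tuple(s.computations)) for s in b
        ]

    def test_csv_roundtrip(self, policy_set, tmp_path):
        sims = simulate_dataset(policy_set, self.TRIALS, self.PRIOR, 1,
                                np.random.default_rng(11))
        # single-policy-episode view in observed format
        from fixopt.simulate import ObservedTrial

        picked = {}
        for s in sims:
            picked.setdefault(s.trial_id, s)
        obs = [
            ObservedTrial(trial_id=s.trial_id, ratings=s.ratings,
                          fixations=s.fixations, choice=s.choice)
            for s in picked.values()
        ]
        write_dataset(obs, tmp_path)
        again = read_observed(tmp_path)
        assert len(again) == len(obs)
        for x, y in zip(obs, again):
            assert x.choice == y.choice
            assert tuple(x.ratings) == tuple(y.ratings)
            assert [(f.item, f.duration_ms) for f in x.fixations] == [
                (f.item, f.duration_ms) for f in y.fixations
            ]
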