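"""Acquisition scores, batch selectors, and the hybrid families."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alscreen import EnsemblePrediction, StrategyConfig, parse_strategy
from alscreen.acquisition import (ALL_STRATEGY_NAMES, default_strategies,
                                  random_phase_iterations, score_greedy,
                                  score_gu, score_uncertainty,
                                  select_diversity, select_hybrid_iteration,
                                  select_hybrid_sampling, select_random,
                                  select_top_n)
from alscreen.errors import ConfigError, DegenerateInputError


def _pred(mu, sigma=None):
    mu = np.asarray(mu, dtype=float)
    sigma = np.zeros_like(mu) if sigma is None else np.asarray(sigma, float)
    return EnsemblePrediction(mu=mu, sigma=sigma,
                              member_preds=np.vstack([mu, mu]))


class TestScores:
    def test_greedy_prefers_low_predicted_auc(self):
        scores = score_greedy(_pred([0.3, 0.8, 0.1]))
        np.testing.assert_allclose(scores, [-0.3, -0.8, -0.1])
        assert np.argmax(scores) == 2

    def test_uncertainty_ignores_mu(self):
        a = score_uncertainty(_pred([0.1, 0.9], [0.0, 0.2]))
        b = score_uncertainty(_pred([5.1, 5.9], [0.0, 0.2]))
        np.testing.assert_allclose(a, b)
        assert np.argmax(a) == 1

    def test_gu_is_sum_of_parts(self):
        pred = _pred([0.5], [0.2])
        assert score_gu(pred)[0] == pytest.approx(-0.3)

    def test_gu_degenerates_to_greedy_when_sigma_zero(self):
        pred = _pred([0.4, 0.1, 0.7])
        np.testing.assert_allclose(np.argsort(score_gu(pred)),
                                   np.argsort(score_greedy(pred)))

    def test_gu_degenerates_to_uncertainty_when_mu_constant(self):
        pred = _pred([0.5, 0.5, 0.5], [0.1, 0.3, 0.2])
        np.testing.assert_allclose(np.argsort(score_gu(pred)),
                                   np.argsort(score_uncertainty(pred)))


class TestSelectTopN:
    def test_highest_scores_win(self):
        batch = select_top_n(np.array([0.5, 0.9, 0.1]),
                             np.array([10, 11, 12]), n=2)
        assert set(batch.selected_idx) == {11, 10}

    def test_tie_broken_by_ascending_candidate_index(self):
        batch = select_top_n(np.array([0.5, 0.5, 0.1]),
                             np.array([7, 3, 9]), n=1)
        assert batch.selected_idx.tolist() == [3]

    def test_short_candidate_pool_returns_everything(self):
        batch = select_top_n(np.array([0.2, 0.1]), np.array([1, 2]), n=20)
        assert set(batch.selected_idx) == {1, 2}

    def test_empty_pool_rejected(self):
        with pytest.raises(DegenerateInputError):
            select_top_n(np.array([]), np.array([], dtype=int), n=5)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_to_monotone_rescaling(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.standard_normal(15)
        cand = np.arange(100, 115)
        a = select_top_n(scores, cand, 6).selected_idx
        b = select_top_n(3.0 * scores + 7.0, cand, 6).selected_idx
        np.testing.assert_array_equal(a, b)


class TestSelectRandom:
    def test_deterministic_and_within_pool(self):
        cand = np.arange(30, 60)
        a = select_random(cand, 10, seed=4).selected_idx
        b = select_random(cand, 10, seed=4).selected_idx
        np.testing.assert_array_equal(a, b)
        assert np.isin(a, cand).all() and np.unique(a).size == 10

    def test_oversized_request_returns_all(self):
        cand = np.arange(5)
        assert set(select_random(cand, 10, seed=0).selected_idx) == set(cand)

    def test_uniform_inclusion_frequency(self):
        # each of 20 candidates should appear with frequency 5/20 = 0.25
        cand = np.arange(20)
        counts = np.zeros(20)
        n_draws = 2000
        for seed in range(n_draws):
            counts[select_random(cand, 5, seed=seed).selected_idx] += 1
        freq = counts / n_draws
        se = np.sqrt(0.25 * 0.75 / n_draws)
        assert (np.abs(freq - 0.25) < 5 * se).all()


class TestSelectDiversity:
    def test_full_pool_returns_every_candidate(self):
        X = np.random.default_rng(0).standard_normal((4, 3))
        batch = select_diversity(X, np.arange(4), n=4, seed=0)
        assert set(batch.selected_idx) == {0, 1, 2, 3}

    def test_two_separated_blobs_get_one_pick_each(self):
        rng = np.random.default_rng(3)
        blob_a = rng.normal(0, 0.3, size=(20, 2))
        blob_b = rng.normal(10, 0.3, size=(20, 2))
        X = np.vstack([blob_a, blob_b])
        batch = select_diversity(X, np.arange(40), n=2, seed=1)
        sides = {int(i) // 20 for i in batch.selected_idx}
        assert sides == {0, 1}

    def test_duplicated_rows_still_give_unique_indices(self):
        X = np.tile(np.array([[0.0, 0.0], [5.0, 5.0]]), (5, 1))
        batch = select_diversity(X, np.arange(10), n=2, seed=0)
        assert np.unique(batch.selected_idx).size == 2

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(0).standard_normal((30, 4))
        a = select_diversity(X, np.arange(30), 5, seed=2).selected_idx
        b = select_diversity(X, np.arange(30), 5, seed=2).selected_idx
        np.testing.assert_array_equal(a, b)


class TestHybridSampling:
    def _cfg(self, ps, n=20):
        return StrategyConfig("hybrid_sampling", ps=ps, batch_n=n)

    def test_ps_020_gives_4_random_16_model(self):
        pred = _pred(np.linspace(0, 1, 50), np.zeros(50))
        batch = select_hybrid_sampling(pred, np.arange(50), self._cfg(0.2),
                                       seed=0)
        assert batch.provenance.count("random") == 4
        assert batch.provenance.count("model") == 16
        assert np.unique(batch.selected_idx).size == 20

    def test_ps_zero_equals_pure_gu(self):
        mu = np.random.default_rng(1).random(30)
        sigma = np.random.default_rng(2).random(30) * 0.1
        pred = _pred(mu, sigma)
        cand = np.arange(30)
        hybrid = select_hybrid_sampling(pred, cand, self._cfg(0.0, 10), seed=5)
        pure = select_top_n(score_gu(pred), cand, 10)
        np.testing.assert_array_equal(np.sort(hybrid.selected_idx),
                                      np.sort(pure.selected_idx))

    def test_ps_one_has_no_model_picks(self):
        pred = _pred(np.zeros(30))
        batch = select_hybrid_sampling(pred, np.arange(30),
                                       self._cfg(1.0, 10), seed=3)
        assert set(batch.provenance) == {"random"}


class TestHybridIteration:
    def _cfg(self, pi, n=10):
        return StrategyConfig("hybrid_iteration", pi=pi, batch_n=n)

    def test_boundary_uses_ceil(self):
        assert random_phase_iterations(0.3, 10) == 3
        assert random_phase_iterations(0.25, 10) == 3  # any pi>0 rounds up
        assert random_phase_iterations(0.0, 10) == 0
        assert random_phase_iterations(1.0, 10) == 10

    def test_random_then_gu_schedule(self):
        pred = _pred(np.linspace(0, 1, 40))
        cand = np.arange(40)
        cfg = self._cfg(0.3)
        early = select_hybrid_iteration(pred, cand, cfg, iteration=3,
                                        total_iterations=10, seed=9)
        late = select_hybrid_iteration(pred, cand, cfg, iteration=4,
                                       total_iterations=10, seed=9)
        np.testing.assert_array_equal(
            early.selected_idx, select_random(cand, 10, seed=9).selected_idx)
        np.testing.assert_array_equal(
            late.selected_idx,
            select_top_n(score_gu(pred), cand, 10).selected_idx)


class TestStrategyConfig:
    def test_thirteen_default_analyses(self):
        strategies = default_strategies()
        assert len(strategies) == 13
        assert [s.label for s in strategies] == ALL_STRATEGY_NAMES

    def test_parse_roundtrip(self):
        s = parse_strategy("hybrid_sampling:0.3", batch_n=10)
        assert (s.name, s.ps, s.batch_n) == ("hybrid_sampling", 0.3, 10)
        assert s.label == "hybrid_sampling:0.3"

    @pytest.mark.parametrize("bad", ["margin", "greedy:0.2",
                                     "hybrid_sampling"])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ConfigError):
            parse_strategy(bad)

    def test_hybrid_param_required_and_exclusive(self):
        with pytest.raises(ConfigError):
            StrategyConfig("hybrid_sampling")
        with pytest.raises(ConfigError):
            StrategyConfig("greedy", ps=0.2)
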