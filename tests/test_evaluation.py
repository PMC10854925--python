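"""Ranking and the paired cross-drug statistical comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from alscreen import (paired_t_test, rank_methods, wilcoxon_signed_rank,
                      build_comparison_tables, method_summary)
from alscreen.errors import ConfigError, SchemaError


def _exhaustive_signed_rank_p(diffs):
    """Independent oracle: full 2^n sign-flip enumeration."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    totals = [np.sum([r for r, s in zip(ranks, signs) if s > 0])
              for signs in itertools.product((-1, 1), repeat=len(d))]
    totals = np.asarray(totals)
    p_le = np.mean(totals <= observed + 1e-12)
    p_ge = np.mean(totals >= observed - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestRankMethods:
    def test_highest_value_gets_rank_one(self):
        df = pd.DataFrame({"a": [0.9], "b": [0.5], "c": [0.7]},
                          index=["d1"])
        ranks = rank_methods(df)
        assert ranks.loc["d1"].tolist() == [1.0, 3.0, 2.0]

    def test_thirteen_methods_span_ranks_one_to_thirteen(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.random((4, 13)),
                          columns=[f"m{i}" for i in range(13)])
        ranks = rank_methods(df)
        assert ranks.min(axis=1).eq(1.0).all()
        assert ranks.max(axis=1).eq(13.0).all()

    def test_ties_get_average_rank(self):
        df = pd.DataFrame({"a": [0.9], "b": [0.9], "c": [0.1]})
        assert rank_methods(df).iloc[0].tolist() == [1.5, 1.5, 3.0]

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), s=st.integers(2, 13))
    def test_rank_sum_conservation(self, seed, s):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.integers(0, 4, size=(3, s)) / 4.0)
        sums = rank_methods(df).sum(axis=1)
        assert np.allclose(sums, s * (s + 1) / 2)

    def test_missing_method_rejected(self):
        df = pd.DataFrame({"a": [0.9, np.nan], "b": [0.5, 0.4]})
        with pytest.raises(SchemaError):
            rank_methods(df)


class TestPairedT:
    def test_matches_textbook_formula(self):
        x = np.array([0.1, -0.2, 0.3, 0.05, 0.15])
        y = np.zeros(5)
        res = paired_t_test(x, y)
        d = x - y
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p = 2 * stats.t.sf(abs(t), df=len(d) - 1)
        assert res.p == pytest.approx(p, abs=1e-10)
        assert res.mean_diff == pytest.approx(d.mean())

    def test_sign_convention_positive_means_method_better(self):
        res = paired_t_test([0.6, 0.7], [0.1, 0.2])
        assert res.mean_diff == pytest.approx(0.5)

    def test_identical_inputs_flagged_with_p_one(self):
        res = paired_t_test([0.3, 0.4], [0.3, 0.4])
        assert res.p == 1.0 and res.degenerate

    def test_constant_nonzero_differences_flagged_with_p_zero(self):
        res = paired_t_test([2.0, 2.0, 2.0, 2.0], [1.0, 1.0, 1.0, 1.0])
        assert res.p == 0.0 and res.degenerate and res.mean_diff == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(8), rng.random(8)
        assert paired_t_test(x, y).mean_diff == pytest.approx(
            -paired_t_test(y, x).mean_diff)
        assert paired_t_test(x, y).p == pytest.approx(paired_t_test(y, x).p)


class TestWilcoxon:
    def test_five_uniform_wins_give_exact_0625(self):
        # method ranked one better on all five drugs: two-sided p = 2/2^5
        baseline = np.array([5.0, 6, 7, 8, 9])
        method = baseline - 1
        res = wilcoxon_signed_rank(method, baseline)
        assert res.p == pytest.approx(0.0625)
        assert res.mean_diff == pytest.approx(1.0)

    def test_identical_ranks_give_p_one(self):
        res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.p == 1.0 and res.degenerate

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 12)
        method = rng.integers(1, 14, size=n).astype(float)
        baseline = rng.integers(1, 14, size=n).astype(float)
        if np.all(method == baseline):
            method[0] += 1
        res = wilcoxon_signed_rank(method, baseline)
        assert res.p == pytest.approx(
            _exhaustive_signed_rank_p(baseline - method), abs=1e-12)

    def test_matches_scipy_exact_when_tie_free(self):
        method = np.array([1.0, 2.5, 3.0, 7.0, 9.0, 4.5])
        baseline = np.array([2.0, 4.5, 6.0, 8.5, 4.0, 10.0])
        ours = wilcoxon_signed_rank(method, baseline)
        ref = stats.wilcoxon(baseline - method, method="exact")
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_differences_dropped_from_statistic(self):
        # pairs (3,3) contribute nothing; remaining pair decides
        res = wilcoxon_signed_rank([3.0, 3.0, 1.0], [3.0, 3.0, 2.0])
        assert res.p == pytest.approx(1.0)  # single pair: 2*min(.5,1) capped
        assert res.mean_diff == pytest.approx(1 / 3)


def _toy_benchmark():
    """4 drugs x 3 strategies x 2 repeats with a known ordering."""
    rows = []
    base = {"greedy": 0.30, "random": 0.20, "uncertainty": 0.25}
    for d in range(4):
        for strat, level in base.items():
            for rep in (1, 2):
                rows.append({
                    "drug_id": f"d{d}", "strategy": strat, "repeat": rep,
                    "auc_hit": 0.5 + level + 0.01 * d + 0.001 * rep,
                    "auc_per": level + 0.02 * d + 0.002 * rep,
                })
    return pd.DataFrame(rows)


class TestComparisonTables:
    def test_structure_mirrors_method_by_baseline_layout(self):
        tables = build_comparison_tables(_toy_benchmark())
        for metric in ("auc_hit", "auc_per_norm"):
            for baseline in ("greedy", "random"):
                t = tables[f"{metric}_vs_{baseline}"]
                assert len(t) == 2  # 3 strategies minus the baseline
                assert baseline not in set(t["method"])

    def test_sign_conventions_agree_with_known_ordering(self):
        tables = build_comparison_tables(_toy_benchmark())
        vs_random = tables["auc_hit_vs_random"].set_index("method")
        assert vs_random.loc["greedy", "mean_value_diff"] > 0
        assert vs_random.loc["greedy", "mean_rank_diff"] > 0
        vs_greedy = tables["auc_hit_vs_greedy"].set_index("method")
        assert vs_greedy.loc["random", "mean_value_diff"] < 0

    def test_antisymmetric_value_diffs(self):
        tables = build_comparison_tables(_toy_benchmark())
        ab = tables["auc_hit_vs_greedy"].set_index("method").loc[
            "random", "mean_value_diff"]
        ba = tables["auc_hit_vs_random"].set_index("method").loc[
            "greedy", "mean_value_diff"]
        assert ab == pytest.approx(-ba)

    def test_missing_baseline_rejected(self):
        df = _toy_benchmark()
        df = df[df.strategy != "greedy"]
        with pytest.raises(SchemaError):
            build_comparison_tables(df)

    def test_method_summary_has_both_metrics(self):
        summary = method_summary(_toy_benchmark())
        assert set(summary["metric"]) == {"auc_hit", "auc_per_norm"}
        assert len(summary) == 6
        random_rank = summary[(summary.metric == "auc_per_norm")
                              & (summary.method == "random")]
        assert random_rank["mean_rank"].iloc[0] == pytest.approx(3.0)


def test_rank_inputs_too_small_rejected():
    with pytest.raises(ConfigError):
        rank_methods(pd.DataFrame({"only": [0.5]}))
    with pytest.raises(ConfigError):
        paired_t_test([0.1], [0.2])
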