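"""Cross-drug ranking and paired statistical comparison of strategies.

Per drug, each strategy's metric is averaged over repeats; strategies are
then ranked within each drug (rank 1 = highest metric, ties get average
ranks).  Every strategy is compared against the two baselines (greedy and
random) with a two-sided paired t-test on the per-drug mean values and a
two-sided Wilcoxon signed-rank test on the per-drug ranks.  Sign
conventions: a positive value difference (method - baseline) and a positive
rank difference (baseline rank - method rank) both mean the method is
better than the baseline.

p-values are reported raw (no multiple-testing correction by default; Holm
correction is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, SchemaError
from .metrics import normalize_auc_per

EXACT_WILCOXON_MAX_N = 25
BASELINES = ("greedy", "random")


@dataclass
class PairedTestResult:
    """Outcome of one paired comparison."""

    p: float
    mean_diff: float
    degenerate: bool = False


def rank_methods(per_drug_means: pd.DataFrame) -> pd.DataFrame:
    """Rank strategies within each drug; 1 = highest metric value.

    Parameters
    ----------
    per_drug_means : DataFrame
        Index = drug_id, columns = strategy, values = per-drug metric means.
        Ties receive the average of the covered positions.
    """
    if per_drug_means.shape[1] < 2:
        raise ConfigError("need at least two methods to rank")
    if per_drug_means.isna().any().any():
        bad = per_drug_means.columns[per_drug_means.isna().any()][0]
        raise SchemaError(f"missing metric value for method {bad!r}")
    return per_drug_means.rank(axis=1, ascending=False, method="average")


def paired_t_test(method_values: Sequence[float],
                  baseline_values: Sequence[float]) -> PairedTestResult:
    """Two-sided paired t-test on (method - baseline) across drugs.

    Degenerate variance is kept total rather than NaN: all-zero differences
    report p = 1, zero-variance nonzero-mean differences report p = 0; both
    carry the ``degenerate`` flag.
    """
    x = np.asarray(method_values, dtype=float)
    y = np.asarray(baseline_values, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ConfigError("paired test needs two equal-length arrays, n >= 2")
    d = x - y
    mean_diff = float(d.mean())
    if np.allclose(d, d[0]):
        if mean_diff == 0.0:
            return PairedTestResult(p=1.0, mean_diff=0.0, degenerate=True)
        return PairedTestResult(p=0.0, mean_diff=mean_diff, degenerate=True)
    t = stats.ttest_rel(x, y)
    return PairedTestResult(p=float(t.pvalue), mean_diff=mean_diff)


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (sum of ranks of positive differences) and the |d| ranks."""
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), ranks


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p under the sign-flip null, tolerating tied ranks.

    Ranks are doubled so average ranks become integers, then the null
    distribution of 2*W+ is built by dynamic-programming convolution over
    the 2^n equiprobable sign assignments.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled:
        nxt = pmf.copy()
        nxt[r:] += pmf[:total + 1 - r]
        pmf = nxt / 2.0
    w2 = int(round(2 * w_plus))
    p_le = pmf[:w2 + 1].sum()
    p_ge = pmf[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _approx_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Normal approximation with tie correction (no continuity correction)."""
    n = ranks.size
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts ** 3 - counts).sum() / 48.0
    if var <= 0:
        return 1.0
    z = (w_plus - mean) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def wilcoxon_signed_rank(method_ranks: Sequence[float],
                         baseline_ranks: Sequence[float]) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired rank differences.

    Differences are oriented baseline - method, so a positive mean means the
    method holds better (lower) ranks.  Zero differences are dropped from
    the test statistic (Wilcoxon's original treatment) but kept in the
    reported mean.  The null is exact (sign-flip enumeration via DP) for
    n <= 25 non-zero pairs, and a tie-corrected normal approximation above.
    """
    mr = np.asarray(method_ranks, dtype=float)
    br = np.asarray(baseline_ranks, dtype=float)
    if mr.shape != br.shape or mr.size < 2:
        raise ConfigError("paired test needs two equal-length arrays, n >= 2")
    d_all = br - mr
    mean_rank_diff = float(d_all.mean())
    d = d_all[d_all != 0]
    if d.size == 0:
        return PairedTestResult(p=1.0, mean_diff=0.0, degenerate=True)
    w_plus, ranks = _signed_rank_statistic(d)
    if d.size <= EXACT_WILCOXON_MAX_N:
        p = _exact_signed_rank_p(w_plus, ranks)
    else:
        p = _approx_signed_rank_p(w_plus, ranks)
    return PairedTestResult(p=p, mean_diff=mean_rank_diff)


def per_drug_means(benchmark: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Pivot the benchmark to per-(drug, strategy) means over repeats."""
    if metric not in benchmark.columns:
        raise SchemaError(f"benchmark table has no column {metric!r}")
    return benchmark.pivot_table(index="drug_id", columns="strategy",
                                 values=metric, aggfunc="mean")


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    adj = np.empty_like(pvals)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (len(pvals) - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def compare_to_baseline(values: pd.DataFrame, ranks: pd.DataFrame,
                        baseline: str, metric: str,
                        holm: bool = False) -> pd.DataFrame:
    """Compare every non-baseline method against one baseline.

    One row per method with the paired t-test on per-drug mean values and
    the Wilcoxon signed-rank test on per-drug ranks; ``significant`` marks
    p < 0.05 together with a positive value difference.
    """
    if baseline not in values.columns:
        raise SchemaError(f"baseline {baseline!r} missing from benchmark")
    rows = []
    for method in values.columns:
        if method == baseline:
            continue
        t = paired_t_test(values[method], values[baseline])
        w = wilcoxon_signed_rank(ranks[method], ranks[baseline])
        rows.append({
            "method": method, "baseline": baseline, "metric": metric,
            "value_p": t.p, "mean_value_diff": t.mean_diff,
            "rank_p": w.p, "mean_rank_diff": w.mean_diff,
            "significant": bool(t.p < 0.05 and t.mean_diff > 0),
        })
    out = pd.DataFrame(rows)
    if holm:
        out["value_p_holm"] = _holm(out["value_p"].to_numpy())
        out["rank_p_holm"] = _holm(out["rank_p"].to_numpy())
    return out


def build_comparison_tables(benchmark: pd.DataFrame,
                            baselines: Sequence[str] = BASELINES,
                            normalization: str = "random_mean",
                            holm: bool = False) -> dict[str, pd.DataFrame]:
    """Run the full cross-drug comparison for both metrics and baselines.

    Returns a dict with the comparison tables (one per metric x baseline,
    keyed e.g. ``auc_hit_vs_greedy``) plus the per-drug mean and rank
    matrices behind them (``auc_hit_means``, ``auc_hit_ranks``,
    ``auc_per_norm_means``, ``auc_per_norm_ranks``).
    """
    with_norm = normalize_auc_per(benchmark, mode=normalization)
    out: dict[str, pd.DataFrame] = {}
    for metric in ("auc_hit", "auc_per_norm"):
        means = per_drug_means(with_norm, metric)
        ranks = rank_methods(means)
        out[f"{metric}_means"] = means
        out[f"{metric}_ranks"] = ranks
        for baseline in baselines:
            out[f"{metric}_vs_{baseline}"] = compare_to_baseline(
                means, ranks, baseline, metric, holm=holm)
    return out


def method_summary(benchmark: pd.DataFrame,
                   normalization: str = "random_mean") -> pd.DataFrame:
    """Mean +/- SD of each metric (and rank) per method across drugs."""
    with_norm = normalize_auc_per(benchmark, mode=normalization)
    rows = []
    for metric in ("auc_hit", "auc_per_norm"):
        means = per_drug_means(with_norm, metric)
        ranks = rank_methods(means)
        for method in means.columns:
            rows.append({
                "metric": metric, "method": method,
                "mean": means[method].mean(),
                "sd": means[method].std(ddof=0),
                "mean_rank": ranks[method].mean(),
                "sd_rank": ranks[method].std(ddof=0),
            })
    return pd.DataFrame(rows)


def write_tables(tables: dict[str, pd.DataFrame], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv",
                  index=name.endswith(("_means", "_ranks")))
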