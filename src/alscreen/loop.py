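"""The iterate-train-predict-select-label cycle and its orchestration.

One *run* is a full active-learning trajectory for a (drug, strategy,
split-seed) triple: starting from the initial split, each iteration trains
the ensemble on the labeled set, scores the holdout set (p_i), selects a
batch Ds_i from the candidate pool with the strategy, and moves the batch
into the labeled set, until the candidate pool is exhausted.  The holdout
R^2 is measured *before* the batch is added (measure-then-select), so p_1
reflects the initial labeled set.

The ensemble is trained every iteration even for strategies that never read
candidate predictions (random, diversity), because p_i must be recorded;
only the candidate-set prediction step is skipped for them.

Repeats and strategies are paired: the split seed of repeat k depends only
on the master seed and k, so all strategies see identical holdout, initial
labeled, and candidate sets in repeat k -- a prerequisite for the paired
statistical comparisons downstream.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import derive_seed
from . import acquisition as acq
from .acquisition import SelectionBatch, StrategyConfig, uses_predictions
from .data import DrugScreen, SplitState, make_initial_split
from .ensemble import EnsembleConfig, predict_stats, train_ensemble, \
    holdout_performance
from .errors import AlscreenError, ConfigError
from .metrics import MetricCurve, auc_hit, auc_per, cumulative_hit_rate

log = logging.getLogger(__name__)

DEFAULT_N_REPEATS = 50
DEFAULT_HOLDOUT_FRAC = 0.15
DEFAULT_INIT_LABELED_FRAC = 0.10


@dataclass
class IterationRecord:
    """Bookkeeping for one iteration of one run."""

    iteration: int
    selected_idx: np.ndarray
    n_hits_selected: int
    holdout_r2: float
    labeled_size_after: int

    def to_dict(self) -> dict:
        return {
            "iteration": self.iteration,
            "selected_idx": [int(i) for i in self.selected_idx],
            "n_hits_selected": self.n_hits_selected,
            "holdout_r2": self.holdout_r2,
            "labeled_size_after": self.labeled_size_after,
        }


@dataclass
class RunResult:
    """Everything produced by one (drug, strategy, repeat) run."""

    drug_id: str
    strategy: StrategyConfig
    split_seed: int
    records: list[IterationRecord]
    total_iterations: int
    initial_candidate_hits: int
    initial_split: SplitState
    r_curve: np.ndarray = field(default=None)  # type: ignore[assignment]
    auc_hit: float = float("nan")
    auc_per: float = float("nan")

    @property
    def p_curve(self) -> np.ndarray:
        return np.array([r.holdout_r2 for r in self.records])


def total_iteration_count(n_candidates: int, batch_n: int) -> int:
    """I = ceil(|Dc_1| / batch_n), fixed before the loop starts."""
    return math.ceil(n_candidates / batch_n)


def _select(screen: DrugScreen, strategy: StrategyConfig, pred,
            candidate_idx: np.ndarray, iteration: int, total_iterations: int,
            sel_seed: int) -> SelectionBatch:
    name = strategy.name
    if name == "random":
        return acq.select_random(candidate_idx, strategy.batch_n, sel_seed)
    if name == "diversity":
        return acq.select_diversity(screen.features[candidate_idx],
                                    candidate_idx, strategy.batch_n, sel_seed)
    if name == "greedy":
        return acq.select_top_n(acq.score_greedy(pred), candidate_idx,
                                strategy.batch_n)
    if name == "uncertainty":
        return acq.select_top_n(acq.score_uncertainty(pred), candidate_idx,
                                strategy.batch_n)
    if name == "gu_combined":
        return acq.select_top_n(acq.score_gu(pred), candidate_idx,
                                strategy.batch_n)
    if name == "hybrid_sampling":
        return acq.select_hybrid_sampling(pred, candidate_idx, strategy,
                                          sel_seed)
    if name == "hybrid_iteration":
        return acq.select_hybrid_iteration(pred, candidate_idx, strategy,
                                           iteration, total_iterations,
                                           sel_seed)
    if name == "oracle":
        # reference upper bound used by tests: lowest true response first
        return acq.select_top_n(-screen.responses[candidate_idx],
                                candidate_idx, strategy.batch_n)
    raise ConfigError(f"unknown strategy {name!r}")


def run_active_learning(screen: DrugScreen, strategy: StrategyConfig,
                        ens_cfg: EnsembleConfig, split_seed: int,
                        holdout_frac: float = DEFAULT_HOLDOUT_FRAC,
                        init_labeled_frac: float = DEFAULT_INIT_LABELED_FRAC,
                        ) -> RunResult:
    """Run one full active-learning trajectory.

    Per-iteration selection and ensemble seeds are derived from
    ``split_seed`` and the iteration index only -- never from the strategy --
    so strategies that degenerate into one another (e.g. the iteration
    hybrid with pi=1 vs pure random) produce identical batches under a
    shared split seed.
    """
    try:
        split = make_initial_split(screen, holdout_frac, init_labeled_frac,
                                   seed=split_seed)
    except AlscreenError as exc:
        raise type(exc)(
            f"[drug={screen.drug_id} strategy={strategy.label} "
            f"seed={split_seed}] {exc}") from exc
    m = screen.n_cell_lines
    holdout = split.holdout_idx
    labeled = split.labeled_idx.copy()
    candidates = split.candidate_idx.copy()
    total_iters = total_iteration_count(candidates.size, strategy.batch_n)
    initial_candidate_hits = int(screen.is_hit(candidates).sum())

    records: list[IterationRecord] = []
    hits_per_iter: list[int] = []
    X, y = screen.features, screen.responses
    for i in range(1, total_iters + 1):
        ens_seed = derive_seed(split_seed, 5, i)
        try:
            ens = train_ensemble(X[labeled], y[labeled],
                                 ens_cfg.with_seed(ens_seed))
        except AlscreenError as exc:
            raise type(exc)(
                f"[drug={screen.drug_id} strategy={strategy.label} "
                f"seed={split_seed} iter={i}] {exc}") from exc
        p_i = holdout_performance(ens, X[holdout], y[holdout])
        pred = (predict_stats(ens, X[candidates])
                if uses_predictions(strategy, i, total_iters) else None)
        sel_seed = derive_seed(split_seed, 3, i)
        batch = _select(screen, strategy, pred, candidates, i, total_iters,
                        sel_seed)
        n_hits = int(screen.is_hit(batch.selected_idx).sum())
        labeled = np.sort(np.concatenate([labeled, batch.selected_idx]))
        candidates = np.setdiff1d(candidates, batch.selected_idx,
                                  assume_unique=True)
        SplitState(holdout, labeled, candidates, iteration=i + 1
                   ).validate(m=m)  # partition contract after bookkeeping
        records.append(IterationRecord(
            iteration=i, selected_idx=batch.selected_idx,
            n_hits_selected=n_hits, holdout_r2=p_i,
            labeled_size_after=labeled.size))
        hits_per_iter.append(n_hits)
        log.debug("drug=%s strategy=%s seed=%d iter=%d/%d labeled=%d "
                  "hits=%d r2=%.3f", screen.drug_id, strategy.label,
                  split_seed, i, total_iters, labeled.size, n_hits, p_i)
    if candidates.size:
        raise AlscreenError("candidate set not exhausted after final "
                            "iteration (internal error)")

    r_curve = cumulative_hit_rate(hits_per_iter, initial_candidate_hits)
    p_curve = MetricCurve(np.array([r.holdout_r2 for r in records]),
                          kind="r_squared")
    return RunResult(
        drug_id=screen.drug_id, strategy=strategy, split_seed=split_seed,
        records=records, total_iterations=total_iters,
        initial_candidate_hits=initial_candidate_hits, initial_split=split,
        r_curve=r_curve.values, auc_hit=auc_hit(r_curve),
        auc_per=auc_per(p_curve))


def repeat_split_seed(master_seed: int, repeat: int) -> int:
    """Split seed for repeat k; strategy-independent so runs are paired."""
    return derive_seed(master_seed, 2, repeat)


def run_repeats(screen: DrugScreen, strategy: StrategyConfig,
                ens_cfg: EnsembleConfig,
                n_repeats: int = DEFAULT_N_REPEATS,
                master_seed: int = 0,
                holdout_frac: float = DEFAULT_HOLDOUT_FRAC,
                init_labeled_frac: float = DEFAULT_INIT_LABELED_FRAC,
                ) -> list[RunResult]:
    """Run ``n_repeats`` independent splits of one (drug, strategy) pair.

    Each repeat draws a fresh holdout *and* initial labeled set.  Repeats are
    mutually independent given their derived seeds, so results are identical
    whether they execute sequentially or concurrently.
    """
    if n_repeats < 1:
        raise ConfigError("n_repeats must be >= 1")
    return [
        run_active_learning(screen, strategy, ens_cfg,
                            repeat_split_seed(master_seed, k),
                            holdout_frac, init_labeled_frac)
        for k in range(1, n_repeats + 1)
    ]


def run_benchmark(panel: Sequence[DrugScreen],
                  strategies: Sequence[StrategyConfig],
                  ens_cfg: EnsembleConfig,
                  n_repeats: int = DEFAULT_N_REPEATS,
                  master_seed: int = 0,
                  holdout_frac: float = DEFAULT_HOLDOUT_FRAC,
                  init_labeled_frac: float = DEFAULT_INIT_LABELED_FRAC,
                  collect_runs: bool = False,
                  ) -> pd.DataFrame | tuple[pd.DataFrame, list[RunResult]]:
    """Run every (drug, strategy, repeat) combination.

    Returns a long-format table with one row per run carrying ``auc_hit``
    and ``auc_per``.  All strategies share the same per-repeat split seeds,
    so rows are paired across strategies.  With ``collect_runs=True`` the
    full :class:`RunResult` list is returned as well.
    """
    if not panel:
        raise ConfigError("empty panel")
    labels = [s.label for s in strategies]
    if len(set(labels)) != len(labels):
        raise ConfigError("duplicate strategies in benchmark")
    rows, runs = [], []
    for screen in panel:
        for strategy in strategies:
            for k in range(1, n_repeats + 1):
                res = run_active_learning(
                    screen, strategy, ens_cfg,
                    repeat_split_seed(master_seed, k),
                    holdout_frac, init_labeled_frac)
                rows.append({
                    "drug_id": screen.drug_id,
                    "strategy": strategy.label,
                    "repeat": k,
                    "split_seed": res.split_seed,
                    "total_iterations": res.total_iterations,
                    "initial_candidate_hits": res.initial_candidate_hits,
                    "auc_hit": res.auc_hit,
                    "auc_per": res.auc_per,
                })
                if collect_runs:
                    runs.append(res)
            log.info("finished drug=%s strategy=%s (%d repeats)",
                     screen.drug_id, strategy.label, n_repeats)
    table = pd.DataFrame(rows)
    return (table, runs) if collect_runs else table


def write_run_records(runs: Sequence[RunResult], outdir: str | Path) -> None:
    """One JSON-lines file per (drug, strategy), one line per repeat."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grouped: dict[tuple[str, str], list[RunResult]] = {}
    for r in runs:
        grouped.setdefault((r.drug_id, r.strategy.label), []).append(r)
    for (drug, label), rs in grouped.items():
        safe = label.replace(":", "_")
        with open(outdir / f"{drug}__{safe}.jsonl", "w") as fh:
            for r in rs:
                fh.write(json.dumps({
                    "drug_id": r.drug_id,
                    "strategy": label,
                    "split_seed": r.split_seed,
                    "total_iterations": r.total_iterations,
                    "initial_candidate_hits": r.initial_candidate_hits,
                    "auc_hit": r.auc_hit,
                    "auc_per": r.auc_per,
                    "records": [rec.to_dict() for rec in r.records],
                }) + "\n")
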