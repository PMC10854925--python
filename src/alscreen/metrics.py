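"""Performance curves and their normalized areas.

Two curves summarize one active-learning run:

* the cumulative hit-detection rate r_i = (sum_{j<=i} h(Ds_j)) / h(Dc_1),
  where h(.) counts hits and Dc_1 is the initial candidate pool, and
* the holdout R^2 trajectory p_i.

Their normalized areas are plain means over the I iterations:
AUC_hit = (1/I) sum_i r_i and AUC_per = (1/I) sum_i p_i.  No trapezoid rule
and no re-weighting of the (possibly shorter) final batch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, NormalizationError, SchemaError

CurveKind = Literal["hit_rate", "r_squared"]


@dataclass
class MetricCurve:
    """A per-iteration metric trajectory."""

    values: np.ndarray
    kind: CurveKind

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise DegenerateInputError("curve must be a non-empty 1-D series")
        if self.kind == "hit_rate":
            if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
                raise SchemaError("hit-rate curve must lie in [0, 1]")
            if (np.diff(self.values) < -1e-12).any():
                raise SchemaError("hit-rate curve must be non-decreasing")


def cumulative_hit_rate(hits_per_iteration: Sequence[int],
                        total_hits_in_candidates: int) -> MetricCurve:
    """r_i = cumulative hits through iteration i over hits in Dc_1."""
    if total_hits_in_candidates < 1:
        raise DegenerateInputError(
            "no hits in the initial candidate set; hit rate undefined")
    hits = np.asarray(hits_per_iteration, dtype=float)
    return MetricCurve(values=np.cumsum(hits) / total_hits_in_candidates,
                       kind="hit_rate")


def auc_hit(curve: MetricCurve) -> float:
    """Mean of r_i over iterations; in [0, 1]."""
    if curve.kind != "hit_rate":
        raise SchemaError("auc_hit expects a hit_rate curve")
    return float(curve.values.mean())


def auc_per(curve: MetricCurve) -> float:
    """Mean of p_i over iterations; may be negative (R^2 can be)."""
    if curve.kind != "r_squared":
        raise SchemaError("auc_per expects an r_squared curve")
    return float(curve.values.mean())


def normalize_auc_per(benchmark: pd.DataFrame,
                      mode: str = "random_mean") -> pd.DataFrame:
    """Add an ``auc_per_norm`` column scaled by the Random baseline per drug.

    ``mode="random_mean"`` divides every (strategy, repeat) value by the mean
    of Random's auc_per over repeats for that drug (stable default);
    ``mode="paired"`` divides by Random's value from the matching repeat.

    Raises
    ------
    NormalizationError
        If a drug has no Random rows or a non-positive Random denominator.
    """
    required = {"drug_id", "strategy", "repeat", "auc_per"}
    missing = required - set(benchmark.columns)
    if missing:
        raise SchemaError(f"benchmark table missing column(s): {sorted(missing)}")
    if mode not in ("random_mean", "paired"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = benchmark.copy()
    random_rows = out[out["strategy"] == "random"]
    for drug in out["drug_id"].unique():
        if not (random_rows["drug_id"] == drug).any():
            raise NormalizationError(f"drug {drug}: no Random rows to "
                                     "normalize by")
    if mode == "random_mean":
        denom = random_rows.groupby("drug_id")["auc_per"].mean()
        bad = denom[denom <= 0]
        if len(bad):
            raise NormalizationError(
                f"drug {bad.index[0]}: Random mean auc_per is "
                f"{bad.iloc[0]:.4g} <= 0; normalization undefined")
        out["auc_per_norm"] = out["auc_per"] / out["drug_id"].map(denom).values
    else:
        denom = random_rows.set_index(["drug_id", "repeat"])["auc_per"]
        if (denom <= 0).any():
            drug = denom[denom <= 0].index[0][0]
            raise NormalizationError(
                f"drug {drug}: a Random repeat has auc_per <= 0; paired "
                "normalization undefined")
        key = pd.MultiIndex.from_frame(out[["drug_id", "repeat"]])
        out["auc_per_norm"] = out["auc_per"].values / denom.reindex(key).values
    return out


def curve_summary(curves: dict[tuple[str, str], list[MetricCurve]]
                  ) -> pd.DataFrame:
    """Mean +/- SD per iteration over repeats for each (drug, strategy).

    Input maps (drug_id, strategy) to the repeats' curves; repeats of one
    key must share a common length (the iteration count is split-determined,
    hence identical across repeats of one drug).
    """
    rows = []
    for (drug, strategy), cs in curves.items():
        arr = np.stack([c.values for c in cs])
        for i in range(arr.shape[1]):
            rows.append({
                "drug_id": drug, "strategy": strategy, "iteration": i + 1,
                "mean": arr[:, i].mean(), "sd": arr[:, i].std(ddof=0),
            })
    return pd.DataFrame(rows)
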