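"""Core dataset types, real-data readers, preprocessing, filtering, splitting.

A screening panel is a set of per-drug supervised datasets sharing one
cell-line x gene expression matrix.  For each drug the regression target is
the normalized area under the dose-response curve (``auc_res``, lower = more
responsive), and a *hit* is a cell line whose ``auc_res`` falls strictly
below the hit threshold (0.5 by default).

The active-learning protocol partitions each drug's cell lines into a fixed
holdout set (15% of the data, used only to score the model), an initial
labeled set (10%), and a candidate pool (the remaining ~75%) from which
batches are acquired.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import round_half_away
from .errors import DegenerateInputError, SchemaError, SplitError

DEFAULT_HIT_THRESHOLD = 0.5


@dataclass
class DrugScreen:
    """One drug's supervised dataset.

    Attributes
    ----------
    drug_id : str
        Identifier of the compound.
    features : (m, g) ndarray
        Standardized expression matrix, rows aligned with ``responses``.
    responses : (m,) ndarray
        ``auc_res`` values in [0, 1]; values outside the range are clipped
        with a warning (normalized dose-response fits can overshoot).
    cell_line_ids : list of str
        Row identifiers, aligned 1:1 with ``features`` / ``responses``.
    hit_threshold : float
        A response strictly below this value counts as a hit.
    """

    drug_id: str
    features: np.ndarray
    responses: np.ndarray
    cell_line_ids: list[str] = field(default_factory=list)
    hit_threshold: float = DEFAULT_HIT_THRESHOLD

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.features.ndim != 2:
            raise SchemaError(f"{self.drug_id}: features must be 2-D")
        m = self.features.shape[0]
        if self.responses.shape != (m,):
            raise SchemaError(
                f"{self.drug_id}: {m} feature rows but "
                f"{self.responses.shape[0]} responses"
            )
        if not self.cell_line_ids:
            self.cell_line_ids = [f"CL_{i:04d}" for i in range(m)]
        if len(self.cell_line_ids) != m:
            raise SchemaError(f"{self.drug_id}: cell_line_ids misaligned")
        if np.isnan(self.features).any() or np.isnan(self.responses).any():
            raise SchemaError(f"{self.drug_id}: missing values are not allowed")
        lo, hi = self.responses.min(), self.responses.max()
        if lo < 0.0 or hi > 1.0:
            warnings.warn(
                f"{self.drug_id}: responses outside [0, 1] "
                f"(min={lo:.3g}, max={hi:.3g}); clipping",
                stacklevel=2,
            )
            self.responses = np.clip(self.responses, 0.0, 1.0)

    @property
    def n_cell_lines(self) -> int:
        return self.features.shape[0]

    @property
    def n_genes(self) -> int:
        return self.features.shape[1]

    def is_hit(self, idx: np.ndarray | Sequence[int] | None = None) -> np.ndarray:
        """Boolean hit mask for the given row indices (all rows if None)."""
        resp = self.responses if idx is None else self.responses[np.asarray(idx)]
        return resp < self.hit_threshold

    @property
    def n_hits(self) -> int:
        return int(self.is_hit().sum())

    @property
    def hit_fraction(self) -> float:
        return self.n_hits / self.n_cell_lines


@dataclass
class SplitState:
    """Disjoint holdout / labeled / candidate index sets at one iteration."""

    holdout_idx: np.ndarray
    labeled_idx: np.ndarray
    candidate_idx: np.ndarray
    iteration: int = 1

    def __post_init__(self) -> None:
        self.holdout_idx = np.asarray(self.holdout_idx, dtype=int)
        self.labeled_idx = np.asarray(self.labeled_idx, dtype=int)
        self.candidate_idx = np.asarray(self.candidate_idx, dtype=int)
        self.validate()

    def validate(self, m: int | None = None) -> None:
        """Check the partition contract: pairwise disjoint, exhaustive."""
        sets = [self.holdout_idx, self.labeled_idx, self.candidate_idx]
        combined = np.concatenate(sets)
        if len(np.unique(combined)) != combined.size:
            raise SchemaError("split sets overlap or contain duplicates")
        if m is not None and (combined.size != m or combined.min() < 0
                              or combined.max() >= m):
            raise SchemaError("split sets do not partition 0..m-1")

    @property
    def total(self) -> int:
        return (self.holdout_idx.size + self.labeled_idx.size
                + self.candidate_idx.size)


@dataclass(frozen=True)
class FilterCriteria:
    """Drug-selection rules applied before any modeling.

    Defaults follow the screening-panel convention: at least 500 tested cell
    lines (enough samples for a response model), at least 20 hits (enough
    signal to chase), and a hit fraction no higher than 70% (excludes broadly
    toxic compounds).
    """

    min_cell_lines: int = 500
    min_hits: int = 20
    max_hit_fraction: float = 0.70

    def __post_init__(self) -> None:
        if self.min_hits < 1:
            raise ValueError("min_hits must be >= 1")
        if not 0 < self.max_hit_fraction <= 1:
            raise ValueError("max_hit_fraction must be in (0, 1]")

    def passes(self, screen: DrugScreen) -> bool:
        return (screen.n_cell_lines >= self.min_cell_lines
                and screen.n_hits >= self.min_hits
                and screen.hit_fraction <= self.max_hit_fraction)


def preprocess_expression(raw: pd.DataFrame) -> pd.DataFrame:
    """log2(x+1)-transform and z-score a nonnegative expression table.

    Each gene (column) ends up with zero mean and unit standard deviation
    across cell lines (rows).  Zero-variance columns cannot be standardized
    and are dropped with a warning.

    Parameters
    ----------
    raw : DataFrame
        Cell lines x genes, nonnegative values (TPM-like).

    Raises
    ------
    DegenerateInputError
        If fewer than two rows are given or every column is constant.
    """
    if raw.shape[0] < 2:
        raise DegenerateInputError("need at least 2 cell lines to standardize")
    if (raw.values < 0).any():
        raise SchemaError("expression values must be nonnegative")
    logged = np.log2(raw.astype(float) + 1.0)
    sd = logged.std(axis=0, ddof=0)
    dead = sd[sd == 0].index
    if len(dead) == len(logged.columns):
        raise DegenerateInputError("all gene columns have zero variance")
    if len(dead):
        warnings.warn(
            f"dropping {len(dead)} zero-variance gene column(s): "
            f"{list(dead[:5])}{'...' if len(dead) > 5 else ''}",
            stacklevel=2,
        )
        logged = logged.drop(columns=dead)
        sd = sd.drop(dead)
    return (logged - logged.mean(axis=0)) / sd


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """z-score each column of a plain array (population SD)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise DegenerateInputError("need at least 2 rows to standardize")
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise DegenerateInputError("zero-variance column cannot be standardized")
    return (X - X.mean(axis=0)) / sd


def filter_drugs(panel: Sequence[DrugScreen],
                 criteria: FilterCriteria | None = None) -> list[DrugScreen]:
    """Keep exactly the screens satisfying all three criteria, in order."""
    criteria = criteria or FilterCriteria()
    return [s for s in panel if criteria.passes(s)]


def filter_report(panel: Sequence[DrugScreen],
                  criteria: FilterCriteria | None = None) -> pd.DataFrame:
    """Per-drug manifest of sizes, hit counts, and pass/fail per criterion."""
    criteria = criteria or FilterCriteria()
    rows = []
    for s in panel:
        rows.append({
            "drug_id": s.drug_id,
            "n_cell_lines": s.n_cell_lines,
            "n_hits": s.n_hits,
            "hit_fraction": s.hit_fraction,
            "pass_min_cell_lines": s.n_cell_lines >= criteria.min_cell_lines,
            "pass_min_hits": s.n_hits >= criteria.min_hits,
            "pass_max_hit_fraction": s.hit_fraction <= criteria.max_hit_fraction,
            "selected": criteria.passes(s),
        })
    return pd.DataFrame(rows)


def make_initial_split(screen: DrugScreen,
                       holdout_frac: float = 0.15,
                       init_labeled_frac: float = 0.10,
                       seed: int = 0,
                       min_labeled: int = 2) -> SplitState:
    """Draw the holdout / initial-labeled / candidate partition for one run.

    All three fractions are taken relative to the full dataset size m:
    15% holdout, 10% initial labeled, and the remaining ~75% seeds the
    candidate pool.  Sizes use round-half-away-from-zero on the holdout and
    labeled counts; the candidate set takes the remainder, so the partition
    is exhaustive for any m.

    Raises
    ------
    SplitError
        If the labeled set would be smaller than ``min_labeled`` (the
        ensemble needs at least one training and one validation sample).
    """
    if holdout_frac <= 0 or init_labeled_frac <= 0:
        raise ValueError("fractions must be positive")
    if holdout_frac + init_labeled_frac >= 1:
        raise ValueError("holdout_frac + init_labeled_frac must be < 1")
    m = screen.n_cell_lines
    n_hold = round_half_away(holdout_frac * m)
    n_lab = round_half_away(init_labeled_frac * m)
    if n_lab < min_labeled:
        raise SplitError(
            f"{screen.drug_id}: initial labeled set of {n_lab} samples is "
            f"below the minimum trainable size {min_labeled}"
        )
    if n_hold + n_lab >= m:
        raise SplitError(f"{screen.drug_id}: no candidates left after split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    return SplitState(
        holdout_idx=np.sort(perm[:n_hold]),
        labeled_idx=np.sort(perm[n_hold:n_hold + n_lab]),
        candidate_idx=np.sort(perm[n_hold + n_lab:]),
        iteration=1,
    )


# ---------------------------------------------------------------------------
# readers / writers

def read_expression(path: str | Path, gene_list: Sequence[str] | None = None
                    ) -> pd.DataFrame:
    """Read an expression CSV/TSV (first column = cell-line IDs).

    If ``gene_list`` is given, columns are subset to it (missing genes are
    ignored with a warning) before any preprocessing.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if gene_list is not None:
        present = [g for g in gene_list if g in df.columns]
        missing = set(gene_list) - set(present)
        if missing:
            warnings.warn(f"{len(missing)} gene(s) from the list are absent "
                          "from the expression table", stacklevel=2)
        if not present:
            raise SchemaError("none of the listed genes are present")
        df = df[present]
    return df


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one symbol per line."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def read_responses(path: str | Path) -> pd.DataFrame:
    """Read a long-format response table with drug_id, cell_line_id, auc_res."""
    df = pd.read_csv(path)
    required = {"drug_id", "cell_line_id", "auc_res"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"response table missing column(s): {sorted(missing)}")
    return df


def build_screens(expression: pd.DataFrame, responses: pd.DataFrame,
                  hit_threshold: float = DEFAULT_HIT_THRESHOLD
                  ) -> list[DrugScreen]:
    """Assemble one DrugScreen per drug from aligned expression + responses.

    Per drug, only cell lines present in both tables are kept; rows with
    missing responses are dropped.
    """
    screens = []
    for drug_id, grp in responses.groupby("drug_id", sort=False):
        grp = grp.dropna(subset=["auc_res"])
        cells = [c for c in grp["cell_line_id"] if c in expression.index]
        if not cells:
            continue
        resp = grp.set_index("cell_line_id").loc[cells, "auc_res"].to_numpy()
        screens.append(DrugScreen(
            drug_id=str(drug_id),
            features=expression.loc[cells].to_numpy(dtype=float),
            responses=resp,
            cell_line_ids=list(cells),
            hit_threshold=hit_threshold,
        ))
    return screens


def write_filter_manifest(panel: Sequence[DrugScreen], path: str | Path,
                          criteria: FilterCriteria | None = None) -> None:
    report = filter_report(panel, criteria)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(report.to_dict(orient="records"), indent=2))
    else:
        report.to_csv(path, index=False)
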