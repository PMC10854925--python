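"""Synthetic screening-panel generator.

Emulates the statistical shape of a cell-line drug screen: a standardized
expression matrix (each gene zero mean, unit SD across cell lines) and, per
drug, a continuous response on the normalized dose-response AUC scale
([0, 1], lower = more sensitive).  Responses carry a learnable sparse linear
signal squashed through a logistic link plus additive Gaussian noise; the
link's offset is calibrated by bisection so that the achieved hit fraction
(fraction of responses below 0.5) lands near a requested target.

The generator is deliberately simple: features are independent Gaussians, so
it reproduces the marginal structure of a standardized expression panel but
not the lineage correlation of real transcriptomes (see the methods note for
what that implies about downstream comparisons).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import derive_seed
from .data import DEFAULT_HIT_THRESHOLD, DrugScreen
from .errors import CalibrationError, DegenerateInputError

#: slope of the logistic link; spreads responses over most of [0, 1]
_LINK_SLOPE = 2.0
#: calibration tolerance on the achieved hit fraction
HIT_FRACTION_TOL = 0.05


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of a synthetic screening panel.

    Attributes
    ----------
    n_drugs : int
        Number of drugs; each gets an independent response vector.
    n_cell_lines : int
        Panel size m (rows of the shared expression matrix).
    n_genes : int
        Feature count g (a landmark-gene-panel scale, ~10^2-10^3).
    signal_genes_per_drug : int
        Size of the random gene subset carrying each drug's signal.
    noise_sd : float
        SD of Gaussian noise added to the squashed signal.
    target_hit_fraction : float
        Desired fraction of responses below the hit threshold, in (0, 1).
    seed : int
        Master seed; per-drug seeds are derived from it.
    """

    n_drugs: int = 8
    n_cell_lines: int = 500
    n_genes: int = 943
    signal_genes_per_drug: int = 10
    noise_sd: float = 0.1
    target_hit_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_lines < 2:
            raise ValueError("n_cell_lines must be >= 2")
        if self.n_genes < 1 or self.n_drugs < 1:
            raise ValueError("n_genes and n_drugs must be >= 1")
        if self.signal_genes_per_drug > self.n_genes:
            raise ValueError("signal_genes_per_drug cannot exceed n_genes")
        if self.signal_genes_per_drug < 0 or self.noise_sd < 0:
            raise ValueError("signal_genes_per_drug and noise_sd must be >= 0")
        if not 0 < self.target_hit_fraction < 1:
            raise ValueError("target_hit_fraction must be in (0, 1)")


@dataclass
class DrugSignal:
    """Planted-signal record kept for diagnostics."""

    signal_genes: np.ndarray
    weights: np.ndarray
    offset: float
    achieved_hit_fraction: float

    def to_dict(self) -> dict:
        return {
            "signal_genes": [int(i) for i in self.signal_genes],
            "weights": [float(w) for w in self.weights],
            "offset": float(self.offset),
            "achieved_hit_fraction": float(self.achieved_hit_fraction),
        }


@dataclass
class Panel:
    """A generated panel: shared expression plus per-drug screens."""

    spec: PanelSpec
    expression: pd.DataFrame
    screens: list[DrugScreen]
    signals: list[DrugSignal] = field(default_factory=list)


def generate_expression(m: int, g: int, seed: int) -> np.ndarray:
    """Generate an m x g standardized expression matrix.

    Entries are drawn i.i.d. standard normal and then z-scored per column
    (population SD), so every gene has exactly zero mean and unit SD across
    cell lines.  Deterministic given the seed.
    """
    if m < 2:
        raise DegenerateInputError("cannot standardize fewer than 2 cell lines")
    if g < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((m, g))
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)


def _responses_at(offset: float, z: np.ndarray, eps: np.ndarray) -> np.ndarray:
    # larger offset shifts the logistic down -> responses shrink -> more hits
    return np.clip(1.0 / (1.0 + np.exp(-_LINK_SLOPE * (z - offset))) + eps,
                   0.0, 1.0)


def generate_drug_response(X: np.ndarray, spec: PanelSpec, drug_seed: int
                           ) -> tuple[np.ndarray, DrugSignal]:
    """Generate one drug's response vector over a standardized panel.

    response = clip01( logistic(slope * (w . x_S - b)) + eps ), with S a
    seeded random gene subset, w seeded Gaussian weights (scaled to unit
    signal variance), eps ~ N(0, noise_sd), and b located by bisection so
    that the fraction of responses below the hit threshold is within
    +/- ``HIT_FRACTION_TOL`` of ``spec.target_hit_fraction``.  Because each
    response is non-increasing in b, the hit count is monotone non-decreasing
    in b and bisection is exact up to the discreteness of the sample.

    Returns the response vector and the planted-signal record.
    """
    rng = np.random.default_rng(drug_seed)
    m, g = X.shape
    k = spec.signal_genes_per_drug
    if k > 0:
        genes = np.sort(rng.choice(g, size=k, replace=False))
        weights = rng.standard_normal(k) / np.sqrt(k)
        z = X[:, genes] @ weights
    else:
        genes = np.empty(0, dtype=int)
        weights = np.empty(0)
        z = np.zeros(m)
    eps = rng.normal(0.0, spec.noise_sd, size=m) if spec.noise_sd > 0 else \
        np.zeros(m)

    target = spec.target_hit_fraction

    def hit_frac(offset: float) -> float:
        return float(np.mean(_responses_at(offset, z, eps)
                             < DEFAULT_HIT_THRESHOLD))

    lo, hi = -20.0, 20.0  # logistic saturates well inside this bracket
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if hit_frac(mid) < target:
            lo = mid
        else:
            hi = mid
    # pick whichever bracket end lands closer to the target
    candidates = sorted(((abs(hit_frac(b) - target), b) for b in (lo, hi)))
    err, offset = candidates[0]
    achieved = hit_frac(offset)
    if err > HIT_FRACTION_TOL:
        raise CalibrationError(
            f"hit-fraction calibration reached {achieved:.3f}, target "
            f"{target:.3f} +/- {HIT_FRACTION_TOL}", achieved=achieved,
        )
    responses = _responses_at(offset, z, eps)
    return responses, DrugSignal(genes, weights, offset, achieved)


def generate_panel(spec: PanelSpec) -> Panel:
    """Generate a full panel: one expression matrix, ``n_drugs`` screens.

    Per-drug seeds are derived from ``spec.seed`` and the drug index, so
    drugs are mutually independent but the panel is reproducible.
    """
    X = generate_expression(spec.n_cell_lines, spec.n_genes, spec.seed)
    cell_ids = [f"CL_{i:04d}" for i in range(spec.n_cell_lines)]
    gene_ids = [f"g_{j:04d}" for j in range(spec.n_genes)]
    expression = pd.DataFrame(X, index=cell_ids, columns=gene_ids)
    screens, signals = [], []
    for d in range(spec.n_drugs):
        drug_seed = derive_seed(spec.seed, 1, d)
        try:
            resp, sig = generate_drug_response(X, spec, drug_seed)
        except CalibrationError as exc:
            raise CalibrationError(
                f"drug {d}: {exc}", achieved=exc.achieved) from exc
        screens.append(DrugScreen(
            drug_id=f"drug_{d:03d}", features=X, responses=resp,
            cell_line_ids=list(cell_ids),
        ))
        signals.append(sig)
    return Panel(spec=spec, expression=expression, screens=screens,
                 signals=signals)


def write_panel(panel: Panel, outdir: str | Path) -> None:
    """Write expression.csv, responses.csv and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel.expression.to_csv(outdir / "expression.csv",
                            index_label="cell_line_id")
    rows = []
    for screen in panel.screens:
        for cid, r in zip(screen.cell_line_ids, screen.responses):
            rows.append((screen.drug_id, cid, r))
    pd.DataFrame(rows, columns=["drug_id", "cell_line_id", "auc_res"]).to_csv(
        outdir / "responses.csv", index=False, float_format="%.10g")
    manifest = {
        "spec": {k: getattr(panel.spec, k) for k in (
            "n_drugs", "n_cell_lines", "n_genes", "signal_genes_per_drug",
            "noise_sd", "target_hit_fraction", "seed")},
        "drugs": {s.drug_id: sig.to_dict()
                  for s, sig in zip(panel.screens, panel.signals)},
    }
    (outdir / "panel_meta.json").write_text(json.dumps(manifest, indent=2))


def read_panel(indir: str | Path,
               hit_threshold: float = DEFAULT_HIT_THRESHOLD) -> Panel:
    """Read a panel previously written by :func:`write_panel`."""
    from .data import build_screens, read_responses

    indir = Path(indir)
    expression = pd.read_csv(indir / "expression.csv", index_col=0)
    responses = read_responses(indir / "responses.csv")
    meta = json.loads((indir / "panel_meta.json").read_text())
    spec = PanelSpec(**meta["spec"])
    screens = build_screens(expression, responses, hit_threshold)
    signals = [
        DrugSignal(
            signal_genes=np.asarray(meta["drugs"][s.drug_id]["signal_genes"]),
            weights=np.asarray(meta["drugs"][s.drug_id]["weights"]),
            offset=meta["drugs"][s.drug_id]["offset"],
            achieved_hit_fraction=(
                meta["drugs"][s.drug_id]["achieved_hit_fraction"]),
        )
        for s in screens
    ]
    return Panel(spec=spec, expression=expression, screens=screens,
                 signals=signals)
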