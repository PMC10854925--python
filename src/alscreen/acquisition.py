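"""Acquisition functions and batch selectors.

Thirteen analyses are benchmarked: random, greedy (-mu), uncertainty
(sigma), GU combined (-mu + sigma), diversity (k-means medoids), four
sampling-level hybrids (a fixed fraction ps of each batch drawn at random,
the rest by GU), and four iteration-level hybrids (the first ceil(pi * I)
iterations fully random, the rest GU).

All score-based selectors depend only on the ranking of scores; ties are
broken by ascending candidate index so every selection is deterministic and
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from ._utils import round_half_away
from .errors import ConfigError, DegenerateInputError
from .ensemble import EnsemblePrediction

BASE_STRATEGIES = ("random", "greedy", "uncertainty", "gu_combined",
                   "diversity")
HYBRID_STRATEGIES = ("hybrid_sampling", "hybrid_iteration")
#: the thirteen benchmark analyses
ALL_STRATEGY_NAMES = list(BASE_STRATEGIES) + [
    f"{fam}:{p}" for fam in HYBRID_STRATEGIES
    for p in ("0.2", "0.3", "0.4", "0.5")
]

#: reference upper-bound selector (true lowest response first); a test/QA
#: harness, never part of the thirteen benchmark analyses
ORACLE_STRATEGY = "oracle"

DEFAULT_BATCH_N = 20


@dataclass(frozen=True)
class StrategyConfig:
    """One sample-selection strategy.

    ``ps`` (random fraction per batch) applies only to ``hybrid_sampling``;
    ``pi`` (random fraction of iterations) only to ``hybrid_iteration``.
    """

    name: str
    ps: float | None = None
    pi: float | None = None
    batch_n: int = DEFAULT_BATCH_N

    def __post_init__(self) -> None:
        if self.name not in BASE_STRATEGIES + HYBRID_STRATEGIES + (
                ORACLE_STRATEGY,):
            raise ConfigError(f"unknown strategy {self.name!r}")
        if self.batch_n < 1:
            raise ConfigError("batch_n must be >= 1")
        for attr, fam in (("ps", "hybrid_sampling"), ("pi", "hybrid_iteration")):
            val = getattr(self, attr)
            if self.name == fam:
                if val is None or not 0 <= val <= 1:
                    raise ConfigError(f"{fam} requires {attr} in [0, 1]")
            elif val is not None:
                raise ConfigError(f"{attr} is only valid for {fam}")

    @property
    def label(self) -> str:
        """Display name, e.g. ``hybrid_sampling:0.2``."""
        if self.name == "hybrid_sampling":
            return f"hybrid_sampling:{self.ps:g}"
        if self.name == "hybrid_iteration":
            return f"hybrid_iteration:{self.pi:g}"
        return self.name


def parse_strategy(spec: str, batch_n: int = DEFAULT_BATCH_N) -> StrategyConfig:
    """Parse a strategy label like ``greedy`` or ``hybrid_sampling:0.3``."""
    name, _, param = spec.partition(":")
    name = name.strip()
    if name in BASE_STRATEGIES:
        if param:
            raise ConfigError(f"strategy {name!r} takes no parameter")
        return StrategyConfig(name=name, batch_n=batch_n)
    if name in HYBRID_STRATEGIES:
        if not param:
            raise ConfigError(f"strategy {name!r} requires a parameter, "
                              f"e.g. {name}:0.2")
        value = float(param)
        key = "ps" if name == "hybrid_sampling" else "pi"
        return StrategyConfig(name=name, batch_n=batch_n, **{key: value})
    raise ConfigError(f"unknown strategy {spec!r}")


def default_strategies(batch_n: int = DEFAULT_BATCH_N) -> list[StrategyConfig]:
    """The thirteen benchmark strategies."""
    return [parse_strategy(s, batch_n) for s in ALL_STRATEGY_NAMES]


@dataclass
class SelectionBatch:
    """A selected batch: candidate-set indices plus per-pick provenance."""

    selected_idx: np.ndarray
    scores: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.selected_idx = np.asarray(self.selected_idx, dtype=int)
        if len(np.unique(self.selected_idx)) != self.selected_idx.size:
            raise ConfigError("selected batch contains duplicate indices")
        if not self.provenance:
            self.provenance = ["model"] * self.selected_idx.size


# ---------------------------------------------------------------------------
# acquisition scores

def score_greedy(pred: EnsemblePrediction) -> np.ndarray:
    """F(x) = -mu(x): low predicted AUC (responsive) scores high."""
    return -pred.mu


def score_uncertainty(pred: EnsemblePrediction) -> np.ndarray:
    """F(x) = sigma(x): prediction spread over the ensemble."""
    return pred.sigma.copy()


def score_gu(pred: EnsemblePrediction) -> np.ndarray:
    """F(x) = -mu(x) + sigma(x): greedy plus uncertainty."""
    return -pred.mu + pred.sigma


# ---------------------------------------------------------------------------
# selectors

def select_top_n(scores: np.ndarray, candidate_idx: np.ndarray, n: int
                 ) -> SelectionBatch:
    """Pick the min(n, #candidates) highest-scoring candidates.

    Ties are broken by ascending candidate index (stable and deterministic).
    """
    candidate_idx = np.asarray(candidate_idx, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if candidate_idx.size == 0:
        raise DegenerateInputError("cannot select from an empty candidate set")
    if scores.shape != candidate_idx.shape:
        raise ConfigError("scores misaligned with candidate set")
    if n < 1:
        raise ConfigError("batch size must be >= 1")
    # primary key: score descending; secondary: candidate index ascending
    order = np.lexsort((candidate_idx, -scores))
    take = order[:min(n, candidate_idx.size)]
    return SelectionBatch(selected_idx=candidate_idx[take],
                          scores=scores[take],
                          provenance=["model"] * take.size)


def select_random(candidate_idx: np.ndarray, n: int, seed: int
                  ) -> SelectionBatch:
    """Uniform sample without replacement of size min(n, #candidates)."""
    candidate_idx = np.asarray(candidate_idx, dtype=int)
    if candidate_idx.size == 0:
        raise DegenerateInputError("cannot select from an empty candidate set")
    rng = np.random.default_rng(seed)
    take = rng.choice(candidate_idx.size, size=min(n, candidate_idx.size),
                      replace=False)
    return SelectionBatch(selected_idx=candidate_idx[take],
                          provenance=["random"] * take.size)


def select_diversity(candidate_features: np.ndarray,
                     candidate_idx: np.ndarray, n: int, seed: int
                     ) -> SelectionBatch:
    """k-means on the candidates; per cluster, the sample nearest its centroid.

    Uses k = min(n, #candidates) clusters, 10 seeded restarts, a 300
    iteration cap, and the squared-Euclidean objective.
    """
    candidate_idx = np.asarray(candidate_idx, dtype=int)
    X = np.asarray(candidate_features, dtype=float)
    if candidate_idx.size == 0:
        raise DegenerateInputError("cannot select from an empty candidate set")
    k = min(n, candidate_idx.size)
    if k == candidate_idx.size:
        return SelectionBatch(selected_idx=candidate_idx.copy(),
                              provenance=["diversity"] * k)
    km = KMeans(n_clusters=k, n_init=10, max_iter=300, random_state=seed)
    labels = km.fit_predict(X)
    picks = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        d2 = np.sum((X[members] - km.cluster_centers_[c]) ** 2, axis=1)
        picks.append(members[np.argmin(d2)])
    return SelectionBatch(selected_idx=candidate_idx[np.array(picks)],
                          provenance=["diversity"] * k)


def select_hybrid_sampling(pred: EnsemblePrediction,
                           candidate_idx: np.ndarray,
                           cfg: StrategyConfig, seed: int) -> SelectionBatch:
    """ps of the batch at random, the rest by GU score.

    ``round_half_away(ps * batch_n)`` slots are drawn uniformly first; the
    remaining slots are filled with the top GU scores among the candidates
    not already taken.
    """
    candidate_idx = np.asarray(candidate_idx, dtype=int)
    if candidate_idx.size == 0:
        raise DegenerateInputError("cannot select from an empty candidate set")
    n_batch = min(cfg.batch_n, candidate_idx.size)
    n_rand = min(round_half_away(cfg.ps * cfg.batch_n), n_batch)
    parts_idx: list[np.ndarray] = []
    prov: list[str] = []
    if n_rand > 0:
        rand = select_random(candidate_idx, n_rand, seed)
        parts_idx.append(rand.selected_idx)
        prov += ["random"] * rand.selected_idx.size
    n_model = n_batch - n_rand
    if n_model > 0:
        taken = set(parts_idx[0].tolist()) if parts_idx else set()
        mask = np.array([i not in taken for i in candidate_idx])
        scores = score_gu(pred)
        top = select_top_n(scores[mask], candidate_idx[mask], n_model)
        parts_idx.append(top.selected_idx)
        prov += ["model"] * top.selected_idx.size
    return SelectionBatch(selected_idx=np.concatenate(parts_idx),
                          provenance=prov)


def random_phase_iterations(pi: float, total_iterations: int) -> int:
    """Number of leading iterations the iteration-hybrid spends on random.

    ``ceil(pi * I)``: any pi > 0 yields at least one random iteration.
    """
    import math

    return math.ceil(pi * total_iterations)


def select_hybrid_iteration(pred: EnsemblePrediction | None,
                            candidate_idx: np.ndarray,
                            cfg: StrategyConfig, iteration: int,
                            total_iterations: int, seed: int
                            ) -> SelectionBatch:
    """Random selection while i <= ceil(pi * I); GU top-n afterwards."""
    if not 1 <= iteration <= total_iterations:
        raise ConfigError("iteration index out of range")
    if iteration <= random_phase_iterations(cfg.pi, total_iterations):
        return select_random(candidate_idx, cfg.batch_n, seed)
    if pred is None:
        raise ConfigError("GU phase of hybrid_iteration needs predictions")
    return select_top_n(score_gu(pred), candidate_idx, cfg.batch_n)


def uses_predictions(cfg: StrategyConfig, iteration: int,
                     total_iterations: int) -> bool:
    """Whether this strategy reads candidate predictions at this iteration."""
    if cfg.name in ("greedy", "uncertainty", "gu_combined", "hybrid_sampling"):
        return True
    if cfg.name == "hybrid_iteration":
        return iteration > random_phase_iterations(cfg.pi, total_iterations)
    return False  # random, diversity
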