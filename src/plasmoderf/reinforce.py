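"""Semi-synthetic "strong predictability" outcome construction.

The weakly predictable outcome of the population is reinforced in five steps:
(1) split the population into k (default 4) approximately equal disjoint
folds; (2) train a probability forest on the other folds; (3) predict
out-of-fold event probabilities and transform them to log odds; (4) multiply
the log odds by a constant c (default 3.5) and back-transform; (5) draw a new
Bernoulli outcome per row from the reinforced probability. The result,
``y_strong``, is a property of the population: it is created once and frozen,
and every scenario subsample reuses it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .metrics import auroc, calibration_slope
from .population import Population
from .strategies import ForestParams, train_probability_forest

__all__ = [
    "ReinforcementConfig",
    "ReinforcementReport",
    "outoffold_probabilities",
    "reinforce_probabilities",
    "sample_strong_outcome",
    "apply_reinforcement",
]

#: forest probabilities of exactly 0/1 are clipped here before the logit
PROB_EPS = 1e-6


@dataclass
class ReinforcementConfig:
    """Parameters of the outcome-reinforcement procedure."""

    n_folds: int = 4
    constant: float = 3.5
    seed: int = 0
    forest: ForestParams = field(default_factory=ForestParams)

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.constant <= 0:
            raise ValueError("reinforcement constant must be positive")


def _fold_assignment(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    if n < n_folds:
        raise ValueError(f"cannot split {n} rows into {n_folds} nonempty folds")
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=np.int64)
    for k, idx in enumerate(np.array_split(perm, n_folds)):
        folds[idx] = k
    return folds


def outoffold_probabilities(pop: Population, cfg: ReinforcementConfig) -> np.ndarray:
    """Cross-fitted event probabilities for the weak outcome.

    Each row's probability comes from a probability forest trained on the
    other folds with all predictors; folds are disjoint, exhaustive, and
    their sizes differ by at most one. Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    folds = _fold_assignment(pop.n_pop, cfg.n_folds, rng)
    X = pop.X
    y = pop.y_weak
    out = np.empty(pop.n_pop, dtype=np.float64)
    for k in range(cfg.n_folds):
        test = folds == k
        if y[test].min() == y[test].max():
            warnings.warn(f"fold {k} contains a single outcome class", stacklevel=2)
        params = ForestParams(
            n_trees=cfg.forest.n_trees,
            mtry=cfg.forest.mtry,
            min_node_size=cfg.forest.min_node_size,
            seed=int((cfg.seed * 1_000_003 + k) % 2**31),
        )
        forest = train_probability_forest(X.loc[~test], y[~test], params)
        out[test] = forest.predict_event_probability(X.loc[test])
    return out


def reinforce_probabilities(p: np.ndarray, c: float) -> np.ndarray:
    """expit(c * logit(p)): scale predicted log odds by a constant.

    Order-preserving for c > 0 with a fixed point at 0.5; probabilities of
    exactly 0 or 1 are clipped to [eps, 1-eps] first so the logit is finite.
    """
    p = np.asarray(p, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if c <= 0:
        raise ValueError("reinforcement constant must be positive")
    return expit(c * logit(np.clip(p, PROB_EPS, 1.0 - PROB_EPS)))


def sample_strong_outcome(p_reinforced: np.ndarray, seed: int) -> np.ndarray:
    """Independent Bernoulli draws from the reinforced probabilities."""
    p = np.asarray(p_reinforced, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return (rng.uniform(size=p.shape) < p).astype(np.int8)


@dataclass
class ReinforcementReport:
    """Diagnostics of one reinforcement run."""

    oof_auroc: float
    oof_cal_slope: float
    event_rate_weak: float
    event_rate_strong: float
    oof_probabilities: np.ndarray


def apply_reinforcement(
    pop: Population, cfg: ReinforcementConfig
) -> tuple[Population, ReinforcementReport]:
    """Attach a reinforced strong outcome to the population.

    Returns the population with ``y_strong`` set, plus a report with the
    cross-fitted AUROC and calibration slope of the forest against the weak
    outcome and the realized event rates.
    """
    oof = outoffold_probabilities(pop, cfg)
    reinforced = reinforce_probabilities(oof, cfg.constant)
    y_strong = sample_strong_outcome(reinforced, seed=int((cfg.seed + 1) % 2**31))
    report = ReinforcementReport(
        oof_auroc=auroc(oof, pop.y_weak),
        oof_cal_slope=calibration_slope(oof, pop.y_weak),
        event_rate_weak=float(np.mean(pop.y_weak)),
        event_rate_strong=float(np.mean(y_strong)),
        oof_probabilities=oof,
    )
    return pop.with_strong_outcome(y_strong), report
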