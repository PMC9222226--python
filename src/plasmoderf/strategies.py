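"""Candidate-variable strategies M1-M5 and the current-study learners.

The current study trains a probability random forest on one of five
candidate-variable sets derived from the two preceding studies:

* M1 — all non-degenerate variables (naive forest, no background knowledge);
* M2 — the Lasso selection;
* M3 — the intersection of Lasso and univariate selection;
* M4 — their union;
* M5 — the selection of whichever preceding model discriminates better when
  applied unchanged to the current sample.

Empty selections are treated as absent background knowledge and resolved by
fallback rules: M2/M4 fall back to all variables, M3 falls back to M4's
resolved set, M5 falls back to the other model and, if both are empty, to
all variables. Variables degenerate in the current sample are removed from
every final set before forest training.

A Lasso model fitted directly on the current sample serves as the parametric
comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from .metrics import auroc
from .preceding import (
    LassoStudy,
    SelectionResult,
    StudySample,
    drop_degenerate,
    predict_logistic,
)

__all__ = [
    "ForestParams",
    "StrategySet",
    "ProbabilityForest",
    "train_probability_forest",
    "build_strategy_set",
    "m5_pick_winner",
    "fit_lasso_comparator",
    "METHODS",
]

#: method labels evaluated in every replication
METHODS = ("LASSO", "M1", "M2", "M3", "M4", "M5")


@dataclass
class ForestParams:
    """Probability-forest hyperparameters.

    ``mtry`` follows the usual convention: "sqrt" resolves to floor(sqrt(p)),
    a float in (0,1] to a fraction of p, an int to a fixed count.
    ``min_node_size`` is the minimal node size eligible for splitting
    (an int count, default 10, or a float fraction of n for the 10%-of-n
    probability-machine variant).
    """

    n_trees: int = 500
    mtry: str | float | int = "sqrt"
    min_node_size: int | float = 10
    seed: int = 0

    def resolve_mtry(self, p: int) -> int:
        if self.mtry == "sqrt":
            m = int(np.floor(np.sqrt(p)))
        elif isinstance(self.mtry, float):
            if not (0.0 < self.mtry <= 1.0):
                raise ValueError("fractional mtry must lie in (0, 1]")
            m = int(np.ceil(self.mtry * p))
        elif isinstance(self.mtry, int):
            m = self.mtry
        else:
            raise ValueError(f"unknown mtry rule {self.mtry!r}")
        return int(min(max(m, 1), p))


class ProbabilityForest(BaseEstimator, ClassifierMixin):
    """Probability random forest for a binary outcome.

    Trees are grown without pruning on bootstrap resamples of size n with the
    Gini impurity split criterion, considering a random ``mtry``-sized
    variable subset at each node; the predicted event probability is the
    ensemble average of per-tree terminal-node class fractions, which is a
    consistent probability estimator for binary outcomes.

    Attributes
    ----------
    model_ : fitted sklearn RandomForestClassifier
    classes_ : ndarray (0, 1)
    """

    def __init__(self, params: ForestParams | None = None):
        self.params = params

    def fit(self, X, y) -> "ProbabilityForest":
        params = self.params or ForestParams()
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=np.int64)
        if X.shape[1] < 1:
            raise ValueError("need at least one predictor")
        if len(np.unique(y)) < 2:
            raise ValueError("outcome has a single class; forest not trainable")
        mtry = params.resolve_mtry(X.shape[1])
        self.model_ = RandomForestClassifier(
            n_estimators=params.n_trees,
            criterion="gini",
            max_features=mtry,
            min_samples_split=(
                params.min_node_size
                if isinstance(params.min_node_size, int)
                else float(params.min_node_size)
            ),
            bootstrap=True,
            random_state=params.seed,
            n_jobs=1,
        ).fit(X.to_numpy(dtype=np.float64), y)
        self.classes_ = self.model_.classes_
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        return self.model_.predict_proba(X.to_numpy(dtype=np.float64))

    def predict_event_probability(self, X) -> np.ndarray:
        """P(Y=1) per row."""
        proba = self.predict_proba(X)
        idx = int(np.flatnonzero(self.classes_ == 1)[0])
        return proba[:, idx]

    def predict(self, X) -> np.ndarray:
        return (self.predict_event_probability(X) >= 0.5).astype(np.int64)


def train_probability_forest(X, y, params: ForestParams) -> ProbabilityForest:
    """Fit a probability forest; deterministic given ``params.seed``."""
    return ProbabilityForest(params=params).fit(X, y)


@dataclass
class StrategySet:
    """Resolved candidate-variable set for one method in one replication."""

    method: str
    variables: tuple[str, ...]
    fallback_applied: str = "none"
    m5_winner: str = "n/a"

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValueError("strategy set must be nonempty after fallback resolution")


def m5_pick_winner(
    sel_lasso: SelectionResult, sel_uni: SelectionResult, current: StudySample
) -> str:
    """Which preceding model discriminates better on the current sample.

    Both published models are applied unchanged (frozen coefficients; columns
    degenerate in the current sample contribute their constant value) and
    compared by AUROC. Ties go to the Lasso model, the methodologically
    stronger preceding study.
    """
    if sel_lasso.empty or sel_uni.empty:
        raise ValueError("m5_pick_winner needs both selections nonempty")
    auc_lasso = auroc(predict_logistic(sel_lasso, current.X), current.y)
    auc_uni = auroc(predict_logistic(sel_uni, current.X), current.y)
    return "lasso" if auc_lasso >= auc_uni else "univariate"


def build_strategy_set(
    method: str,
    sel_lasso: SelectionResult,
    sel_uni: SelectionResult,
    current: StudySample,
) -> StrategySet:
    """Resolve the candidate-variable set for ``method`` with fallback rules.

    ``current`` is the current-study sample with all drawn columns; variable
    sets are restricted to its non-degenerate columns (in column order) and
    the fallback ladder re-fires if the restriction empties a set.
    """
    nondeg = current.nondegenerate_names
    nondeg_set = set(nondeg)

    def restrict(names) -> tuple[str, ...]:
        wanted = set(names)
        return tuple(v for v in nondeg if v in wanted)

    all_vars = tuple(nondeg)
    lasso_set = set(sel_lasso.selected)
    uni_set = set(sel_uni.selected)

    if method == "M1":
        return StrategySet("M1", all_vars)

    if method == "M2":
        if sel_lasso.empty:
            return StrategySet("M2", all_vars, fallback_applied="all-variables")
        kept = restrict(lasso_set)
        if not kept:
            return StrategySet("M2", all_vars, fallback_applied="all-variables")
        return StrategySet("M2", kept)

    if method == "M4":
        union = lasso_set | uni_set
        kept = restrict(union)
        if not union or not kept:
            return StrategySet("M4", all_vars, fallback_applied="all-variables")
        return StrategySet("M4", kept)

    if method == "M3":
        inter = lasso_set & uni_set
        kept = restrict(inter)
        if inter and kept:
            return StrategySet("M3", kept)
        m4 = build_strategy_set("M4", sel_lasso, sel_uni, current)
        return StrategySet("M3", m4.variables, fallback_applied="union-substitute")

    if method == "M5":
        if sel_lasso.empty and sel_uni.empty:
            return StrategySet("M5", all_vars, fallback_applied="both-empty-all")
        if sel_lasso.empty or sel_uni.empty:
            other = sel_uni if sel_lasso.empty else sel_lasso
            kept = restrict(other.selected)
            winner = other.method
            if not kept:
                return StrategySet(
                    "M5", all_vars, fallback_applied="all-variables", m5_winner=winner
                )
            return StrategySet("M5", kept, fallback_applied="other-model", m5_winner=winner)
        winner = m5_pick_winner(sel_lasso, sel_uni, current)
        primary, secondary = (
            (sel_lasso, sel_uni) if winner == "lasso" else (sel_uni, sel_lasso)
        )
        kept = restrict(primary.selected)
        if kept:
            return StrategySet("M5", kept, m5_winner=winner)
        kept = restrict(secondary.selected)
        if kept:
            return StrategySet(
                "M5", kept, fallback_applied="other-model", m5_winner=secondary.method
            )
        return StrategySet("M5", all_vars, fallback_applied="all-variables", m5_winner=winner)

    raise ValueError(f"unknown method label {method!r}")


def write_strategy_audit(sets, path, replication: int | None = None) -> None:
    """Append-style audit table for resolved strategy sets.

    One row per set: replication, method, fallback flag, M5 winner and the
    space-joined variable list, in delimited text (comma or tab by suffix).
    """
    from pathlib import Path

    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    if isinstance(sets, StrategySet):
        sets = [sets]
    frame = pd.DataFrame(
        [
            {
                "replication": replication if replication is not None else -1,
                "method": s.method,
                "fallback_applied": s.fallback_applied,
                "m5_winner": s.m5_winner,
                "n_variables": len(s.variables),
                "variables": " ".join(s.variables),
            }
            for s in sets
        ]
    )
    frame.to_csv(path, sep=sep, index=False, mode="a", header=not path.exists())


def fit_lasso_comparator(
    current: StudySample,
    seed: int | None = None,
    n_cv_folds: int = 10,
    n_lambdas: int = 15,
    lambda_min_ratio: float | None = None,
) -> SelectionResult:
    """Lasso logistic model fitted on the current sample (comparator column).

    Shares the implementation of the preceding-study Lasso; fitted on the
    non-degenerate columns of the current sample.
    """
    filtered = drop_degenerate(current)
    est = LassoStudy(
        n_folds=n_cv_folds,
        n_lambdas=n_lambdas,
        lambda_min_ratio=lambda_min_ratio,
        random_state=seed,
    ).fit(filtered.X, filtered.y)
    return est.result_
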