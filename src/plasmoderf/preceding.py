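"""Preceding-study models: Lasso logistic selection and univariate screening.

A "preceding study" fits a predictive logistic model on its own sample and
publishes (i) the set of selected variables and (ii) the fitted coefficients,
which a later study can reuse either as a candidate-variable list or as a
frozen prediction model.

Two selectors are implemented as sklearn-style estimators:

``LassoStudy``
    L1-penalized logistic regression over a data-driven penalty path, the
    penalty chosen by minimizing the 10-fold cross-validated deviance;
    selected variables are those with nonzero coefficients at the chosen
    penalty. Binary predictors are deliberately left unstandardized: all
    share the 0/1 scale, and standardizing would up-weight rare columns.

``UnivariateStudy``
    Screens each candidate with a univariable logistic Wald test and refits
    one multivariable logistic model on the significant candidates. A known
    suboptimal but popular practice, included deliberately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "StudySample",
    "SelectionResult",
    "drop_degenerate",
    "LassoStudy",
    "UnivariateStudy",
    "fit_lasso_study",
    "fit_univariate_study",
    "predict_logistic",
    "univariate_wald_pvalues",
    "write_selection",
]


@dataclass
class StudySample:
    """A sample drawn for one study: predictor table plus binary outcome."""

    X: pd.DataFrame
    y: np.ndarray
    n_dropped_degenerate: int = 0

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        if len(self.X) != len(self.y):
            raise ValueError("X and y must have the same number of rows")

    @property
    def nondegenerate_names(self) -> list[str]:
        nun = self.X.nunique(axis=0)
        return [c for c in self.X.columns if nun[c] > 1]


def drop_degenerate(sample: StudySample) -> StudySample:
    """Restrict to columns with at least two distinct observed values.

    Sparse indicators frequently collapse to a constant in small samples and
    carry no information for either splitting or regression. The number of
    dropped columns is recorded on the returned sample.
    """
    keep = sample.nondegenerate_names
    if not keep:
        raise ValueError("all columns are degenerate; nothing to fit")
    dropped = sample.X.shape[1] - len(keep)
    return StudySample(X=sample.X[keep], y=sample.y, n_dropped_degenerate=dropped)


@dataclass
class SelectionResult:
    """A preceding study's published output: selected variables + model."""

    method: str
    selected: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    stabilized: bool = False

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(self.selected):
            raise ValueError("coefficients must be keyed exactly by selected")

    @property
    def empty(self) -> bool:
        return len(self.selected) == 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"method": self.method, "variable": "(intercept)", "coefficient": self.intercept}]
        rows += [
            {"method": self.method, "variable": v, "coefficient": self.coefficients[v]}
            for v in self.selected
        ]
        return pd.DataFrame(rows)


def write_selection(results, path: str | Path) -> None:
    """Serialize one or more SelectionResults to a delimited audit file."""
    if isinstance(results, SelectionResult):
        results = [results]
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    pd.concat([r.to_frame() for r in results]).to_csv(path, sep=sep, index=False)


def predict_logistic(result: SelectionResult, X: pd.DataFrame) -> np.ndarray:
    """expit(intercept + sum coef * x) for a published logistic model.

    ``X`` must contain every selected variable; a variable that is degenerate
    in ``X`` simply contributes its constant observed value, which is how a
    frozen preceding model is applied "unchanged" to new data.
    """
    missing = [v for v in result.selected if v not in X.columns]
    if missing:
        raise KeyError(f"selected variables absent from data: {missing}")
    eta = np.full(len(X), result.intercept, dtype=np.float64)
    for v in result.selected:
        eta += result.coefficients[v] * X[v].to_numpy(dtype=np.float64)
    return expit(eta)


def _check_two_classes(y: np.ndarray) -> None:
    counts = np.bincount(np.asarray(y, dtype=np.int64), minlength=2)
    if counts[0] < 2 or counts[1] < 2:
        raise ValueError(
            f"need >=2 rows per outcome class, got {counts[1]} events / {counts[0]} non-events"
        )


def _lambda_path(X: np.ndarray, y: np.ndarray, n_lambdas: int, min_ratio: float | None):
    """glmnet-style penalty path from lambda_max (null model) downward."""
    n, p = X.shape
    ybar = y.mean()
    lam_max = float(np.max(np.abs(X.T @ (y - ybar))) / n)
    if lam_max <= 0:
        lam_max = 1e-3
    if min_ratio is None:
        min_ratio = 0.01 if n < p else 1e-4
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambdas)


class LassoStudy(BaseEstimator):
    """Cross-validated L1-penalized logistic regression selector.

    Parameters
    ----------
    n_folds : int
        CV folds for the penalty choice (default 10).
    n_lambdas : int
        Length of the geometric penalty path from the smallest
        all-coefficients-zero penalty downward.
    lambda_min_ratio : float or None
        Ratio of smallest to largest penalty; defaults to 0.01 when p > n
        else 1e-4.
    fixed_lambda : float or None
        If given, skip the cross-validated penalty choice and fit at this
        penalty (mean-log-likelihood scale) directly.
    random_state : int or None
        Seed for the shuffled stratified CV split.

    Attributes
    ----------
    selected_ : tuple of str
        Variables with nonzero coefficient at the chosen penalty.
    intercept_ : float
    coef_ : dict mapping selected variable -> coefficient
    lambda_ : float
        Chosen penalty (on the mean-log-likelihood scale).
    result_ : SelectionResult
    """

    def __init__(
        self,
        n_folds: int = 10,
        n_lambdas: int = 15,
        lambda_min_ratio: float | None = None,
        fixed_lambda: float | None = None,
        random_state: int | None = None,
    ):
        self.n_folds = n_folds
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.fixed_lambda = fixed_lambda
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y) -> "LassoStudy":
        y = np.asarray(y, dtype=np.int64)
        _check_two_classes(y)
        names = list(X.columns)
        Xv = X.to_numpy(dtype=np.float64)
        n = len(y)
        seed = 0 if self.random_state is None else self.random_state
        # sklearn's C is the inverse of the total penalty; glmnet's lambda is
        # per-observation, hence C = 1 / (n * lambda)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if self.fixed_lambda is not None:
                model = LogisticRegression(
                    C=1.0 / (n * self.fixed_lambda),
                    penalty="l1",
                    solver="liblinear",
                    intercept_scaling=100.0,
                    tol=1e-8,
                    max_iter=2000,
                    random_state=seed,
                ).fit(Xv, y)
                chosen_c = 1.0 / (n * self.fixed_lambda)
            else:
                lambdas = _lambda_path(Xv, y, self.n_lambdas, self.lambda_min_ratio)
                cv = StratifiedKFold(
                    n_splits=self.n_folds, shuffle=True, random_state=self.random_state
                )
                model = LogisticRegressionCV(
                    Cs=1.0 / (n * lambdas),
                    cv=cv,
                    penalty="l1",
                    solver="liblinear",
                    scoring="neg_log_loss",
                    intercept_scaling=100.0,
                    tol=1e-6,
                    max_iter=500,
                    refit=True,
                    random_state=seed,
                ).fit(Xv, y)
                chosen_c = float(model.C_[0])
        coefs = model.coef_.ravel()
        nz = np.flatnonzero(coefs != 0.0)
        self.selected_ = tuple(names[j] for j in nz)
        self.intercept_ = float(model.intercept_[0])
        self.coef_ = {names[j]: float(coefs[j]) for j in nz}
        self.lambda_ = float(1.0 / (n * chosen_c))
        self.result_ = SelectionResult(
            method="lasso",
            selected=self.selected_,
            intercept=self.intercept_,
            coefficients=self.coef_,
        )
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p1 = predict_logistic(self.result_, X)
        return np.column_stack([1.0 - p1, p1])


def univariate_wald_pvalues(X: pd.DataFrame, y) -> pd.Series:
    """Two-sided Wald p-value of the slope in a univariable logistic model,
    per column.

    For binary 0/1 predictors the univariable logistic MLE has the closed
    form of the 2x2-table log odds ratio with its standard error
    sqrt(sum of reciprocal cell counts); any empty cell makes the Wald
    statistic degenerate and the column is assigned p = 1. Numeric columns
    are fitted iteratively.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    pvals = pd.Series(np.ones(X.shape[1]), index=X.columns, dtype=np.float64)

    values = X.to_numpy(dtype=np.float64)
    is_binary = np.array([np.isin(values[:, j], (0.0, 1.0)).all() for j in range(X.shape[1])])

    if is_binary.any():
        Xb = values[:, is_binary]
        y1 = y.sum()
        x1 = Xb.sum(axis=0)
        n11 = Xb.T @ y
        n10 = x1 - n11
        n01 = y1 - n11
        n00 = n - x1 - y1 + n11
        with np.errstate(divide="ignore", invalid="ignore"):
            ok = (n11 > 0) & (n10 > 0) & (n01 > 0) & (n00 > 0)
            log_or = np.log(n11 * n00 / (n10 * n01))
            se = np.sqrt(1 / n11 + 1 / n10 + 1 / n01 + 1 / n00)
            z = np.where(ok, log_or / se, 0.0)
        pvals.iloc[np.flatnonzero(is_binary)] = np.where(ok, 2 * norm.sf(np.abs(z)), 1.0)

    for j in np.flatnonzero(~is_binary):
        x = values[:, j]
        if np.ptp(x) == 0:
            continue
        design = sm.add_constant(x)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=100)
            pvals.iloc[j] = float(res.pvalues[1]) if res.converged else 1.0
        except Exception:
            pvals.iloc[j] = 1.0
    return pvals


class UnivariateStudy(BaseEstimator):
    """Univariate-screening logistic selector.

    Each candidate is tested in a univariable logistic model (Wald test on
    the slope); candidates with p < ``alpha`` enter a single multivariable
    logistic fit whose coefficients form the published model. When the plain
    maximum-likelihood fit separates or fails to converge — common with
    sparse binary columns in small samples — a tiny L2 stabilizer
    (``ridge_stabilizer``, default 1e-6 total penalty) is applied instead and
    the result flagged.

    Attributes: ``selected_``, ``intercept_``, ``coef_``, ``pvalues_``,
    ``result_``.
    """

    def __init__(self, alpha: float = 0.05, ridge_stabilizer: float = 1e-6):
        self.alpha = alpha
        self.ridge_stabilizer = ridge_stabilizer

    def fit(self, X: pd.DataFrame, y) -> "UnivariateStudy":
        y = np.asarray(y, dtype=np.int64)
        _check_two_classes(y)
        self.pvalues_ = univariate_wald_pvalues(X, y)
        selected = [c for c in X.columns if self.pvalues_[c] < self.alpha]
        stabilized = False
        if not selected:
            intercept = float(np.log(y.mean() / (1.0 - y.mean())))
            coefs: dict[str, float] = {}
        else:
            Xs = X[selected].to_numpy(dtype=np.float64)
            params = self._fit_multivariable(Xs, y)
            if params is None:
                stabilized = True
                params = self._fit_stabilized(Xs, y)
                warnings.warn(
                    "multivariable fit after univariate selection did not "
                    "converge; using ridge-stabilized fit",
                    stacklevel=2,
                )
            intercept = float(params[0])
            coefs = {v: float(params[1 + j]) for j, v in enumerate(selected)}
        self.selected_ = tuple(selected)
        self.intercept_ = intercept
        self.coef_ = coefs
        self.result_ = SelectionResult(
            method="univariate",
            selected=self.selected_,
            intercept=intercept,
            coefficients=coefs,
            stabilized=stabilized,
        )
        return self

    @staticmethod
    def _fit_multivariable(Xs: np.ndarray, y: np.ndarray):
        design = sm.add_constant(Xs)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=100)
            if res.converged and np.all(np.isfinite(res.params)) and np.max(np.abs(res.params)) < 30:
                return np.asarray(res.params)
        except Exception:
            pass
        return None

    def _fit_stabilized(self, Xs: np.ndarray, y: np.ndarray) -> np.ndarray:
        model = LogisticRegression(
            penalty="l2", C=1.0 / self.ridge_stabilizer, solver="lbfgs", max_iter=2000
        ).fit(Xs, y)
        return np.concatenate([model.intercept_, model.coef_.ravel()])

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p1 = predict_logistic(self.result_, X)
        return np.column_stack([1.0 - p1, p1])


def fit_lasso_study(
    sample: StudySample,
    n_cv_folds: int = 10,
    seed: int | None = None,
    n_lambdas: int = 15,
    lambda_min_ratio: float | None = None,
) -> SelectionResult:
    """Fit the Lasso preceding study on a (degenerate-filtered) sample."""
    est = LassoStudy(
        n_folds=n_cv_folds,
        n_lambdas=n_lambdas,
        lambda_min_ratio=lambda_min_ratio,
        random_state=seed,
    ).fit(sample.X, sample.y)
    return est.result_


def fit_univariate_study(sample: StudySample, alpha: float = 0.05) -> SelectionResult:
    """Fit the univariate-selection preceding study on a sample."""
    return UnivariateStudy(alpha=alpha).fit(sample.X, sample.y).result_
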