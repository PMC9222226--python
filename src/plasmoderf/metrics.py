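"""Performance measures for probabilistic binary predictions.

All measures are computed on a validation set: AUROC (concordance), Brier
score, calibration slope (slope of a logistic recalibration of the outcome on
the predicted log odds; 1 is ideal, >1 underfit, <1 overfit) and cross-entropy
(negative Bernoulli log-likelihood, reported as the SUM over the validation
set together with its maximum single-observation contribution).

A single clipping constant is shared by every measure that takes a logarithm
or a logit of a predicted probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import rankdata

__all__ = [
    "PerformanceRecord",
    "auroc",
    "brier",
    "cross_entropy",
    "calibration_slope",
    "mse_log_slope",
    "calibration_table",
    "calibration_plot",
    "evaluate_predictions",
]

#: default clipping constant for logs/logits of predicted probabilities
CLIP = 1e-6


@dataclass
class PerformanceRecord:
    """One (scenario x replication x method) row of the four measures."""

    scenario_id: str
    replication: int
    method: str
    auroc: float
    brier: float
    cal_slope: float
    cross_entropy: float
    max_ce_contribution: float
    failed: bool = False


def _check_pair(p, y) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y)
    if p.shape != y.shape:
        raise ValueError("p and y must have the same length")
    return p, y


def auroc(p, y) -> float:
    """Concordance statistic: P(prediction of an event exceeds that of a
    non-event), ties counting 1/2 (rank-sum / Mann-Whitney formulation)."""
    p, y = _check_pair(p, y)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC needs both outcome classes present")
    ranks = rankdata(p)
    rank_sum = float(ranks[y == 1].sum())
    return (rank_sum - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def brier(p, y) -> float:
    """Mean squared difference between prediction and outcome; ideal 0."""
    p, y = _check_pair(p, y)
    return float(np.mean((y - p) ** 2))


def cross_entropy(p, y, clip: float = CLIP) -> tuple[float, float]:
    """Summed negative Bernoulli log-likelihood and its maximum contribution.

    Predictions are clipped into [clip, 1-clip] before taking logs. Returns
    ``(total, max_contribution)`` where the total is a sum, not a mean.
    """
    p, y = _check_pair(p, y)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predictions must lie in [0, 1]")
    pc = np.clip(p, clip, 1.0 - clip)
    contrib = -(y * np.log(pc) + (1 - y) * np.log(1.0 - pc))
    return float(contrib.sum()), float(contrib.max())


def calibration_slope(p, y, clip: float = CLIP) -> float:
    """Slope of a logistic regression of ``y`` on logit(p), with intercept.

    Ideal value 1. Returns ``nan`` when the fit is degenerate (constant
    log odds) or does not converge; callers exclude flagged values from
    aggregation.
    """
    p, y = _check_pair(p, y)
    eta = logit(np.clip(p, clip, 1.0 - clip))
    if np.ptp(eta) == 0.0:
        return float("nan")
    design = sm.add_constant(eta)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=100)
        if not res.converged or not np.all(np.isfinite(res.params)):
            return float("nan")
        return float(res.params[1])
    except Exception:
        return float("nan")


def mse_log_slope(slopes) -> float:
    """Mean of squared log calibration slopes.

    Evaluates the deviation of the log slope from its ideal value 0.
    Non-positive or non-finite slopes are excluded (the caller counts them);
    an empty input after exclusion is an error.
    """
    s = np.asarray(slopes, dtype=np.float64)
    s = s[np.isfinite(s) & (s > 0)]
    if s.size == 0:
        raise ValueError("no positive finite slopes to aggregate")
    return float(np.mean(np.log(s) ** 2))


def calibration_table(p, y, n_groups: int = 10) -> pd.DataFrame:
    """Decile-grouped observed vs. predicted probabilities.

    Groups are defined by the quantiles of ``p``; groups collapsed by ties
    are merged (with a warning). Returns one row per group with its size,
    mean prediction and observed event rate.
    """
    p, y = _check_pair(p, y)
    if len(p) < n_groups:
        raise ValueError("need at least n_groups observations")
    if np.ptp(p) == 0.0:
        warnings.warn(f"ties collapsed {n_groups} groups into 1", stacklevel=2)
        return pd.DataFrame(
            {"n": [len(p)], "mean_predicted": [float(p.mean())],
             "observed_rate": [float(np.mean(y))]}
        )
    bins = pd.qcut(p, q=n_groups, duplicates="drop")
    if len(bins.categories) < n_groups:
        warnings.warn(
            f"ties collapsed {n_groups} groups into {len(bins.categories)}",
            stacklevel=2,
        )
    frame = pd.DataFrame({"p": p, "y": np.asarray(y, dtype=float), "group": bins})
    grouped = frame.groupby("group", observed=True)
    out = pd.DataFrame(
        {
            "n": grouped.size(),
            "mean_predicted": grouped["p"].mean(),
            "observed_rate": grouped["y"].mean(),
        }
    ).reset_index(drop=True)
    out.index.name = "group"
    return out


def calibration_plot(p, y, n_groups: int = 10, clip: float = CLIP, ax=None):
    """Calibration plot: grouped observed rates against mean predictions,
    with the diagonal and the logistic recalibration curve overlaid.

    Returns ``(ax, table)``; the table is the grouped summary used for the
    points, suitable for testing without rendering.
    """
    import matplotlib

    if ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = calibration_table(p, y, n_groups=n_groups)
    p, y = _check_pair(p, y)
    eta = logit(np.clip(p, clip, 1.0 - clip))
    slope = calibration_slope(p, y, clip=clip)

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot([0, 1], [0, 1], color="grey", lw=0.8, ls="--", label="ideal")
    if np.isfinite(slope) and np.ptp(eta) > 0:
        design = sm.add_constant(eta)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=100)
        grid = np.linspace(eta.min(), eta.max(), 200)
        ax.plot(
            expit(grid),
            expit(res.params[0] + res.params[1] * grid),
            color="C1",
            label=f"recalibration (slope {slope:.2f})",
        )
    ax.plot(
        table["mean_predicted"], table["observed_rate"], "o", color="C0",
        label="grouped observed",
    )
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed event rate")
    ax.legend(loc="best", fontsize=8)
    return ax, table


def evaluate_predictions(
    p, y, scenario_id: str = "", replication: int = 0, method: str = "",
    clip: float = CLIP,
) -> PerformanceRecord:
    """All four measures on one prediction vector, as a PerformanceRecord."""
    total, max_contrib = cross_entropy(p, y, clip=clip)
    return PerformanceRecord(
        scenario_id=scenario_id,
        replication=replication,
        method=method,
        auroc=auroc(p, y),
        brier=brier(p, y),
        cal_slope=calibration_slope(p, y, clip=clip),
        cross_entropy=total,
        max_ce_contribution=max_contrib,
    )
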