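"""ADEMP orchestration: scenarios, replications, aggregation, run manifest.

One replication of one scenario draws four mutually disjoint samples from the
population — two "preceding studies", the "current study" (all of the
scenario's sample size) and a validation set — fits both preceding selectors,
resolves the M1-M5 candidate sets, trains five probability forests plus a
Lasso comparator on the current sample, and evaluates all six prediction
vectors on the validation set.

Every stochastic component derives its seed from
(base seed, sample size, arm, replication, component tag), so results are
reproducible regardless of how replications are scheduled across workers.
"""

from __future__ import annotations

import platform
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import __version__
from .config import StudyConfig
from .metrics import PerformanceRecord, evaluate_predictions, mse_log_slope
from .population import Population, generate_population
from .preceding import (
    StudySample,
    drop_degenerate,
    fit_lasso_study,
    fit_univariate_study,
    predict_logistic,
)
from .reinforce import apply_reinforcement
from .strategies import (
    METHODS,
    ForestParams,
    build_strategy_set,
    fit_lasso_comparator,
    train_probability_forest,
)

__all__ = [
    "Scenario",
    "StudyResult",
    "derive_seed",
    "draw_replication_samples",
    "run_replication",
    "run_study",
    "aggregate_records",
    "aggregate_descriptives",
]

_ARM_CODE = {"weak": 0, "strong": 1}
_TAGS = {"sampling": 1, "lasso": 2, "forest": 3, "comparator": 4}

RECORD_COLUMNS = [
    "scenario_id", "replication", "method", "auroc", "brier", "cal_slope",
    "cross_entropy", "max_ce_contribution", "failed",
]


@dataclass(frozen=True)
class Scenario:
    """One cell of the sample-size x predictability design."""

    sample_size: int
    predictability: str
    n_replications: int
    validation_size: int

    def __post_init__(self) -> None:
        if self.predictability not in _ARM_CODE:
            raise ValueError(f"unknown predictability arm {self.predictability!r}")
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")

    @property
    def scenario_id(self) -> str:
        return f"{self.predictability}_n{self.sample_size}"


def derive_seed(base_seed: int, *keys: int) -> int:
    """Stable per-component seed from (base seed, structured keys), < 2**31."""
    ss = np.random.SeedSequence([int(base_seed)] + [int(k) for k in keys])
    return int(ss.generate_state(1)[0] % 2**31)


def _scenario_seed(base: int, scenario: Scenario, rep: int, tag: str, extra: int = 0) -> int:
    return derive_seed(
        base, scenario.sample_size, _ARM_CODE[scenario.predictability],
        rep, _TAGS[tag], extra,
    )


def draw_replication_samples(
    pop: Population,
    scenario: Scenario,
    rep_index: int,
    base_seed: int,
    max_retries: int = 5,
) -> tuple[StudySample, StudySample, StudySample, StudySample]:
    """Four mutually disjoint samples drawn without replacement.

    Returns (preceding 1, preceding 2, current, validation), each with the
    outcome of the scenario's predictability arm. Disjointness prevents any
    leakage from the preceding studies into the current study or the
    validation set. Draws in which any training sample contains a single
    outcome class are retried (fresh permutation) up to ``max_retries``
    times, then rejected.
    """
    n, v = scenario.sample_size, scenario.validation_size
    if 3 * n + v > pop.n_pop:
        raise ValueError(
            f"infeasible scenario: 3*{n} + {v} rows needed from population of {pop.n_pop}"
        )
    y_all = pop.outcome(scenario.predictability)
    for attempt in range(max_retries + 1):
        seed = _scenario_seed(base_seed, scenario, rep_index, "sampling", attempt)
        perm = np.random.default_rng(seed).permutation(pop.n_pop)
        cuts = np.cumsum([n, n, n, v])
        idx_sets = np.split(perm[: cuts[-1]], cuts[:-1])
        # original row labels are kept so disjointness stays verifiable
        samples = [StudySample(X=pop.X.iloc[idx], y=y_all[idx]) for idx in idx_sets]
        if all(s.y.min() != s.y.max() for s in samples[:3]):
            return tuple(samples)  # type: ignore[return-value]
    raise RuntimeError(
        f"replication {rep_index} of {scenario.scenario_id}: single-class draw "
        f"persisted through {max_retries} retries"
    )


def _failed_record(scenario_id: str, rep: int, method: str) -> PerformanceRecord:
    nan = float("nan")
    return PerformanceRecord(scenario_id, rep, method, nan, nan, nan, nan, nan, failed=True)


def run_replication(
    pop: Population, scenario: Scenario, rep_index: int, config: StudyConfig
) -> tuple[list[PerformanceRecord], dict]:
    """One full replication: 6 performance records plus descriptive counts."""
    pre1, pre2, current, validation = draw_replication_samples(
        pop, scenario, rep_index, config.base_seed
    )
    sel_lasso = fit_lasso_study(
        drop_degenerate(pre1),
        n_cv_folds=config.lasso.n_folds,
        seed=_scenario_seed(config.base_seed, scenario, rep_index, "lasso"),
        n_lambdas=config.lasso.n_lambdas,
        lambda_min_ratio=config.lasso.lambda_min_ratio,
    )
    sel_uni = fit_univariate_study(drop_degenerate(pre2), alpha=config.alpha)
    current_nd = drop_degenerate(current)

    scenario_id = scenario.scenario_id
    forest_seed = _scenario_seed(config.base_seed, scenario, rep_index, "forest")
    records: list[PerformanceRecord] = []
    descr: dict = {
        "scenario_id": scenario_id,
        "replication": rep_index,
        "n_nondegenerate": current_nd.X.shape[1],
        "n_selected_lasso": len(sel_lasso.selected),
        "n_selected_univariate": len(sel_uni.selected),
        "n_union": len(set(sel_lasso.selected) | set(sel_uni.selected)),
        "n_intersection": len(set(sel_lasso.selected) & set(sel_uni.selected)),
        "m5_winner": "n/a",
    }

    try:
        comparator = fit_lasso_comparator(
            current,
            seed=_scenario_seed(config.base_seed, scenario, rep_index, "comparator"),
            n_cv_folds=config.lasso.n_folds,
            n_lambdas=config.lasso.n_lambdas,
            lambda_min_ratio=config.lasso.lambda_min_ratio,
        )
        p_val = predict_logistic(comparator, validation.X)
        records.append(
            evaluate_predictions(
                p_val, validation.y, scenario_id, rep_index, "LASSO", clip=config.clip
            )
        )
        descr["n_selected_comparator"] = len(comparator.selected)
    except Exception:
        records.append(_failed_record(scenario_id, rep_index, "LASSO"))
        descr["n_selected_comparator"] = -1

    params = config.forest
    for method in METHODS[1:]:
        try:
            sset = build_strategy_set(method, sel_lasso, sel_uni, current)
            if method == "M5":
                descr["m5_winner"] = sset.m5_winner
            descr[f"n_vars_{method}"] = len(sset.variables)
            descr[f"fallback_{method}"] = sset.fallback_applied
            forest = train_probability_forest(
                current_nd.X[list(sset.variables)],
                current_nd.y,
                ForestParams(
                    n_trees=params.n_trees,
                    mtry=params.mtry,
                    min_node_size=params.min_node_size,
                    seed=forest_seed,
                ),
            )
            p_val = forest.predict_event_probability(validation.X[list(sset.variables)])
            records.append(
                evaluate_predictions(
                    p_val, validation.y, scenario_id, rep_index, method, clip=config.clip
                )
            )
        except Exception:
            records.append(_failed_record(scenario_id, rep_index, method))
            descr.setdefault(f"n_vars_{method}", -1)
            descr.setdefault(f"fallback_{method}", "error")
    return records, descr


def aggregate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Per-(scenario, method) summaries: mean/SD of every measure, the MSE of
    the log calibration slope, the mean maximum cross-entropy contribution,
    and exclusion counts for degenerate slopes."""
    rows = []
    for (scenario_id, method), g in records.groupby(["scenario_id", "method"], sort=True):
        ok = g[~g["failed"]]
        slopes = ok["cal_slope"].to_numpy()
        finite = slopes[np.isfinite(slopes)]
        positive = finite[finite > 0]
        row = {
            "scenario_id": scenario_id,
            "method": method,
            "n_replications": len(g),
            "n_failed": int(g["failed"].sum()),
            "n_slope_excluded": len(ok) - len(positive),
        }
        for measure in ("auroc", "brier", "cross_entropy", "max_ce_contribution"):
            row[f"mean_{measure}"] = float(ok[measure].mean())
            row[f"sd_{measure}"] = float(ok[measure].std(ddof=1)) if len(ok) > 1 else 0.0
        row["mean_cal_slope"] = float(finite.mean()) if finite.size else float("nan")
        row["sd_cal_slope"] = float(finite.std(ddof=1)) if finite.size > 1 else 0.0
        row["mse_log_slope"] = (
            mse_log_slope(positive) if positive.size else float("nan")
        )
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_descriptives(descriptives: pd.DataFrame) -> pd.DataFrame:
    """Per-scenario mean (min, max) of non-degenerate and selected counts."""
    rows = []
    count_cols = [
        "n_nondegenerate", "n_selected_lasso", "n_selected_univariate",
        "n_union", "n_intersection",
    ]
    for scenario_id, g in descriptives.groupby("scenario_id", sort=True):
        row = {"scenario_id": scenario_id, "n_replications": len(g)}
        for col in count_cols:
            row[f"mean_{col}"] = float(g[col].mean())
            row[f"min_{col}"] = int(g[col].min())
            row[f"max_{col}"] = int(g[col].max())
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StudyResult:
    """Everything a study run produces."""

    records: pd.DataFrame
    descriptives: pd.DataFrame
    aggregates: pd.DataFrame
    selection_summary: pd.DataFrame
    manifest: dict
    population: Population | None = None


def _versions() -> dict:
    import scipy
    import sklearn
    import statsmodels

    return {
        "plasmoderf": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def build_population(config: StudyConfig) -> tuple[Population, dict]:
    """Generate the synthetic population and, if a strong arm is requested,
    apply the reinforcement step. Returns the population plus diagnostics."""
    pop = generate_population(config.population)
    info: dict = {"event_rate_weak": float(np.mean(pop.y_weak))}
    if "strong" in config.arms:
        pop, report = apply_reinforcement(pop, config.reinforcement)
        info.update(
            reinforcement_oof_auroc=float(report.oof_auroc),
            reinforcement_oof_cal_slope=float(report.oof_cal_slope),
            event_rate_strong=float(report.event_rate_strong),
        )
    return pop, info


def run_study(
    config: StudyConfig,
    pop: Population | None = None,
    out_dir=None,
    verbose: int = 0,
) -> StudyResult:
    """Run the full scenario grid and aggregate the results.

    Replications are parallelizable (``config.n_jobs``) and reproducible
    regardless of worker count because every replication derives its own
    seeds. Fails before any work if a scenario is infeasible for the
    population size. If ``out_dir`` is given, tidy records, descriptives,
    aggregate tables and a manifest are written there.
    """
    pop_info: dict = {}
    if pop is None:
        if not config.feasible(config.population.n_pop):
            raise ValueError("scenario grid infeasible for configured population size")
        pop, pop_info = build_population(config)
    if not config.feasible(pop.n_pop):
        raise ValueError("scenario grid infeasible for the supplied population")
    if "strong" in config.arms and pop.y_strong is None:
        raise ValueError("strong arm requested but population has no y_strong")

    scenarios = [
        Scenario(n, arm, config.n_replications, config.validation_size)
        for arm in config.arms
        for n in config.sample_sizes
    ]

    all_records: list[PerformanceRecord] = []
    all_descr: list[dict] = []
    for scenario in scenarios:
        results = Parallel(n_jobs=config.n_jobs, verbose=verbose)(
            delayed(run_replication)(pop, scenario, rep, config)
            for rep in range(scenario.n_replications)
        )
        for records, descr in results:
            all_records.extend(records)
            all_descr.append(descr)

    records = pd.DataFrame([asdict(r) for r in all_records], columns=RECORD_COLUMNS)
    descriptives = pd.DataFrame(all_descr)
    aggregates = aggregate_records(records)
    selection_summary = aggregate_descriptives(descriptives)

    manifest = {
        "config": _plain(asdict(config)),
        "versions": _versions(),
        "population": pop_info,
        "scenarios": [s.scenario_id for s in scenarios],
        "n_records": len(records),
        "n_failed": int(records["failed"].sum()),
        "n_slope_excluded": int(aggregates["n_slope_excluded"].sum()),
    }

    result = StudyResult(
        records=records,
        descriptives=descriptives,
        aggregates=aggregates,
        selection_summary=selection_summary,
        manifest=manifest,
        population=pop,
    )
    if out_dir is not None:
        write_study_outputs(result, out_dir)
    return result


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_study_outputs(result: StudyResult, out_dir) -> None:
    """Write tidy records, descriptives, aggregate tables and the manifest."""
    import yaml
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(out / "records.csv", index=False)
    result.descriptives.to_csv(out / "descriptives.csv", index=False)
    result.aggregates.to_csv(out / "aggregate_measures.csv", index=False)
    result.selection_summary.to_csv(out / "aggregate_selection.csv", index=False)
    (out / "manifest.yaml").write_text(yaml.safe_dump(result.manifest, sort_keys=False))
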