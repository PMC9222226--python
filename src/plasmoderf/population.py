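"""Synthetic plasmode population: generation, summaries and delimited-text I/O.

The population emulates a large pharmacoepidemiologic registry extract: a few
numeric covariates (standardized age/year analogues) plus many sparse binary
indicators (prescription / diagnosis codes) whose prevalences are heavily
left-skewed on the log scale, and one weakly predictable binary outcome.

A second, strongly predictable outcome (``y_strong``) is attached later by the
reinforcement procedure in :mod:`plasmoderf.reinforce`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "VariableSpec",
    "PopulationConfig",
    "Population",
    "PopulationSchema",
    "generate_population",
    "empirical_prevalence_quartiles",
    "read_population",
    "write_population",
]

#: quartiles of binary-predictor prevalence emulated by default (sparse
#: registry indicators: Q1 = 1/3371, median = 1/1530, Q3 = 1/112)
DEFAULT_PREVALENCE_QUARTILES = (1.0 / 3371.0, 1.0 / 1530.0, 1.0 / 112.0)


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one predictor column.

    Parameters
    ----------
    name : str
        Unique column name.
    kind : {"binary", "numeric"}
    prevalence : float or None
        Target P(X=1) for binary variables, in (0, 1); None for numeric.
    effect : float
        Log-odds coefficient of the variable in the synthetic outcome model
        (0 for null variables).
    """

    name: str
    kind: str
    prevalence: float | None = None
    effect: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "numeric"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == "binary":
            if self.prevalence is None or not (0.0 < self.prevalence < 1.0):
                raise ValueError(
                    f"binary variable {self.name!r} needs prevalence in (0,1), "
                    f"got {self.prevalence!r}"
                )


@dataclass
class PopulationConfig:
    """Parameters of the synthetic population generator.

    The defaults emulate the registry fingerprint the simulation is built
    around: ~1150 mostly sparse binary predictors, two standardized numeric
    covariates, and a weakly predictable outcome with event rate 0.558.
    """

    n_pop: int = 20_000
    p_binary: int = 1150
    p_numeric: int = 2
    prevalence_quartiles: tuple[float, float, float] = DEFAULT_PREVALENCE_QUARTILES
    target_event_rate: float = 0.558
    signal_fraction: float = 0.05
    effect_scale: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_event_rate < 1.0):
            raise ValueError("target_event_rate must lie in (0,1)")
        q1, med, q3 = self.prevalence_quartiles
        if not (0.0 < q1 <= med <= q3 < 1.0):
            raise ValueError("prevalence quartiles must satisfy 0 < q1 <= median <= q3 < 1")
        if self.p_binary < 1:
            raise ValueError("p_binary must be >= 1")
        if not (0.0 <= self.signal_fraction <= 1.0):
            raise ValueError("signal_fraction must lie in [0,1]")


@dataclass
class Population:
    """A plasmode population: predictor table, outcomes and variable metadata."""

    X: pd.DataFrame
    y_weak: np.ndarray
    specs: list[VariableSpec]
    seed: int = 0
    y_strong: np.ndarray | None = None
    generator_intercept: float | None = None

    def __post_init__(self) -> None:
        self.y_weak = np.asarray(self.y_weak, dtype=np.int8)
        if self.y_strong is not None:
            self.y_strong = np.asarray(self.y_strong, dtype=np.int8)
        if self.X.shape[1] != len(self.specs):
            raise ValueError("column count must equal len(specs)")
        names = [s.name for s in self.specs]
        if list(self.X.columns) != names:
            raise ValueError("spec names must match predictor columns in order")
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        if len(self.y_weak) != len(self.X):
            raise ValueError("y_weak length must equal number of rows")
        if self.X.isna().any().any():
            raise ValueError("population must not contain missing values")
        for y, label in ((self.y_weak, "y_weak"), (self.y_strong, "y_strong")):
            if y is not None and not np.isin(y, (0, 1)).all():
                raise ValueError(f"{label} must be binary 0/1")
        if len(self.X) < 4:
            raise ValueError("population needs at least 4 rows")

    @property
    def n_pop(self) -> int:
        return len(self.X)

    @property
    def binary_names(self) -> list[str]:
        return [s.name for s in self.specs if s.kind == "binary"]

    @property
    def numeric_names(self) -> list[str]:
        return [s.name for s in self.specs if s.kind == "numeric"]

    def outcome(self, predictability: str) -> np.ndarray:
        """Outcome vector for a predictability arm ("weak" or "strong")."""
        if predictability == "weak":
            return self.y_weak
        if predictability == "strong":
            if self.y_strong is None:
                raise ValueError("y_strong not present; apply reinforcement first")
            return self.y_strong
        raise ValueError(f"unknown predictability arm {predictability!r}")

    def with_strong_outcome(self, y_strong: np.ndarray) -> "Population":
        return replace(self, y_strong=np.asarray(y_strong, dtype=np.int8))


def _sample_prevalences(
    n: int, quartiles: tuple[float, float, float], rng: np.random.Generator
) -> np.ndarray:
    """Two-piece log-uniform prevalence law pinned to three quartiles.

    Half of the mass is uniform in log-prevalence on [q1**2/med, med], half on
    [med, q3**2/med]; the 25/50/75% quantiles of the law are then exactly
    (q1, med, q3).
    """
    q1, med, q3 = (np.log(q) for q in quartiles)
    lo, hi = 2.0 * q1 - med, 2.0 * q3 - med
    u = rng.uniform(size=n)
    logq = np.where(
        u < 0.5,
        lo + (u / 0.5) * (med - lo),
        med + ((u - 0.5) / 0.5) * (hi - med),
    )
    return np.exp(logq)


def _draw_effects(
    prevalences: np.ndarray,
    signal_fraction: float,
    effect_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sparse signed log-odds effects over the binary predictors.

    A fixed round(signal_fraction * p) subset carries signal; membership is
    drawn with probability proportional to q(1-q), so better-supported
    variables are more likely informative (ultra-sparse indicators carry
    almost no learnable information either way). Magnitudes are
    exponential with mean ``effect_scale``, signs random.
    """
    p = len(prevalences)
    effects = np.zeros(p)
    n_signal = int(round(signal_fraction * p))
    if n_signal == 0 or effect_scale == 0.0:
        return effects
    weights = prevalences * (1.0 - prevalences)
    weights = weights / weights.sum()
    idx = rng.choice(p, size=n_signal, replace=False, p=weights)
    effects[idx] = rng.choice((-1.0, 1.0), size=n_signal) * rng.exponential(
        scale=effect_scale, size=n_signal
    )
    return effects


def _solve_intercept(eta0: np.ndarray, target: float) -> float:
    """Intercept b0 with mean(expit(b0 + eta0)) == target, by root bracketing."""

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + eta0)) - target)

    lo, hi = -40.0, 40.0
    if not (gap(lo) < 0.0 < gap(hi)):
        raise ValueError(
            "event-rate intercept has no finite solution; check generator effects "
            f"(linear predictor range [{eta0.min():.2f}, {eta0.max():.2f}], "
            f"target rate {target})"
        )
    b0 = brentq(gap, lo, hi, xtol=1e-10)
    if not np.isfinite(b0):
        raise ValueError("non-finite intercept solution")
    return float(b0)


def generate_population(config: PopulationConfig) -> Population:
    """Draw a synthetic population under ``config``.

    Binary predictors are independent Bernoulli columns with prevalences from
    the two-piece log-uniform law; numeric predictors are standard normal.
    The weak outcome is Bernoulli(expit(b0 + sum_j beta_j x_j)) with the
    intercept b0 solved numerically so the expected event rate equals
    ``target_event_rate``. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    prevalences = _sample_prevalences(config.p_binary, config.prevalence_quartiles, rng)
    effects = _draw_effects(prevalences, config.signal_fraction, config.effect_scale, rng)

    width = max(4, len(str(config.p_binary)))
    specs = [
        VariableSpec(f"bin_{i + 1:0{width}d}", "binary", float(prevalences[i]), float(effects[i]))
        for i in range(config.p_binary)
    ]
    Xb = (rng.uniform(size=(config.n_pop, config.p_binary)) < prevalences).astype(np.float64)
    columns = {s.name: Xb[:, i] for i, s in enumerate(specs)}

    for j in range(config.p_numeric):
        name = f"num_{j + 1}"
        specs.append(VariableSpec(name, "numeric", None, 0.0))
        columns[name] = rng.standard_normal(config.n_pop)

    X = pd.DataFrame(columns)
    eta0 = Xb @ effects
    b0 = _solve_intercept(eta0, config.target_event_rate)
    probs = expit(b0 + eta0)
    y_weak = (rng.uniform(size=config.n_pop) < probs).astype(np.int8)

    return Population(
        X=X, y_weak=y_weak, specs=specs, seed=config.seed, generator_intercept=b0
    )


def empirical_prevalence_quartiles(pop: Population) -> tuple[float, float, float]:
    """(Q1, median, Q3) of per-column means over the binary predictors.

    Uses linear-interpolation (type-7) quantiles.
    """
    names = pop.binary_names
    if not names:
        raise ValueError("population has no binary variables")
    means = pop.X[names].mean(axis=0).to_numpy()
    q1, med, q3 = np.quantile(means, [0.25, 0.5, 0.75], method="linear")
    return float(q1), float(med), float(q3)


@dataclass
class PopulationSchema:
    """Names of the outcome columns inside a population file."""

    outcome: str = "y_weak"
    strong_outcome: str | None = "y_strong"
    binary_columns: Sequence[str] | None = None


def _dialect(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _vars_path(path: Path) -> Path:
    return path.with_name(path.stem + ".vars" + path.suffix)


def write_population(pop: Population, path: str | Path) -> None:
    """Write a population plus its variable-metadata companion file.

    The data file holds the predictors and the outcome column(s); binary
    columns and outcomes are written as integers so the round trip is exact.
    A companion ``<stem>.vars`` file records name, kind, prevalence and
    generator effect per variable.
    """
    path = Path(path)
    sep = _dialect(path)
    table = pop.X.copy()
    for s in pop.specs:
        if s.kind == "binary":
            table[s.name] = table[s.name].astype(np.int64)
    table["y_weak"] = pop.y_weak.astype(np.int64)
    if pop.y_strong is not None:
        table["y_strong"] = pop.y_strong.astype(np.int64)
    table.to_csv(path, sep=sep, index=False)

    meta = pd.DataFrame(
        {
            "name": [s.name for s in pop.specs],
            "kind": [s.kind for s in pop.specs],
            "prevalence": [s.prevalence for s in pop.specs],
            "effect": [s.effect for s in pop.specs],
        }
    )
    meta.to_csv(_vars_path(path), sep=sep, index=False)


def read_population(
    path: str | Path, schema: PopulationSchema | None = None, seed: int = 0
) -> Population:
    """Read and validate a delimited-text population.

    Raises with row/column diagnostics on missing values, non-binary entries
    in declared binary columns, duplicate names, or a missing outcome column.
    """
    path = Path(path)
    schema = schema or PopulationSchema()
    sep = _dialect(path)
    table = pd.read_csv(path, sep=sep)

    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise ValueError(f"duplicate column names in {path}: {dupes}")
    if schema.outcome not in table.columns:
        raise ValueError(f"outcome column {schema.outcome!r} missing from {path}")
    na_cols = table.columns[table.isna().any()].tolist()
    if na_cols:
        rows = table.index[table[na_cols].isna().any(axis=1)].tolist()[:5]
        raise ValueError(f"missing values in columns {na_cols} (e.g. rows {rows})")

    y_weak = table.pop(schema.outcome).to_numpy()
    y_strong = None
    if schema.strong_outcome and schema.strong_outcome in table.columns:
        y_strong = table.pop(schema.strong_outcome).to_numpy()

    vars_file = _vars_path(path)
    specs: list[VariableSpec] = []
    if vars_file.exists():
        meta = pd.read_csv(vars_file, sep=sep)
        by_name = {str(r["name"]): r for _, r in meta.iterrows()}
        for col in table.columns:
            if col not in by_name:
                raise ValueError(f"column {col!r} absent from metadata file {vars_file}")
            r = by_name[col]
            prev = None if pd.isna(r["prevalence"]) else float(r["prevalence"])
            specs.append(VariableSpec(str(col), str(r["kind"]), prev, float(r["effect"])))
    else:
        declared = set(schema.binary_columns or [])
        for col in table.columns:
            values = table[col].to_numpy()
            is_binary = col in declared or bool(np.isin(values, (0, 1)).all())
            if is_binary:
                prev = float(np.clip(values.mean(), 1e-12, 1 - 1e-12))
                specs.append(VariableSpec(str(col), "binary", prev))
            else:
                specs.append(VariableSpec(str(col), "numeric"))

    for s in specs:
        if s.kind == "binary":
            values = table[s.name].to_numpy()
            bad = ~np.isin(values, (0, 1))
            if bad.any():
                rows = np.flatnonzero(bad)[:5].tolist()
                raise ValueError(
                    f"non-binary entries in binary column {s.name!r} (rows {rows})"
                )
            table[s.name] = table[s.name].astype(np.float64)

    return Population(X=table, y_weak=y_weak, specs=specs, seed=seed, y_strong=y_strong)
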