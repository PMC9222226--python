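"""Study configuration: nested dataclasses with YAML round-trip and profiles."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .population import PopulationConfig
from .reinforce import ReinforcementConfig
from .strategies import ForestParams

__all__ = [
    "LassoParams",
    "StudyConfig",
    "load_config",
    "save_config",
    "default_config",
    "desk_config",
    "compact_config",
]


@dataclass
class LassoParams:
    """Cross-validation settings shared by the preceding-study Lasso and the
    current-study comparator."""

    n_folds: int = 10
    n_lambdas: int = 15
    lambda_min_ratio: float | None = None


@dataclass
class StudyConfig:
    """Everything needed to run the simulation study end to end."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    reinforcement: ReinforcementConfig = field(default_factory=ReinforcementConfig)
    forest: ForestParams = field(default_factory=ForestParams)
    lasso: LassoParams = field(default_factory=LassoParams)
    sample_sizes: tuple[int, ...] = (4000, 2000, 1000, 500, 250)
    arms: tuple[str, ...] = ("weak", "strong")
    n_replications: int = 1000
    validation_size: int = 10_000
    alpha: float = 0.05
    clip: float = 1e-6
    base_seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")
        for arm in self.arms:
            if arm not in ("weak", "strong"):
                raise ValueError(f"unknown predictability arm {arm!r}")

    def feasible(self, n_pop: int) -> bool:
        """Three same-size training draws plus the validation set must fit
        disjointly inside the population."""
        return all(3 * n + self.validation_size <= n_pop for n in self.sample_sizes)


def _to_plain(obj):
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def save_config(config: StudyConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(asdict(config)), sort_keys=False))


def load_config(path: str | Path) -> StudyConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> StudyConfig:
    raw = dict(raw)
    pop = PopulationConfig(**_tupled(raw.pop("population", {}), "prevalence_quartiles"))
    reinf_raw = dict(raw.pop("reinforcement", {}))
    reinf_forest = ForestParams(**reinf_raw.pop("forest", {}))
    reinforcement = ReinforcementConfig(forest=reinf_forest, **reinf_raw)
    forest = ForestParams(**raw.pop("forest", {}))
    lasso = LassoParams(**raw.pop("lasso", {}))
    for key in ("sample_sizes", "arms"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return StudyConfig(
        population=pop, reinforcement=reinforcement, forest=forest, lasso=lasso, **raw
    )


def _tupled(d: dict, key: str) -> dict:
    d = dict(d)
    if key in d:
        d[key] = tuple(d[key])
    return d


def default_config(seed: int = 0) -> StudyConfig:
    """Full-scale study profile: 5 sample sizes x 2 arms, 1000 replications,
    validation sets of 10,000 drawn from a 200k population with ~1150 sparse
    binary predictors."""
    return StudyConfig(
        population=PopulationConfig(n_pop=200_000, p_binary=1150, seed=seed),
        reinforcement=ReinforcementConfig(seed=seed + 1),
        base_seed=seed,
    )


def desk_config(seed: int = 0, n_replications: int = 100) -> StudyConfig:
    """Scaled-down example profile for desk-scale execution: 20k population,
    400 binary predictors, validation 2000, 100 replications."""
    return StudyConfig(
        population=PopulationConfig(
            n_pop=20_000, p_binary=400, effect_scale=0.8, seed=seed
        ),
        reinforcement=ReinforcementConfig(
            seed=seed + 1, forest=ForestParams(n_trees=200)
        ),
        forest=ForestParams(n_trees=200),
        sample_sizes=(2000, 1000, 500, 250),
        n_replications=n_replications,
        validation_size=2000,
        base_seed=seed,
    )


def compact_config(
    seed: int = 0,
    n_replications: int = 200,
    sample_sizes: tuple[int, ...] = (250,),
    arms: tuple[str, ...] = ("weak", "strong"),
) -> StudyConfig:
    """Compact profile for single-CPU directional checks.

    12k population with 400 sparse binary predictors plus 2 numeric
    covariates, 100-tree forests, validation sets of 1000 and 200
    replications at n=250. The generator's effect scale is set so the weak
    outcome's achievable discrimination sits near AUROC 0.65, mirroring the
    weak-predictability level the study emulates.
    """
    return StudyConfig(
        population=PopulationConfig(
            n_pop=12_000, p_binary=400, effect_scale=0.8, seed=seed
        ),
        reinforcement=ReinforcementConfig(
            seed=seed + 1, forest=ForestParams(n_trees=100)
        ),
        forest=ForestParams(n_trees=100),
        lasso=LassoParams(n_lambdas=12),
        sample_sizes=tuple(sample_sizes),
        arms=tuple(arms),
        n_replications=n_replications,
        validation_size=1000,
        base_seed=seed,
    )
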