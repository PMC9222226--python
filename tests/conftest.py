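import numpy as np
import pandas as pd
import pytest

from plasmoderf import Population, PopulationConfig, VariableSpec, generate_population


def make_population(
    n_pop=2000,
    p_binary=40,
    p_numeric=2,
    seed=0,
    signal_fraction=0.1,
    effect_scale=1.0,
    prevalence_quartiles=(0.02, 0.08, 0.25),
):
    """Small, dense-ish population for fast unit tests."""
    return generate_population(
        PopulationConfig(
            n_pop=n_pop,
            p_binary=p_binary,
            p_numeric=p_numeric,
            prevalence_quartiles=prevalence_quartiles,
            signal_fraction=signal_fraction,
            effect_scale=effect_scale,
            seed=seed,
        )
    )


@pytest.fixture(scope="session")
def small_population():
    return make_population()


@pytest.fixture(scope="session")
def noise_population():
    return make_population(signal_fraction=0.0, seed=3)


def population_from_columns(columns: dict, y_weak, specs=None) -> Population:
    X = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()})
    if specs is None:
        specs = [
            VariableSpec(
                name,
                "binary",
                float(np.clip(X[name].mean(), 1e-9, 1 - 1e-9)),
            )
            for name in X.columns
        ]
    return Population(X=X, y_weak=np.asarray(y_weak), specs=specs)
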