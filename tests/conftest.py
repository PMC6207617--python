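import numpy as np
import pandas as pd
import pytest

from sociovar import ModelSpec, SimulationConfig, build_design, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic small cohort shared across read-only tests."""
    return simulate_cohort(SimulationConfig(n_individuals=40, seed=11))


@pytest.fixture(scope="session")
def base_spec():
    return ModelSpec()


def make_one_way(seed, n_groups=30, per_group=5, between=0.5, within=1.0):
    """Balanced one-way layout in the canonical observation schema."""
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), per_group)
    y = rng.normal(0.0, np.sqrt(between), n_groups)[g] + rng.normal(
        0.0, np.sqrt(within), len(g)
    )
    return pd.DataFrame(
        {
            "individual_id": g,
            "indicator": "a",
            "wave_year": np.tile(np.arange(per_group), n_groups),
            "age": 0.0,
            "gender": 0,
            "score_std": y,
        }
    )


def one_way_design(df):
    spec = ModelSpec(fixed_terms=("intercept",), random_terms=("individual",))
    return build_design(df, None, spec), spec
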