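"""Shared fixtures: toy tables and synthetic cohorts of graded size."""

import numpy as np
import pandas as pd
import pytest

from mbplsc import (
    MBPLSC,
    AnalysisConfig,
    SyntheticConfig,
    dataset_from_frame,
    generate_dataset,
)

TOY_SCHEMA = {
    "participant_id": "id",
    "group": "group",
    "age": "covariate",
    "gm_a": "gm",
    "gm_b": "gm",
    "gm_c": "gm",
    "wm_a": "wm",
    "wm_b": "wm",
    "cog_a": "cognition",
}


def toy_frame(n_per_group: int = 6, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    return pd.DataFrame(
        {
            "participant_id": [f"s{i:02d}" for i in range(n)],
            "group": ["HC"] * n_per_group + ["ROP"] * n_per_group,
            "age": rng.uniform(18, 30, n).round(1),
            "gm_a": rng.normal(2.5, 0.2, n),
            "gm_b": rng.normal(2.4, 0.2, n),
            "gm_c": rng.normal(2.6, 0.2, n),
            "wm_a": rng.uniform(0.3, 0.7, n),
            "wm_b": rng.uniform(0.3, 0.7, n),
            "cog_a": rng.normal(100, 15, n),
        }
    )


@pytest.fixture
def toy_df():
    return toy_frame()


@pytest.fixture
def toy_ds(toy_df):
    return dataset_from_frame(toy_df, TOY_SCHEMA)


@pytest.fixture(scope="session")
def small_planted():
    """Planted two-component cohort, small enough for resampling tests."""
    cfg = SyntheticConfig(
        n_per_group=40, p=12, q=8, seed=7, age_effect=0.0, cognition_link=(0.0, 0.0)
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_planted_results(small_planted):
    ds, _ = small_planted
    return MBPLSC(ds, AnalysisConfig(seed=7)).fit()


@pytest.fixture(scope="session")
def default_planted():
    """Study-scale shared+differential cohort (n=71/group, 68 GM, 48 WM)."""
    cfg = SyntheticConfig(seed=11, age_effect=0.0, cognition_link=(0.0, 0.0))
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_planted_results(default_planted):
    ds, _ = default_planted
    return MBPLSC(ds, AnalysisConfig(seed=11)).fit()
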