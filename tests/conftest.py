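"""Shared fixtures: synthetic cohorts reused across test modules.

The expensive Monte-Carlo inputs (planted-effect cohorts at the default
128 x 128 x 16 frame and null cohorts at a 48 x 48 x 16 desk-scale frame)
are generated once per session and shared by the property and acceptance
suites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wavetex import SimParams, extract_feature_table, generate_cohort

#: Frozen cohort seeds of the planted-effect suite (one per cohort).
PLANTED_COHORT_SEEDS = tuple(1000 * i for i in range(10))

N_NULL_COHORTS = 200


@pytest.fixture(scope="session")
def planted_tables() -> list[pd.DataFrame]:
    """Raw feature tables of 10 default (effect_scale=1) 39-sample cohorts."""
    tables = []
    for seed in PLANTED_COHORT_SEEDS:
        cohort = generate_cohort(seed=seed)
        tables.append(extract_feature_table(cohort))
    return tables


@pytest.fixture(scope="session")
def null_tables() -> list[pd.DataFrame]:
    """Raw feature tables of 200 null (effect_scale=0) 39-sample cohorts.

    Frames are 48 x 48 x 16 to keep the Monte-Carlo desk-scale; cohorts use
    disjoint per-sample seed ranges so they are independent.
    """
    params = SimParams(width=48, height=48, effect_scale=0.0)
    tables = []
    for i in range(N_NULL_COHORTS):
        cohort = generate_cohort(params=params, seed=100_000 + 39 * i)
        tables.append(extract_feature_table(cohort))
    return tables


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
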