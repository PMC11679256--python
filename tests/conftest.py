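"""Shared fixtures: synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from pdstages.classify import run_three_experiments
from pdstages.synthetic import CohortConfig, generate_feature_cohort, generate_phantom_cohort


@pytest.fixture(scope="session")
def small_phantom():
    """Six phantom subjects (2 per group) with study-condition effects."""
    return generate_phantom_cohort(CohortConfig(n_per_group=2, seed=11))


@pytest.fixture(scope="session")
def fast_cohort():
    """Full-size fast-mode cohort (56 per group) with study-condition effects."""
    table, truth = generate_feature_cohort(CohortConfig(seed=7))
    return table, truth


@pytest.fixture(scope="session")
def experiments(fast_cohort):
    """The three binary experiments run once on the fast cohort."""
    table, _ = fast_cohort
    return run_three_experiments(table, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
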