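"""Shared fixtures: small phantom cohorts generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from dosederm.cohort import CohortConfig, generate_cohort, sample_population
from dosederm.features import population_feature_table


@pytest.fixture(scope="session")
def small_cohort():
    """12-patient phantom cohort with full images (desk-scale grid)."""
    return generate_cohort(CohortConfig(n_patients=12, seed=7))


@pytest.fixture(scope="session")
def cohort148():
    """Default-size phantom cohort (148 patients, default betas)."""
    return generate_cohort(CohortConfig(n_patients=148, seed=11))


@pytest.fixture(scope="session")
def planted_population():
    """Covariate-level planted-signal cohort: (features, labels)."""
    records, dvh, labels, _ = sample_population(CohortConfig(), 148, seed=5)
    return population_feature_table(records, dvh), labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
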