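"""Shared fixtures.

The planted-complexity cohort (200 subjects whose groups differ only in
the spectral exponent of the gait-variability noise) is expensive to
build and evaluate, so it is generated once per session and shared by
the pipeline-level tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import gaitropy as g
from gaitropy import synthetic_data as sd

PLANTED_SEED = 42


@pytest.fixture(scope="session")
def planted_cohort():
    """Default-spec cohort, n=200: groups differ only in noise exponent."""
    spec = sd.CohortSpec(n_subjects=200, seed=PLANTED_SEED)
    records = sd.simulate_cohort(spec)
    features = g.extract_feature_table(
        {r.subject_id: r.recording for r in records})
    labels = g.label_table(sd.cohort_scores_table(records))
    return spec, records, features, labels


@pytest.fixture(scope="session")
def mse_comparison(planted_cohort):
    """With/without-MSE comparison on the planted cohort (TUG label)."""
    _, _, features, labels = planted_cohort
    config = g.CvConfig(seed=PLANTED_SEED, rf_n_trees=200)
    return g.compare_with_without_mse(
        features, labels["TUG"].to_numpy(), config, k_list=(15, 10, 5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
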