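"""Shared fixtures.

The expensive benchmark fixture (five full RBM trainings on the
standard synthetic cohort) is session-scoped so the recovery and
training-quality tests share one set of fitted models.
"""

from __future__ import annotations

import numpy as np
import pytest

from pharmphen.cdm_encoding import encode_matrix
from pharmphen.rbm_phenotyping import train_rbm
from pharmphen.synthetic_cohort import SyntheticSpec, generate_cohort

BENCHMARK_SEEDS = (0, 1, 2, 3, 4)


@pytest.fixture(scope="session")
def benchmark_runs():
    """Five standard cohorts (500 patients, 100 medications, 5 planted
    groups, 5 archetypes, 0.8 diagonal mixing, 5% noise) with fully
    trained RBMs, keyed by seed."""
    runs = {}
    for seed in BENCHMARK_SEEDS:
        cohort = generate_cohort(SyntheticSpec(seed=seed))
        matrix = encode_matrix(cohort.mar)
        model = train_rbm(matrix.X, seed=seed, feature_names=matrix.order_keys)
        runs[seed] = {"cohort": cohort, "matrix": matrix, "model": model}
    return runs


@pytest.fixture()
def small_cohort():
    """Quick cohort for plumbing tests: 60 patients, 12 medications,
    3 groups / 3 archetypes."""
    spec = SyntheticSpec(
        n_patients=60, n_medications=12, n_groups=3, n_archetypes=3,
        orders_per_patient_mean=8.0, noise_rate=0.05, seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
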