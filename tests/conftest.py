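"""Shared fixtures: scoring matrices and synthetic cohorts at test scale.

Session-scoped fixtures hold the expensive artifacts (preprocessed cohorts,
the planted-signal train/test split) so the model-recovery tests and the
acceptance suite reuse one pipeline run.
"""

from __future__ import annotations

import pytest

from oxytriage.datasets import split_patients
from oxytriage.preprocess import run_pipeline
from oxytriage.scoring import load_matrices
from oxytriage.synthetic import GeneratorConfig, degrade, generate_cohort


@pytest.fixture(scope="session")
def matrices():
    return load_matrices()


@pytest.fixture(scope="session")
def small_cohort(matrices):
    """A 12-patient naturalistic cohort with short admissions."""
    config = GeneratorConfig(
        seed=11,
        n_patients=12,
        admission_median_minutes=300.0,
        admission_min_minutes=60,
        admission_max_minutes=1500,
    )
    return generate_cohort(config, *matrices)


@pytest.fixture(scope="session")
def small_observations(small_cohort):
    return degrade(small_cohort)


@pytest.fixture(scope="session")
def small_processed(small_cohort, small_observations, matrices):
    """Model-ready minute table for the small cohort."""
    return run_pipeline(
        small_observations, small_cohort.demographics, *matrices, seed=3
    )


#: Fixed configuration of the planted-signal recovery experiment.
PLANTED_CONFIG = GeneratorConfig(
    seed=20240,
    n_patients=60,
    mode="planted_signal",
    admission_median_minutes=400.0,
    admission_min_minutes=120,
    admission_max_minutes=1200,
    obs_gap_mean_minutes=3.0,
    missing_rate=0.03,
)


@pytest.fixture(scope="session")
def planted_bundle(matrices):
    return generate_cohort(PLANTED_CONFIG, *matrices)


@pytest.fixture(scope="session")
def planted_frames(planted_bundle, matrices):
    """Preprocessed planted-signal cohort, split patient-wise 75/12.5/12.5."""
    obs = degrade(planted_bundle)
    table = run_pipeline(obs, planted_bundle.demographics, *matrices, seed=5)
    split = split_patients(sorted(table["patient_id"].unique()), seed=17)
    return {
        name: split.split_frame(table, name) for name in ("train", "val", "test")
    } | {"split": split, "table": table}
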