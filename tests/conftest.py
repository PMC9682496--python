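"""Shared fixtures.

The expensive session-scoped fixtures simulate one moderately sized
cohort with a strong pre-intubation prodrome and run the patient-wise
cross-validation once; the recovery tests all read from them.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from picurisk import (CohortConfig, generate_cohort, build_feature_table,
                      label_records, patient_folds, cross_validate)
from picurisk.pipeline import (FEATURE_COLUMNS_ALL,
                               FEATURE_COLUMNS_NO_MONITORING,
                               event_times_by_admission)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small cohort for structural/IO tests (fast)."""
    return generate_cohort(CohortConfig(n_admissions=10, event_rate=0.3,
                                        elective_rate=0.5, seed=7))


@pytest.fixture(scope="session")
def prodrome_cohort():
    """400-admission cohort with the default (strong, >= 2 SD) prodrome."""
    return generate_cohort(CohortConfig(n_admissions=400, seed=20))


@pytest.fixture(scope="session")
def prodrome_records(prodrome_cohort):
    features = build_feature_table(prodrome_cohort)
    return label_records(features, prodrome_cohort, mode="chart_review")


@pytest.fixture(scope="session")
def prodrome_event_times(prodrome_cohort):
    return event_times_by_admission(prodrome_cohort, "chart_review")


@pytest.fixture(scope="session")
def prodrome_folds(prodrome_records):
    return patient_folds(prodrome_records["admission_id"], k=5, seed=20)


@pytest.fixture(scope="session")
def cv_all(prodrome_records, prodrome_folds):
    """Out-of-fold predictions, all features."""
    return cross_validate(prodrome_records, FEATURE_COLUMNS_ALL,
                          prodrome_folds, seed=20)


@pytest.fixture(scope="session")
def cv_no_monitoring(prodrome_records, prodrome_folds):
    """Out-of-fold predictions without continuous-monitoring features."""
    return cross_validate(prodrome_records, FEATURE_COLUMNS_NO_MONITORING,
                          prodrome_folds, seed=20)
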