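"""Shared fixtures: compact synthetic studies and feature-table factories.

Problem sizes here are deliberately small (short trials, few subjects) so
the suite exercises every stage of the pipeline on realistic-statistics
inputs while staying fast.
"""

import numpy as np
import pandas as pd
import pytest

from gaitdecode.decode import FEATURE_COLUMNS
from gaitdecode.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_study():
    """Two-subject, single-medication-state cohort with one freeze trial."""
    cfg = CohortConfig(
        n_subjects=2, med_states=("Moff",),
        trials_per_status={"walking": 1, "dual_task": 1, "freezing": 1},
        sit_duration=16.0, stand_duration=16.0, gait_duration=14.0,
        freeze_trial_duration=20.0, freeze_intervals=((7.0, 12.0),))
    return simulate_cohort(cfg, seed=7)


def gaussian_feature_table(n_per_class: int = 50, n_classes: int = 5,
                           separation: float = 3.0, seed: int = 0,
                           n_informative: int = 32) -> pd.DataFrame:
    """Feature table with Gaussian class clouds.

    The first ``n_informative`` columns have class means ``separation`` SDs
    apart (unit SD); remaining columns are pure noise.  Labels reuse the five
    motor statuses.
    """
    rng = np.random.default_rng(seed)
    labels = ["sitting", "standing", "walking", "dual_task", "freeze"][:n_classes]
    rows = []
    for ci, lab in enumerate(labels):
        x = rng.normal(0.0, 1.0, size=(n_per_class, len(FEATURE_COLUMNS)))
        x[:, :n_informative] += ci * separation
        for r in x:
            rows.append({"label": lab, "subject": "subX", "med_state": "Moff",
                         "trial_id": f"t{ci}",
                         **dict(zip(FEATURE_COLUMNS, r))})
    return pd.DataFrame(rows)


@pytest.fixture
def feature_table_factory():
    return gaussian_feature_table
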