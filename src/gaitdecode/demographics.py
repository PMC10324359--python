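"""Reference cohort demographics and their summary statistics.

The packaged table describes the 18-subject Parkinson's cohort the analysis
design targets (age, disease duration, levodopa-equivalent dose, UPDRS III
motor scores off/on medication, rigidity and tremor sub-scores, freezing-of-
gait questionnaire, medication-state order).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_cohort_table", "summarize_cohort"]


def load_cohort_table() -> pd.DataFrame:
    """Load the packaged 18-row cohort demographics table."""
    with resources.files("gaitdecode.data").joinpath(
            "cohort_demographics.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def summarize_cohort(table: pd.DataFrame | None = None) -> dict:
    """Cohort means of the headline demographic/clinical variables."""
    t = table if table is not None else load_cohort_table()
    return {
        "n_subjects": int(len(t)),
        "mean_age_years": float(t["age"].mean()),
        "mean_disease_duration_years": float(t["dd_years"].mean()),
        "mean_updrs3_moff": float(t["updrs3_moff"].mean()),
        "mean_updrs3_mon": float(t["updrs3_mon"].mean()),
        "mean_ledd_mg": float(t["ledd_mg"].mean()),
    }
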