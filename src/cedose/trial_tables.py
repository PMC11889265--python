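"""Published per-cohort summary tables from the phase 1 CED rhenium-186
nanoliposome glioma trial that this pipeline models.

These printed summaries are *inputs*: the dose-escalation plan parameterizes
the synthetic cohort generator, and the adverse-event / response count tables
feed the event-level summarizers directly (the trial deposits no patient-level
imaging data, so voxel-level quantities are exercised on synthetic phantoms
instead).

Cohorts are numbered 1..6. All activities are mCi, volumes mL, ages years.
"""

from __future__ import annotations

import pandas as pd

COHORTS = (1, 2, 3, 4, 5, 6)

#: Dose escalation plan: infused volume (mL), administered activity (mCi),
#: number of patients enrolled per cohort.  Activity doubles from 1 mCi
#: (cohort 1) to 8 mCi (cohort 4), then rises ~67% in cohorts 5 and 6;
#: concentration is held at 1.5 mCi/mL through cohort 4 and 2.5 mCi/mL after.
COHORT_PLAN = pd.DataFrame(
    {
        "cohort": COHORTS,
        "infused_volume_mL": [0.66, 1.32, 2.64, 5.28, 5.28, 8.80],
        "administered_mCi": [1.0, 2.0, 4.0, 8.0, 13.4, 22.3],
        "n_patients": [3, 3, 3, 3, 3, 6],
    }
).set_index("cohort")

#: Age, mean +/- SD (min, max) per cohort, and cohort size.
COHORT_AGE_STATS = pd.DataFrame(
    {
        "cohort": COHORTS,
        "mean_y": [52.0, 60.0, 49.3, 53.0, 51.0, 53.2],
        "sd_y": [12.1, 10.1, 15.0, 15.1, 8.5, 7.0],
        "min_y": [39, 49, 35, 36, 42, 41],
        "max_y": [63, 69, 65, 65, 59, 60],
        "n": [3, 3, 3, 3, 3, 6],
    }
).set_index("cohort")

#: Baseline gross tumor volume, mean +/- SD (min, max) per cohort (mL).
COHORT_TUMOR_VOLUME_STATS = pd.DataFrame(
    {
        "cohort": COHORTS,
        "mean_mL": [1.8, 4.2, 13.0, 8.0, 11.7, 9.5],
        "sd_mL": [1.5, 3.7, 9.1, 6.5, 6.8, 10.1],
        "min_mL": [0.9, 2.0, 2.5, 2.4, 3.9, 1.0],
        "max_mL": [3.5, 8.5, 18.4, 15.1, 16.0, 22.8],
        "n": [3, 3, 3, 3, 3, 6],
    }
).set_index("cohort")

#: ECOG performance-status counts per cohort (columns: status 0/1/2).
COHORT_ECOG_COUNTS = pd.DataFrame(
    {
        "cohort": COHORTS,
        0: [1, 1, 3, 1, 3, 6],
        1: [1, 1, 0, 1, 0, 0],
        2: [1, 1, 0, 1, 0, 0],
    }
).set_index("cohort")

#: Event-level adverse-event counts by CTCAE grade per cohort (all events,
#: no per-patient deduplication).
AE_GRADE_COUNTS = pd.DataFrame(
    {
        "cohort": COHORTS,
        1: [21, 23, 22, 12, 12, 24],
        2: [4, 9, 4, 4, 3, 10],
        3: [0, 2, 0, 4, 2, 3],
    }
).set_index("cohort")

#: Event-level adverse-event counts by attribution category per cohort.
AE_RELATION_COUNTS = pd.DataFrame(
    {
        "cohort": COHORTS,
        "definite": [1, 0, 0, 0, 0, 0],
        "probable": [0, 0, 0, 0, 0, 1],
        "possible": [2, 0, 0, 3, 3, 12],
        "unlikely": [3, 0, 1, 3, 7, 14],
        "unrelated": [19, 34, 25, 14, 7, 10],
    }
).set_index("cohort")

#: Best radiological response (RANO category) counts per cohort.
BEST_RESPONSE_COUNTS = pd.DataFrame(
    {
        "cohort": COHORTS,
        "CR": [0, 0, 0, 0, 0, 0],
        "PR": [0, 0, 0, 0, 0, 1],
        "SD": [2, 1, 1, 3, 2, 3],
        "PD": [1, 2, 2, 0, 1, 2],
    }
).set_index("cohort")


def cohort_concentration_mCi_per_mL(round_decimals: int | None = 1) -> pd.Series:
    """Administered activity / infused volume per cohort.

    The escalation plan reports concentration to one decimal; pass
    ``round_decimals=None`` for the unrounded ratio.
    """
    conc = COHORT_PLAN["administered_mCi"] / COHORT_PLAN["infused_volume_mL"]
    if round_decimals is not None:
        conc = conc.round(round_decimals)
    return conc.rename("concentration_mCi_per_mL")
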