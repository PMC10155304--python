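"""Worked-example demographic table.

Per-cluster summary cells for a published-style cohort of 991
critically ill adults split into five patient clusters, in the layout
:func:`pharmphen.outcome_stats.pooled_summary` consumes.  The cells are
the kind a demographic "Table 1" prints — cluster sizes, mean severity
scores and support durations, and event counts with their non-missing
denominators — and serve as the arithmetic check that pooling
per-cluster cells reproduces the whole-cohort column.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["icu_demographics_example", "ICU_EXAMPLE_POOLED"]


def icu_demographics_example() -> pd.DataFrame:
    """Per-cluster demographic cells for a 991-patient ICU cohort."""
    return pd.DataFrame(
        {
            "cluster": [1, 2, 3, 4, 5],
            "n": [304, 191, 229, 144, 123],
            "age_mean": [59.7, 63.2, 61.4, 61.1, 61.9],
            "apache_ii_mean": [13.5, 15.7, 14.6, 13.3, 14.7],
            "mrc_icu_mean": [9.4, 11.6, 10.0, 10.1, 11.2],
            "vasopressor_days_mean": [2.1, 1.4, 1.5, 2.1, 1.2],
            "mortality_count": [30, 11, 27, 19, 10],
            "female_count": [136, 80, 96, 69, 47],
            "medical_icu_count": [111, 70, 104, 54, 65],
            "mech_vent_count": [91, 83, 60, 37, 41],
            "aki_count": [52, 22, 40, 26, 14],
            "aki_denom": [303, 191, 229, 144, 122],
        }
    )


# Whole-cohort column the pooled cells should reproduce (one-decimal
# reporting convention).
ICU_EXAMPLE_POOLED = {
    "n": 991.0,
    "age_mean": 61.2,
    "apache_ii_mean": 14.3,
    "mrc_icu_mean": 10.3,
    "vasopressor_days_mean": 1.7,
    "mortality_count": 97.0,
    "mortality_pct": 9.8,
    "female_pct": 43.2,
    "medical_icu_pct": 40.8,
    "mech_vent_pct": 31.5,
    "aki_count": 154.0,
    "aki_pct": 15.6,
}
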