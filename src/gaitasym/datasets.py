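"""Bundled example data.

``pd_cohort_summaries`` carries published-style demographic and clinical
summary statistics (n, mean, SD per group) for a male Parkinson's disease
gait cohort: 29 PD subjects vs 13 age-matched controls, the PD cohort split
into postural-instability/gait-difficulty (PIGD, n=12) vs tremor-dominant
(TD, n=15) subtypes, and into clinically asymmetric (n=9) vs symmetric
(n=20) gait groups.  Weight was unavailable for one PD and one control
subject and height for one PD subject; the ns below are the effective ones.
These summaries are inputs for Welch-t group comparisons.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # analysis, variable, group1, n1, mean1, sd1, group2, n2, mean2, sd2
    ("pd_vs_control", "age_years", "PD", 29, 65.8, 5.9, "control", 13, 62.2, 8.4),
    ("pd_vs_control", "height_in", "PD", 28, 69.4, 2.1, "control", 13, 69.9, 2.4),
    ("pd_vs_control", "weight_kg", "PD", 28, 83.7, 12.6, "control", 12, 88.4, 7.3),
    ("pd_vs_control", "moca", "PD", 29, 26.2, 2.8, "control", 13, 27.6, 1.9),
    ("pd_vs_control", "avg_speed_ms", "PD", 29, 0.91, 0.20, "control", 13, 0.96, 0.17),
    ("pigd_vs_td", "age_years", "PIGD", 12, 65.8, 5.1, "TD", 15, 65.0, 6.6),
    ("pigd_vs_td", "height_in", "PIGD", 12, 69.2, 1.9, "TD", 15, 69.5, 2.3),
    ("pigd_vs_td", "weight_kg", "PIGD", 12, 81.7, 8.3, "TD", 15, 84.7, 15.8),
    ("pigd_vs_td", "moca", "PIGD", 12, 25.1, 3.2, "TD", 15, 26.9, 2.2),
    ("pigd_vs_td", "disease_duration_years", "PIGD", 12, 9.7, 5.1, "TD", 15, 7.7, 3.4),
    ("pigd_vs_td", "mds_updrs_iii", "PIGD", 12, 30.8, 8.4, "TD", 15, 30.1, 8.9),
    ("pigd_vs_td", "ldopa_equiv_mg", "PIGD", 12, 999.0, 549.0, "TD", 15, 479.0, 358.0),
    ("pigd_vs_td", "hoehn_yahr", "PIGD", 12, 2.5, 0.4, "TD", 15, 2.0, 0.4),
    ("pigd_vs_td", "avg_speed_ms", "PIGD", 12, 0.88, 0.14, "TD", 15, 0.95, 0.24),
    ("asym_vs_symm", "age_years", "asym", 9, 67.6, 3.9, "symm", 20, 65.0, 6.6),
    ("asym_vs_symm", "height_in", "asym", 9, 68.8, 1.9, "symm", 20, 69.7, 2.1),
    ("asym_vs_symm", "weight_kg", "asym", 9, 87.0, 11.8, "symm", 20, 82.2, 13.0),
    ("asym_vs_symm", "moca", "asym", 9, 26.4, 2.9, "symm", 20, 26.2, 2.8),
    ("asym_vs_symm", "disease_duration_years", "asym", 9, 8.1, 4.6, "symm", 20, 8.1, 4.5),
    ("asym_vs_symm", "mds_updrs_iii", "asym", 9, 33.6, 5.4, "symm", 20, 29.1, 9.0),
    ("asym_vs_symm", "ldopa_equiv_mg", "asym", 9, 502.0, 575.0, "symm", 20, 733.0, 507.0),
    ("asym_vs_symm", "hoehn_yahr", "asym", 9, 2.3, 0.5, "symm", 20, 2.1, 0.5),
    ("asym_vs_symm", "avg_speed_ms", "asym", 9, 0.95, 0.23, "symm", 20, 0.89, 0.19),
]

_COLUMNS = [
    "analysis", "variable",
    "group1", "n1", "mean1", "sd1",
    "group2", "n2", "mean2", "sd2",
]


def pd_cohort_summaries() -> pd.DataFrame:
    """Clinical summary statistics for the example PD cohort (tidy table)."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)
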