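"""Reference tabulations from the original Danish IHD registry analysis.

The registry data behind the original 72,249-patient analysis are
access-restricted, but its printed summary tables are self-contained inputs:
the cluster-level table (sizes, mean ages, sex counts, hazard ratios and
Holm-adjusted p-values for the three outcomes over the 31 clusters of
>500 patients) and the cohort demographics counts.  They are transcribed
here so the tally arithmetic (significant-cluster counts, member totals,
demographic percentages) can be recomputed and checked, and to serve as a
realistic worked input for :func:`morbnet.survival.significance_table`.

Values are transcribed as printed, including the table's own internal
inconsistencies (e.g. a handful of rows where males + females differs
slightly from the size column; the size column is authoritative).
An adjusted p-value printed as "0" means below the table's precision.
"""

from __future__ import annotations

import pandas as pd

from .cohort import pct

#: Cohort-level demographic counts (Table of cohort demographics).
COHORT_COUNTS = {
    "n_patients": 72_249,
    "n_males": 45_576,
    "n_females": 26_673,
    "n_with_comorbidity": 68_103,
    "n_hypertension_I109": 24_818,
    "n_angina_I20": 38_239,
    "n_unclustered_singletons": 4_365,  # patients outside the 36 raw clusters
    "n_outside_31_clusters": 5_113,  # singletons plus members of clusters <500
    "n_new_ischemic_events": 14_679,
    "n_all_cause_deaths": 13_247,
    "n_non_ihd_deaths": 10_684,
}

# (cluster, size, mean_age, age_sd, males, females,
#  hr_isch, p_isch, hr_nonihd, p_nonihd, hr_allcause, p_allcause)
_TABLE2_ROWS = [
    ("C1", 7191, 64.8, 11.3, 3897, 3294, 1.000, 1.0, 0.856, 0.103, 0.863, 2.74e-4),
    ("C2", 5990, 58.6, 11.5, 2862, 3127, 0.825, 7.24e-5, 0.600, 1.73e-10, 0.645, 0.0),
    ("C3", 4641, 56.8, 11.4, 2727, 1914, 0.757, 3.25e-8, 0.586, 2.04e-8, 0.653, 2.07e-14),
    ("C4", 4401, 69.6, 10.2, 2853, 1548, 0.920, 1.0, 1.461, 0.0, 1.403, 0.0),
    ("C5", 4290, 63.9, 10.7, 2803, 1487, 1.402, 0.0, 1.629, 0.0, 1.571, 0.0),
    ("C6", 3589, 59.7, 10.9, 2388, 1201, 0.969, 1.0, 0.675, 2.14e-4, 0.732, 1.67e-7),
    ("C7", 3309, 63.8, 11.0, 2025, 1284, 0.889, 1.0, 0.611, 1.53e-7, 0.690, 5.52e-11),
    ("C8", 2802, 71.1, 10.9, 1867, 935, 0.943, 1.0, 0.842, 0.551, 0.866, 0.051),
    ("C9", 2581, 63.7, 11.8, 1803, 778, 1.314, 1.34e-7, 1.789, 0.0, 2.010, 0.0),
    ("C10", 2562, 74.2, 9.6, 1225, 1337, 0.978, 1.0, 0.928, 1.0, 0.986, 1.0),
    ("C11", 2292, 66.1, 11.0, 2186, 106, 0.926, 1.0, 0.650, 4.89e-5, 0.716, 8.04e-8),
    ("C12", 2213, 70.3, 10.2, 2068, 145, 0.920, 1.0, 0.805, 0.241, 0.815, 1.57e-3),
    ("C13", 2070, 58.6, 10.2, 1348, 722, 0.946, 1.0, 0.577, 1.21e-3, 0.599, 3.40e-8),
    ("C14", 2070, 68.2, 9.6, 1030, 1010, 1.146, 1.0, 3.390, 0.0, 2.566, 0.0),
    ("C15", 2040, 63.9, 10.1, 1208, 805, 1.031, 1.0, 0.784, 0.877, 0.745, 3.11e-4),
    ("C16", 1654, 64.1, 12.1, 1013, 641, 1.107, 1.0, 1.761, 1.86e-13, 1.483, 2.54e-12),
    ("C17", 1281, 65.3, 9.9, 714, 567, 1.001, 1.0, 1.761, 0.299, 0.735, 7.24e-3),
    ("C18", 1251, 68.2, 9.8, 802, 449, 1.790, 0.0, 3.421, 0.0, 2.129, 0.0),
    ("C19", 1168, 58.5, 9.7, 995, 173, 0.752, 0.085, 1.571, 0.146, 0.616, 8.42e-4),
    ("C20", 1119, 71.5, 11.3, 713, 406, 1.213, 0.421, 1.782, 1.45e-13, 1.576, 0.0),
    ("C21", 1000, 61.0, 11.0, 769, 231, 1.116, 1.0, 0.890, 1.0, 0.806, 1.0),
    ("C22", 988, 69.2, 10.4, 516, 472, 1.023, 1.0, 0.978, 1.0, 0.977, 1.0),
    ("C23", 935, 58.7, 12.2, 588, 347, 1.609, 7.59e-10, 2.275, 0.0, 1.951, 0.0),
    ("C24", 932, 67.9, 10.1, 28, 904, 0.787, 1.0, 1.589, 1.22e-4, 1.256, 0.146),
    ("C25", 860, 56.2, 9.9, 664, 196, 0.978, 1.0, 2.691, 0.0, 2.461, 0.0),
    ("C26", 852, 58.7, 12.1, 391, 461, 0.939, 1.0, 1.108, 1.0, 0.943, 1.0),
    ("C27", 823, 65.1, 10.9, 532, 291, 1.201, 1.0, 1.289, 1.0, 1.430, 4.48e-5),
    ("C28", 686, 71.7, 8.0, 673, 13, 0.866, 1.0, 1.786, 1.48e-8, 1.345, 3.63e-3),
    ("C29", 550, 57.2, 11.1, 435, 115, 0.906, 1.0, 0.985, 1.0, 0.986, 1.0),
    ("C30", 533, 61.2, 11.7, 391, 172, 1.874, 1.22e-10, 5.364, 0.0, 3.951, 0.0),
    ("C31", 520, 64.4, 11.2, 213, 307, 1.052, 1.0, 1.484, 0.370, 1.356, 0.130),
]


def cluster_table() -> pd.DataFrame:
    """The 31-cluster summary table in wide form, one row per cluster."""
    return pd.DataFrame(
        _TABLE2_ROWS,
        columns=[
            "cluster_label", "n_members", "mean_age", "age_sd", "males", "females",
            "hr_new_ischemic", "p_adj_new_ischemic",
            "hr_non_ihd_death", "p_adj_non_ihd_death",
            "hr_all_cause", "p_adj_all_cause",
        ],
    )


def cluster_cox_long() -> pd.DataFrame:
    """The cluster table reshaped to the tidy (cluster, outcome) form
    consumed by :func:`morbnet.survival.significance_table`."""
    wide = cluster_table()
    frames = []
    for outcome in ("new_ischemic", "non_ihd_death", "all_cause"):
        frames.append(
            pd.DataFrame(
                {
                    "cluster_label": wide["cluster_label"],
                    "outcome": outcome,
                    "n_members": wide["n_members"],
                    "hr": wide[f"hr_{outcome}"],
                    "p_adjusted": wide[f"p_adj_{outcome}"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def demographic_percentages() -> dict:
    """Recompute the printed demographic percentages from the raw counts."""
    c = COHORT_COUNTS
    n = c["n_patients"]
    return {
        "pct_male": pct(c["n_males"], n),
        "pct_with_comorbidity": pct(c["n_with_comorbidity"], n),
        "pct_hypertension": pct(c["n_hypertension_I109"], n),
        "pct_angina": pct(c["n_angina_I20"], n),
        "pct_unclustered": pct(c["n_unclustered_singletons"], n),
    }
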