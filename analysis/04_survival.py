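"""Cause-specific Cox characterization of the recovered clusters.

Derives the composite endpoints from the synthetic outcome table, fits
member-vs-rest Cox models (sex + 3-knot restricted cubic age spline) per
cluster and outcome, Holm-adjusts within each outcome family, and tallies
significant clusters.  Also runs a compact hazard-ratio recovery experiment
(true HR 2.0, 10 replicates) as a calibration readout.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from morbnet.experiments import cox_recovery_replicates
from morbnet.mcl import Clustering
from morbnet.survival import (
    EndpointRules,
    derive_composite_event,
    fit_cluster_cox,
    significance_table,
    tukey_age_comparisons,
)

DATA = Path("results/data")
OUT = Path("results")


def main(seed: int = 1) -> None:
    patients = pd.read_csv(DATA / "patients.tsv", sep="\t")
    events = pd.read_csv(DATA / "events.tsv", sep="\t")
    clusters = pd.read_csv(OUT / "clusters.tsv", sep="\t")
    index_days = patients.set_index("patient_id")["index_day"]

    labels, uniq = pd.factorize(clusters["cluster"])
    labels = np.where(clusters["cluster"].to_numpy() == "unclustered", -1, labels)
    clustering = Clustering(clusters["patient_id"].to_numpy(), labels, labels=list(uniq))

    records = derive_composite_event(events, index_days, EndpointRules())
    cov = patients.set_index("patient_id")[["sex", "age_at_index"]].rename(
        columns={"age_at_index": "age"})
    frames = [
        fit_cluster_cox(records, clustering, cov, outcome=o)
        for o in ("new_ischemic", "non_ihd_death", "all_cause")
    ]
    cox = pd.concat(frames, ignore_index=True)
    cox.to_csv(OUT / "cox_results.tsv", sep="\t", index=False)
    print("per-cluster member-vs-rest Cox models:")
    print(cox[["cluster_label", "outcome", "n_events", "hr", "p_adjusted"]]
          .round(3).to_string(index=False))
    print("\nsignificance tallies (the synthetic cohort has no planted hazard "
          "differences, so none are expected):")
    print(significance_table(cox).to_string(index=False))

    clustered = clustering.assignment >= 0
    ages = cov.loc[clustering.node_ids[clustered], "age"].to_numpy()
    tk = tukey_age_comparisons(ages, clustering.assignment[clustered])
    tk.to_csv(OUT / "age_comparisons.tsv", sep="\t", index=False)
    print(f"\npairwise age contrasts: {len(tk)} tests, "
          f"{int(tk['significant'].sum())} significant after Holm")

    rec = cox_recovery_replicates(seed=seed, n_replicates=10)
    print(f"\nHR-recovery calibration (true cause-specific HR 2.0, "
          f"n=2000/arm, 10 replicates): mean HR {rec['hr'].mean():.3f}, "
          f"CI coverage {int(rec['covered'].sum())}/10")


if __name__ == "__main__":
    main()
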