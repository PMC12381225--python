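"""Cluster characterization: O/E enrichment, polypharmacy, lab scores, traits.

Observed/expected (O/E) ratios contrast the carrier prevalence of each
diagnosis code inside a cluster with its cohort-wide prevalence; O/E > 2
marks enrichment, 0 < O/E < 1 an inverse change, and a cluster whose ten
largest O/E values sum to less than 50 is flagged as showing little
enrichment.  Laboratory results are summarized per cluster as the mean of a
below/within/above classification (-1/0/1) against the reference interval.
Standardized trait scores (polygenic-score stand-ins) are compared per
cluster against all other clustered patients with two-sided Wilcoxon
rank-sum tests, a Hodges-Lehmann location-shift effect size, and
Benjamini-Hochberg FDR across all cluster x trait tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .cohort import CountMatrix
from .mcl import Clustering

log = logging.getLogger(__name__)

ENRICHED_OE = 2.0
LITTLE_ENRICHMENT_TOP10_SUM = 50.0


def oe_ratios(m: CountMatrix, clustering: Clustering) -> pd.DataFrame:
    """Observed/expected carrier-frequency ratios per (cluster, code).

    Frequency = fraction of patients carrying (>= 1 assignment of) the code.
    Codes with zero cohort frequency are excluded.  Adds ``enriched``
    (oe > 2) and ``inverse`` (0 < oe < 1) flags.
    """
    carriers = m.carriers()
    n = m.shape[0]
    cohort_freq = np.asarray(carriers.sum(axis=0)).ravel() / n
    keep = cohort_freq > 0
    rows = []
    for k in range(clustering.n_clusters):
        members = clustering.assignment == k
        size = int(members.sum())
        label = clustering.labels[k]
        if size == 0:
            log.warning("cluster %s is empty; skipped", label)
            continue
        clu_freq = np.asarray(carriers[members].sum(axis=0)).ravel() / size
        oe = np.divide(clu_freq, cohort_freq, out=np.zeros_like(clu_freq), where=keep)
        for j in np.nonzero(keep)[0]:
            rows.append((label, m.code_labels[j], clu_freq[j], cohort_freq[j], oe[j]))
    out = pd.DataFrame(
        rows, columns=["cluster", "code", "observed_freq", "expected_freq", "oe"]
    )
    out["enriched"] = out["oe"] > ENRICHED_OE
    out["inverse"] = (out["oe"] > 0) & (out["oe"] < 1)
    return out


def little_enrichment_flags(oe_table: pd.DataFrame) -> pd.Series:
    """Per-cluster flag: sum of the ten largest O/E ratios < 50."""
    return (
        oe_table.groupby("cluster")["oe"]
        .apply(lambda s: s.nlargest(10).sum() < LITTLE_ENRICHMENT_TOP10_SUM)
        .rename("little_enrichment")
    )


def polypharmacy_flags(
    prescriptions: pd.DataFrame,
    index_days: pd.Series,
    min_distinct: int = 5,
    min_redemptions: int = 2,
    window_days: int = 365,
) -> pd.Series:
    """Polypharmacy: more than ``min_distinct`` distinct codes, each redeemed
    at least ``min_redemptions`` times within 1 year pre-index (strictly more
    than five distinct, per the definition)."""
    rx = prescriptions[prescriptions["patient_id"].isin(index_days.index)].copy()
    idx = rx["patient_id"].map(index_days)
    in_window = (rx["redeem_day"] >= idx - window_days) & (rx["redeem_day"] < idx)
    rx = rx[in_window]
    per_code = rx.groupby(["patient_id", "atc_code"]).size()
    recurrent = per_code[per_code >= min_redemptions]
    n_recurrent = recurrent.groupby("patient_id").size()
    flags = pd.Series(False, index=index_days.index, name="polypharmacy")
    flagged = n_recurrent[n_recurrent > min_distinct].index
    flags.loc[flags.index.intersection(flagged)] = True
    return flags


def polypharmacy_fractions(flags: pd.Series, clustering: Clustering) -> pd.Series:
    """Per-cluster fraction of polypharmacy patients."""
    out = {}
    for k in range(clustering.n_clusters):
        members = pd.Index(clustering.members(k))
        out[clustering.labels[k]] = float(flags.reindex(members).fillna(False).mean())
    return pd.Series(out, name="polypharmacy_fraction")


def lab_subcohort(
    labs: pd.DataFrame,
    index_days: pd.Series,
    window_days: int = 90,
    completeness_analytes: tuple = ("sodium", "potassium", "hemoglobin", "creatinine"),
    min_availability: float = 0.5,
):
    """Completeness-filtered lab subcohort and closest-to-index results.

    A patient is eligible iff all four completeness analytes were sampled in
    ``[index - 90 d, index]``.  Per (patient, test) the result closest to the
    index is selected (ties: latest sample, then first record).  Tests
    available for fewer than ``min_availability`` of eligible patients are
    dropped.  Returns ``(eligible_patient_ids, selected_results)``.
    """
    lab = labs[labs["patient_id"].isin(index_days.index)].copy()
    idx = lab["patient_id"].map(index_days)
    lab["days_before"] = idx - lab["sample_day"]
    lab = lab[(lab["days_before"] >= 0) & (lab["days_before"] <= window_days)]

    have = lab.groupby("patient_id")["test_code"].agg(set)
    required = set(completeness_analytes)
    eligible = have[have.map(lambda s: required <= s)].index
    lab = lab[lab["patient_id"].isin(eligible)]
    if len(eligible) == 0:
        return pd.Index([]), lab.iloc[0:0]

    lab = lab.sort_values(
        ["patient_id", "test_code", "days_before", "sample_day"],
        ascending=[True, True, True, False],
        kind="stable",
    )
    selected = lab.groupby(["patient_id", "test_code"], sort=False).head(1)

    avail = selected.groupby("test_code")["patient_id"].nunique() / len(eligible)
    kept_tests = avail[avail >= min_availability].index
    dropped = set(avail.index) - set(kept_tests)
    if dropped:
        log.info("dropped tests below %.0f%% availability: %s", 100 * min_availability, sorted(dropped))
    selected = selected[selected["test_code"].isin(kept_tests)]
    return pd.Index(eligible), selected.reset_index(drop=True)


def classify_vs_reference(values, ref_low, ref_high) -> np.ndarray:
    """-1 below, 0 within (inclusive bounds), +1 above the reference interval."""
    v = np.asarray(values, dtype=float)
    lo = np.asarray(ref_low, dtype=float)
    hi = np.asarray(ref_high, dtype=float)
    return np.where(v < lo, -1, np.where(v > hi, 1, 0))


@dataclass
class LabScoreMatrix:
    scores: pd.DataFrame  # clusters x tests, values in [-1, 1]
    n_contributing: pd.DataFrame  # clusters x tests patient counts
    cluster_order: list  # hierarchical-clustering leaf order


def lab_scores(selected: pd.DataFrame, clustering: Clustering) -> LabScoreMatrix:
    """Per-cluster mean of the -1/0/1 classification, with hierarchical
    ordering of clusters (complete linkage on Euclidean distance)."""
    sel = selected.copy()
    sel["class"] = classify_vs_reference(sel["value"], sel["ref_low"], sel["ref_high"])
    member_of = pd.Series(
        [clustering.labels[a] if a >= 0 else None for a in clustering.assignment],
        index=pd.Index(clustering.node_ids),
    )
    sel["cluster"] = sel["patient_id"].map(member_of)
    sel = sel[sel["cluster"].notna()]
    scores = sel.pivot_table(index="cluster", columns="test_code", values="class", aggfunc="mean")
    counts = sel.pivot_table(
        index="cluster", columns="test_code", values="class", aggfunc="count"
    ).fillna(0).astype(int)
    order = list(scores.index)
    if len(scores) > 2:
        z = linkage(scores.fillna(0.0).to_numpy(), method="complete", metric="euclidean")
        order = [scores.index[i] for i in leaves_list(z)]
    return LabScoreMatrix(scores=scores, n_contributing=counts, cluster_order=order)


def hodges_lehmann_shift(x: np.ndarray, y: np.ndarray, max_pairs: int = 5_000_000) -> float:
    """Median of pairwise differences x_i - y_j (location-shift estimate).

    Computed exactly when |x|*|y| <= max_pairs, otherwise on an evenly
    strided subsample of pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) * len(y) > max_pairs:
        step = int(np.ceil((len(x) * len(y) / max_pairs) ** 0.5))
        x = x[:: max(1, step)]
        y = y[:: max(1, step)]
    return float(np.median((x[:, None] - y[None, :]).ravel()))


def trait_tests(
    traits: pd.DataFrame, clustering: Clustering, min_cluster_size: int = 2
) -> pd.DataFrame:
    """Per (cluster, trait) Wilcoxon rank-sum tests, members vs all other
    clustered patients, with Hodges-Lehmann effect sizes and BH-FDR across
    all cluster x trait tests.  Unclustered patients are excluded."""
    member_of = pd.Series(clustering.assignment, index=pd.Index(clustering.node_ids))
    tr = traits[traits["patient_id"].isin(member_of.index)].copy()
    tr["cluster_idx"] = tr["patient_id"].map(member_of)
    tr = tr[tr["cluster_idx"] >= 0]
    rows = []
    for trait, tgrp in tr.groupby("trait", sort=False):
        scores = tgrp["score"].to_numpy()
        cl = tgrp["cluster_idx"].to_numpy()
        for k in range(clustering.n_clusters):
            x = scores[cl == k]
            y = scores[cl != k]
            if len(x) < min_cluster_size:
                log.warning("cluster %s too small for trait test; skipped", clustering.labels[k])
                continue
            stat, p = mannwhitneyu(x, y, alternative="two-sided")
            rows.append(
                (clustering.labels[k], trait, hodges_lehmann_shift(x, y), float(p))
            )
    out = pd.DataFrame(rows, columns=["cluster", "trait", "effect_size", "p_raw"])
    if len(out):
        out["fdr"] = multipletests(out["p_raw"].to_numpy(), method="fdr_bh")[1]
        out["significant"] = out["fdr"] < 0.05
    return out
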