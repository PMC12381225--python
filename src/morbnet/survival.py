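"""Composite endpoints and cause-specific Cox characterization of clusters.

Three outcomes are analyzed: a composite "new ischemic event" (MI/unstable
angina hospitalization at least 30 days post-index, revascularization at
least 90 days post-index — earlier ones reflect the planned work-up of the
index disease — or any death with an IHD cause), death from non-IHD causes,
and all-cause mortality.  Competing risks are handled as cause-specific
hazards (the competing event censors); follow-up is truncated at 5 years.
Each cluster is contrasted against all non-members with a Cox model adjusted
for sex and a 3-knot restricted cubic spline of age at index; p-values are
Holm-adjusted across clusters per outcome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .cohort import IHD_PREFIXES, truncate_code

log = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
OUTCOMES = ("new_ischemic", "non_ihd_death", "all_cause")


@dataclass
class EndpointRules:
    mi_uap_min_days: int = 30
    revasc_min_days: int = 90
    ihd_death_any_time: bool = True
    max_followup_years: float = 5.0
    #: cause-specific convention for the non-IHD-death analysis: whether a
    #: composite ischemic event censors it (config-switchable)
    ischemic_censors_non_ihd: bool = True

    def __post_init__(self):
        if self.mi_uap_min_days < 0 or self.revasc_min_days < 0:
            raise ValueError("minimum-day rules must be >= 0")


def _is_ihd_cause(primary, secondary) -> np.ndarray:
    def match(col):
        return (
            pd.Series(col, dtype=object)
            .fillna("")
            .map(truncate_code)
            .str.startswith(IHD_PREFIXES)
        )

    return (match(primary) | match(secondary)).to_numpy()


def derive_composite_event(
    events: pd.DataFrame,
    index_days: pd.Series,
    rules: EndpointRules | None = None,
    followup_end_day: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-patient survival records for the three outcomes.

    Returns a frame indexed by patient_id with, per outcome, ``time_*`` (days
    from index, truncated) and ``event_*`` (0/1) columns.  Records dated on or
    before the index are rejected with a logged count.
    """
    rules = rules or EndpointRules()
    ev = events.copy()
    ev = ev[ev["patient_id"].isin(index_days.index)]
    idx = ev["patient_id"].map(index_days)
    bad = ev["event_day"] <= idx
    if bad.any():
        log.warning("rejected %d event records dated on/before index", int(bad.sum()))
        ev = ev[~bad]
        idx = idx[~bad]
    ev["days"] = ev["event_day"] - idx

    is_death = (ev["event_type"] == "death").to_numpy()
    ihd_cause = _is_ihd_cause(ev.get("cause_primary"), ev.get("cause_secondary"))

    isch_mask = (
        ((ev["event_type"] == "mi_uap_hosp") & (ev["days"] >= rules.mi_uap_min_days))
        | ((ev["event_type"] == "revascularization") & (ev["days"] >= rules.revasc_min_days))
        | (is_death & ihd_cause)
    )
    t_isch = ev.loc[isch_mask].groupby("patient_id")["days"].min()
    t_death_any = ev.loc[is_death].groupby("patient_id")["days"].min()
    t_death_non_ihd = ev.loc[is_death & ~ihd_cause].groupby("patient_id")["days"].min()

    pid = index_days.index
    max_t = rules.max_followup_years * DAYS_PER_YEAR
    if followup_end_day is not None:
        admin = (followup_end_day.reindex(pid) - index_days).clip(upper=max_t)
    else:
        admin = pd.Series(max_t, index=pid)
    admin = admin.astype(float)

    def cause_specific(t_event: pd.Series, t_censor_events: list[pd.Series]):
        te = t_event.reindex(pid)
        censor = admin.copy()
        for tc in t_censor_events:
            censor = pd.concat([censor, tc.reindex(pid)], axis=1).min(axis=1)
        event = te.notna() & (te <= censor) & (te <= max_t)
        time = np.where(event, te, np.minimum(censor, max_t))
        return pd.Series(time, index=pid), event.astype(int)

    out = pd.DataFrame(index=pid)
    out.index.name = "patient_id"
    t, e = cause_specific(t_isch, [t_death_non_ihd])
    out["time_new_ischemic"], out["event_new_ischemic"] = t, e
    censors = [t_isch] if rules.ischemic_censors_non_ihd else []
    t, e = cause_specific(t_death_non_ihd, censors)
    out["time_non_ihd_death"], out["event_non_ihd_death"] = t, e
    t, e = cause_specific(t_death_any, [])
    out["time_all_cause"], out["event_all_cause"] = t, e
    # guard: times strictly positive
    for c in out.columns:
        if c.startswith("time_"):
            out[c] = out[c].clip(lower=0.5)
    return out


def rcs_basis(x: np.ndarray, knots: np.ndarray | None = None, n_knots: int = 3) -> np.ndarray:
    """Restricted cubic spline basis (natural spline, linear in the tails).

    For k knots the basis has k-1 columns: the linear term plus k-2
    truncated-cubic terms.  Default knots at the 10th/50th/90th percentiles.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        qs = np.linspace(10, 90, n_knots)
        knots = np.percentile(x, qs)
    knots = np.sort(np.asarray(knots, dtype=float))
    k = len(knots)
    if k < 3:
        raise ValueError("restricted cubic spline needs >= 3 knots")
    out = np.empty((len(x), k - 1))
    out[:, 0] = x
    denom = knots[-1] - knots[0]

    def cub(u):
        return np.maximum(u, 0.0) ** 3

    for j in range(k - 2):
        out[:, j + 1] = (
            cub(x - knots[j])
            - cub(x - knots[-2]) * (knots[-1] - knots[j]) / (knots[-1] - knots[-2])
            + cub(x - knots[-1]) * (knots[-2] - knots[j]) / (knots[-1] - knots[-2])
        ) / denom**2
    return out


def holm_adjust(p, m: int | None = None) -> np.ndarray:
    """Step-down Holm adjustment with enforced monotonicity.

    The family size ``m`` may exceed ``len(p)`` (a fixed nominal family, as
    when 465 pairwise tests are assumed); defaults to ``len(p)``.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if m is None:
        m = n
    if m < n:
        raise ValueError("family size m must be >= number of p-values")
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 0.0
    for rank, i in enumerate(order):
        val = min(1.0, (m - rank) * p[i])
        running = max(running, val)
        adj[i] = running
    return adj


@dataclass
class CoxResult:
    cluster_label: str
    outcome: str
    n_members: int
    n_events: int
    hr: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_adjusted: float = float("nan")


def fit_cluster_cox(
    records: pd.DataFrame,
    clustering,
    covariates: pd.DataFrame,
    outcome: str = "new_ischemic",
    holm_m: int | None = None,
    age_knots: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-cluster member-vs-rest Cox models for one outcome.

    ``records`` is the output of :func:`derive_composite_event`;
    ``covariates`` has columns ``sex`` ('M'/'F') and ``age`` indexed by
    patient_id; ``clustering`` is a finalized :class:`morbnet.mcl.Clustering`.
    Only clustered patients enter the risk set.  Returns a tidy frame with
    Wald CIs and Holm-adjusted p-values across the per-outcome family.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    assign = clustering.assignment
    clustered = assign >= 0
    ids = pd.Index(clustering.node_ids[clustered])
    sub = records.loc[ids]
    cov = covariates.loc[ids]
    labels = assign[clustered]

    age = cov["age"].to_numpy(dtype=float)
    spline = rcs_basis(age, knots=age_knots)
    base = pd.DataFrame(
        {
            "time": sub[f"time_{outcome}"].to_numpy(),
            "event": sub[f"event_{outcome}"].to_numpy(),
            "male": (cov["sex"] == "M").astype(float).to_numpy(),
            "age1": spline[:, 0],
        },
        index=ids,
    )
    for j in range(1, spline.shape[1]):
        base[f"age{j + 1}"] = spline[:, j]

    results = []
    for k in range(clustering.n_clusters):
        member = (labels == k).astype(float)
        n_events_members = int(base["event"][member == 1].sum())
        label = clustering.labels[k]
        if n_events_members == 0:
            log.warning("cluster %s has zero %s events; HR reported missing", label, outcome)
            results.append(
                CoxResult(label, outcome, int(member.sum()), 0,
                          float("nan"), float("nan"), float("nan"), float("nan"))
            )
            continue
        df = base.copy()
        df["member"] = member
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        s = cph.summary.loc["member"]
        results.append(
            CoxResult(
                label, outcome, int(member.sum()), n_events_members,
                float(np.exp(s["coef"])),
                float(np.exp(s["coef lower 95%"])),
                float(np.exp(s["coef upper 95%"])),
                float(s["p"]),
            )
        )
    out = pd.DataFrame([r.__dict__ for r in results])
    ok = out["p_raw"].notna()
    if ok.any():
        out.loc[ok, "p_adjusted"] = holm_adjust(
            out.loc[ok, "p_raw"].to_numpy(), m=holm_m or int(ok.sum())
        )
    return out


def tukey_age_comparisons(ages, labels, holm_m: int | None = None) -> pd.DataFrame:
    """All pairwise mean-age contrasts between clusters (Tukey HSD).

    Studentized-range p-values with pooled within-cluster variance, then
    Holm-adjusted with family size ``holm_m`` (default: the number of pairs,
    k(k-1)/2).  Returns a tidy frame of pairs.
    """
    from scipy.stats import tukey_hsd

    ages = np.asarray(ages, dtype=float)
    labels = np.asarray(labels)
    uniq = [u for u in pd.unique(labels)]
    groups = [ages[labels == u] for u in uniq]
    if len(groups) < 2 or any(len(gr) < 2 for gr in groups):
        raise ValueError("need >= 2 clusters with >= 2 members each")
    res = tukey_hsd(*groups)
    rows = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            rows.append(
                (
                    uniq[i],
                    uniq[j],
                    float(np.mean(groups[i]) - np.mean(groups[j])),
                    float(res.pvalue[i, j]),
                )
            )
    out = pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "mean_diff", "p_raw"])
    m = holm_m or len(out)
    out["p_adjusted"] = holm_adjust(out["p_raw"].to_numpy(), m=m)
    out["significant"] = out["p_adjusted"] < 0.05
    return out


def significance_table(cox_results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-outcome tallies of significant clusters, split by risk direction.

    Input is a tidy frame with columns cluster_label, outcome, n_members, hr,
    p_adjusted (one row per cluster x outcome).  Reports, per outcome, counts
    and summed member totals of clusters with adjusted p < alpha, split into
    increased (HR > 1) and decreased (HR < 1) risk.
    """
    rows = []
    for outcome, grp in cox_results.groupby("outcome", sort=False):
        sig = grp[(grp["p_adjusted"] < alpha) & grp["hr"].notna()]
        up = sig[sig["hr"] > 1]
        down = sig[sig["hr"] < 1]
        rows.append(
            {
                "outcome": outcome,
                "n_significant": len(sig),
                "members_significant": int(sig["n_members"].sum()),
                "n_increased": len(up),
                "members_increased": int(up["n_members"].sum()),
                "n_decreased": len(down),
                "members_decreased": int(down["n_members"].sum()),
            }
        )
    return pd.DataFrame(rows)


def high_risk_clusters(cox_results: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Clusters at significantly increased risk of every outcome present."""
    outcomes = cox_results["outcome"].unique()
    sets = []
    for outcome in outcomes:
        grp = cox_results[cox_results["outcome"] == outcome]
        sets.append(set(grp.loc[(grp["p_adjusted"] < alpha) & (grp["hr"] > 1), "cluster_label"]))
    common = set.intersection(*sets) if sets else set()
    return sorted(common)
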