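"""Endpoint derivation, Holm, splines, Cox fits, Tukey and tally tables."""

import numpy as np
import pandas as pd
import pytest

from morbnet.mcl import Clustering
from morbnet.survival import (
    DAYS_PER_YEAR,
    EndpointRules,
    derive_composite_event,
    fit_cluster_cox,
    high_risk_clusters,
    holm_adjust,
    rcs_basis,
    significance_table,
    tukey_age_comparisons,
)


def _events(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "event_type", "event_day", "cause_primary", "cause_secondary"]
    )


class TestCompositeEndpoint:
    IDX = pd.Series({"p1": 1000}, name="index_day")

    def test_early_mi_hospitalization_not_an_endpoint(self):
        ev = _events([("p1", "mi_uap_hosp", 1020, "I214", "")])  # day 20 post-index
        rec = derive_composite_event(ev, self.IDX)
        assert rec.loc["p1", "event_new_ischemic"] == 0

    def test_late_revascularization_is_endpoint(self):
        ev = _events([("p1", "revascularization", 1100, "", "")])
        rec = derive_composite_event(ev, self.IDX)
        assert rec.loc["p1", "event_new_ischemic"] == 1
        assert rec.loc["p1", "time_new_ischemic"] == 100

    def test_early_revascularization_not_an_endpoint(self):
        ev = _events([("p1", "revascularization", 1050, "", "")])
        rec = derive_composite_event(ev, self.IDX)
        assert rec.loc["p1", "event_new_ischemic"] == 0

    def test_ihd_death_any_time_counts(self):
        ev = _events([("p1", "death", 1005, "I219", "")])
        rec = derive_composite_event(ev, self.IDX)
        assert rec.loc["p1", "event_new_ischemic"] == 1
        assert rec.loc["p1", "time_new_ischemic"] == 5
        assert rec.loc["p1", "event_all_cause"] == 1
        assert rec.loc["p1", "event_non_ihd_death"] == 0

    def test_non_ihd_death_censors_ischemic_analysis(self):
        ev = _events([("p1", "death", 1400, "C349", "")])
        rec = derive_composite_event(ev, self.IDX)
        assert rec.loc["p1", "event_non_ihd_death"] == 1
        assert rec.loc["p1", "time_non_ihd_death"] == 400
        assert rec.loc["p1", "event_new_ischemic"] == 0
        assert rec.loc["p1", "time_new_ischemic"] == 400

    def test_five_year_truncation(self):
        ev = _events([("p1", "death", 1000 + 6 * 365, "C349", "")])  # year 6
        rec = derive_composite_event(ev, self.IDX)
        assert rec.loc["p1", "event_all_cause"] == 0
        assert rec.loc["p1", "time_all_cause"] == pytest.approx(5 * DAYS_PER_YEAR)

    def test_event_before_index_rejected(self, caplog):
        ev = _events([("p1", "death", 900, "C349", "")])
        with caplog.at_level("WARNING"):
            rec = derive_composite_event(ev, self.IDX)
        assert rec.loc["p1", "event_all_cause"] == 0
        assert any("rejected" in r.message for r in caplog.records)

    def test_events_plus_censored_partition_patients(self):
        idx = pd.Series({f"p{i}": 0 for i in range(6)}, name="index_day")
        ev = _events(
            [
                ("p0", "mi_uap_hosp", 200, "I214", ""),
                ("p1", "death", 300, "C349", ""),
                ("p2", "death", 400, "I219", ""),
            ]
        )
        rec = derive_composite_event(ev, idx)
        for outcome in ("new_ischemic", "non_ihd_death", "all_cause"):
            e = rec[f"event_{outcome}"]
            assert set(e.unique()) <= {0, 1}
            assert len(e) == 6


class TestHolm:
    def test_two_values_closed_form(self):
        assert np.allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_fixed_family_single_p(self):
        assert holm_adjust([0.001], m=465)[0] == pytest.approx(0.465)
        assert holm_adjust([0.01], m=465)[0] == 1.0

    def test_monotone_in_raw_p(self, rng):
        p = rng.random(20)
        adj = holm_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_matches_statsmodels_when_family_equals_length(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(15)
        assert np.allclose(holm_adjust(p), multipletests(p, method="holm")[1])

    def test_idempotent_on_adjusted_values(self, rng):
        p = np.sort(rng.random(8))
        adj = holm_adjust(p)
        # a monotone already-adjusted sequence with rank-1 multipliers only
        # grows by the same rule; re-adjusting the adjusted p with m equal to
        # the remaining steps must preserve order and never shrink any value
        again = holm_adjust(adj)
        assert (again >= adj - 1e-12).all()

    def test_rejects_bad_p(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            holm_adjust([0.1, 0.2], m=1)


class TestSpline:
    def test_three_knot_basis_has_two_columns(self, rng):
        x = rng.normal(60, 10, size=200)
        b = rcs_basis(x, n_knots=3)
        assert b.shape == (200, 2)

    def test_linear_outside_boundary_knots(self):
        knots = np.array([40.0, 60.0, 80.0])
        x = np.linspace(85, 120, 50)  # beyond the last knot
        b = rcs_basis(x, knots=knots)
        # second differences of each basis column vanish => linear tails
        for j in range(b.shape[1]):
            second = np.diff(b[:, j], 2)
            assert np.abs(second).max() < 1e-8

    def test_too_few_knots_rejected(self):
        with pytest.raises(ValueError):
            rcs_basis(np.arange(10.0), knots=np.array([1.0, 2.0]))


def _two_group_cohort(seed, log_hr, n_per_arm=1500):
    from morbnet.experiments import simulate_survival_cohort

    return simulate_survival_cohort(seed, n_per_arm=n_per_arm, log_hr=log_hr)


class TestCox:
    def test_null_effect_recovers_hr_one(self):
        patients, truth, records, cov = _two_group_cohort(21, log_hr=0.0, n_per_arm=2500)
        clustering = Clustering(patients["patient_id"].to_numpy(), truth.group_label)
        res = fit_cluster_cox(records, clustering, cov, outcome="all_cause")
        assert np.abs(np.log(res["hr"])).max() < 0.1

    def test_zero_event_cluster_reported_missing(self):
        patients, truth, records, cov = _two_group_cohort(22, log_hr=0.0, n_per_arm=200)
        # erase all events in group 1
        g1 = patients["patient_id"][truth.group_label == 1]
        records.loc[records.index.isin(g1), "event_new_ischemic"] = 0
        clustering = Clustering(patients["patient_id"].to_numpy(), truth.group_label)
        res = fit_cluster_cox(records, clustering, cov, outcome="new_ischemic")
        row = res[res["cluster_label"] == "1"]
        assert row["hr"].isna().all() and row["p_adjusted"].isna().all()
        other = res[res["cluster_label"] == "0"]
        assert other["p_adjusted"].notna().all()


class TestTukey:
    def test_pair_count_is_k_choose_2(self, rng):
        k = 8
        ages = rng.normal(60, 10, size=40 * k)
        labels = np.repeat(np.arange(k), 40)
        out = tukey_age_comparisons(ages, labels)
        assert len(out) == k * (k - 1) // 2

    def test_identical_clusters_not_significant(self, rng):
        x = rng.normal(65, 5, size=100)
        ages = np.concatenate([x, x])
        labels = np.array([0] * 100 + [1] * 100)
        out = tukey_age_comparisons(ages, labels)
        assert out["p_adjusted"].iloc[0] > 0.9
        assert not out["significant"].any()

    def test_planted_ten_year_gap_detected(self, rng):
        a = rng.normal(55, 5, size=200)
        b = rng.normal(65, 5, size=200)
        c = rng.normal(55.5, 5, size=200)
        ages = np.concatenate([a, b, c])
        labels = np.repeat([0, 1, 2], 200)
        out = tukey_age_comparisons(ages, labels, holm_m=465)
        gap = out[(out.cluster_a == 0) & (out.cluster_b == 1)]
        assert gap["significant"].all()


class TestSignificanceTable:
    def test_no_significant_rows_gives_zero_tallies(self):
        df = pd.DataFrame(
            {
                "cluster_label": ["C1", "C2"],
                "outcome": ["all_cause"] * 2,
                "n_members": [100, 200],
                "hr": [1.2, 0.8],
                "p_adjusted": [0.9, 0.3],
            }
        )
        out = significance_table(df)
        assert out["n_significant"].iloc[0] == 0
        assert out["members_significant"].iloc[0] == 0

    def test_direction_split(self):
        df = pd.DataFrame(
            {
                "cluster_label": ["C1", "C2", "C3"],
                "outcome": ["new_ischemic"] * 3,
                "n_members": [10, 20, 30],
                "hr": [2.0, 0.5, 1.5],
                "p_adjusted": [0.01, 0.02, 0.5],
            }
        )
        out = significance_table(df).iloc[0]
        assert out["n_increased"] == 1 and out["members_increased"] == 10
        assert out["n_decreased"] == 1 and out["members_decreased"] == 20

    def test_high_risk_requires_all_outcomes(self):
        rows = []
        for outcome in ("new_ischemic", "non_ihd_death", "all_cause"):
            rows.append(("C1", outcome, 10, 2.0, 0.01))
            rows.append(("C2", outcome, 10, 2.0, 0.5 if outcome == "all_cause" else 0.01))
        df = pd.DataFrame(
            rows, columns=["cluster_label", "outcome", "n_members", "hr", "p_adjusted"]
        )
        assert high_risk_clusters(df) == ["C1"]
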