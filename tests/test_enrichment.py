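"""O/E enrichment, polypharmacy, lab subcohort/scores and trait rank tests."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from morbnet.cohort import CountMatrix
from morbnet.enrichment import (
    classify_vs_reference,
    hodges_lehmann_shift,
    lab_scores,
    lab_subcohort,
    little_enrichment_flags,
    oe_ratios,
    polypharmacy_flags,
    trait_tests,
)
from morbnet.mcl import Clustering


def _count_matrix(dense, codes=None):
    dense = np.asarray(dense)
    codes = codes or [f"A{j:03d}" for j in range(dense.shape[1])]
    return CountMatrix(
        sp.csr_matrix(dense),
        np.array([f"p{i}" for i in range(dense.shape[0])]),
        np.array(codes, dtype=object),
    )


def _clustering(labels, names=None):
    c = Clustering(np.array([f"p{i}" for i in range(len(labels))]), np.asarray(labels))
    if names:
        c.labels = names
    return c


class TestOE:
    def test_ratio_arithmetic_and_enrichment_flag(self):
        # 10 patients; cluster = first 5; code carried by 4 in cluster, 1 outside
        col = np.array([1, 1, 1, 1, 0, 1, 0, 0, 0, 0]).reshape(-1, 1)
        m = _count_matrix(col)
        c = _clustering([0] * 5 + [1] * 5)
        oe = oe_ratios(m, c)
        row = oe[(oe.cluster == "0") & (oe.code == "A000")].iloc[0]
        assert row["observed_freq"] == pytest.approx(0.8)
        assert row["expected_freq"] == pytest.approx(0.5)
        assert row["oe"] == pytest.approx(1.6)
        other = oe[(oe.cluster == "1")].iloc[0]
        assert other["inverse"] and not other["enriched"]

    def test_whole_cohort_cluster_gives_unit_ratios(self):
        m = _count_matrix(np.eye(6))
        c = _clustering([0] * 6)
        oe = oe_ratios(m, c)
        assert np.allclose(oe["oe"], 1.0)

    def test_weighted_mean_conservation(self, rng):
        """Sum over clusters of size x cluster_freq equals n x cohort_freq."""
        dense = (rng.random((40, 8)) < 0.3).astype(int)
        m = _count_matrix(dense)
        labels = rng.integers(0, 3, size=40)
        c = _clustering(labels)
        oe = oe_ratios(m, c)
        sizes = {c.labels[k]: int((labels == k).sum()) for k in range(3)}
        for code, grp in oe.groupby("code"):
            weighted = sum(sizes[r.cluster] * r.observed_freq for r in grp.itertuples())
            assert weighted == pytest.approx(40 * grp["expected_freq"].iloc[0])

    def test_little_enrichment_flag(self):
        oe = pd.DataFrame(
            {"cluster": ["a"] * 3 + ["b"] * 3, "code": list("xyz") * 2,
             "oe": [20.0, 20.0, 20.0, 1.1, 1.2, 0.9]}
        )
        flags = little_enrichment_flags(oe)
        assert not flags["a"] and flags["b"]


class TestPolypharmacy:
    def _rx(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "atc_code", "redeem_day"])

    IDX = pd.Series({"p1": 1000}, name="index_day")

    def test_six_recurrent_codes_flagged(self):
        rows = [("p1", f"A{j}", 900) for j in range(6)] + [("p1", f"A{j}", 950) for j in range(6)]
        flags = polypharmacy_flags(self._rx(rows), self.IDX)
        assert flags["p1"]

    def test_five_codes_not_flagged(self):
        rows = [("p1", f"A{j}", 900) for j in range(5)] + [("p1", f"A{j}", 950) for j in range(5)]
        assert not polypharmacy_flags(self._rx(rows), self.IDX)["p1"]

    def test_single_redemption_code_does_not_count(self):
        rows = [("p1", f"A{j}", 900) for j in range(6)] + [("p1", f"A{j}", 950) for j in range(5)]
        # six distinct codes but one redeemed only once
        assert not polypharmacy_flags(self._rx(rows), self.IDX)["p1"]

    def test_window_is_one_year_pre_index(self):
        rows = [("p1", f"A{j}", 500) for j in range(6)] + [("p1", f"A{j}", 550) for j in range(6)]
        # all redemptions more than a year before index
        assert not polypharmacy_flags(self._rx(rows), self.IDX)["p1"]


class TestLabSubcohort:
    def _labs(self, rows):
        return pd.DataFrame(
            rows,
            columns=["patient_id", "test_code", "value", "unit", "ref_low", "ref_high",
                     "sample_day"],
        )

    IDX = pd.Series({"p1": 1000, "p2": 1000}, name="index_day")
    FOUR = ["sodium", "potassium", "hemoglobin", "creatinine"]

    def _complete(self, pid, day=950):
        return [(pid, t, 1.0, "u", 0.0, 2.0, day) for t in self.FOUR]

    def test_closest_to_index_selected(self):
        rows = self._complete("p1") + [
            ("p1", "sodium", 5.0, "u", 0.0, 2.0, 990),  # closer than day 950
        ] + self._complete("p2")
        _, sel = lab_subcohort(self._labs(rows), self.IDX)
        v = sel[(sel.patient_id == "p1") & (sel.test_code == "sodium")]["value"]
        assert v.iloc[0] == 5.0

    def test_missing_analyte_excludes_patient(self):
        rows = self._complete("p1") + self._complete("p2")
        rows = [r for r in rows if not (r[0] == "p2" and r[1] == "potassium")]
        eligible, _ = lab_subcohort(self._labs(rows), self.IDX)
        assert list(eligible) == ["p1"]

    def test_low_availability_test_dropped(self):
        idx = pd.Series({f"p{i}": 1000 for i in range(5)}, name="index_day")
        rows = []
        for i in range(5):
            rows += self._complete(f"p{i}")
        rows.append(("p0", "glucose", 1.0, "u", 0.0, 2.0, 980))  # 20% availability
        _, sel = lab_subcohort(self._labs(rows), idx)
        assert "glucose" not in set(sel["test_code"])

    def test_out_of_window_sample_ignored(self):
        rows = self._complete("p1", day=850)  # 150 days before index
        eligible, _ = lab_subcohort(self._labs(rows), self.IDX)
        assert len(eligible) == 0


class TestLabScores:
    def test_classification_boundaries_inclusive(self):
        out = classify_vs_reference([1.0, 2.0, 0.5, 2.5], [1.0] * 4, [2.0] * 4)
        assert out.tolist() == [0, 0, -1, 1]

    def test_score_is_mean_of_classes(self):
        sel = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(4)],
                "test_code": ["sodium"] * 4,
                "value": [3.0, 3.0, 1.5, 0.5],  # 1, 1, 0, -1
                "ref_low": [1.0] * 4,
                "ref_high": [2.0] * 4,
            }
        )
        c = _clustering([0, 0, 0, 0])
        out = lab_scores(sel, c)
        assert out.scores.loc["0", "sodium"] == pytest.approx(0.25)

    def test_identical_score_rows_adjacent_in_order(self, rng):
        rows = []
        for i, (cluster, value) in enumerate(
            [(0, 3.0), (1, 0.5), (2, 3.0)]  # clusters 0 and 2 identical
        ):
            rows.append((f"p{i}", "sodium", value, 1.0, 2.0))
        sel = pd.DataFrame(rows, columns=["patient_id", "test_code", "value", "ref_low",
                                          "ref_high"])
        c = _clustering([0, 1, 2])
        out = lab_scores(sel, c)
        order = out.cluster_order
        assert abs(order.index("0") - order.index("2")) == 1


class TestTraits:
    def _traits(self, scores_by_pid):
        rows = [(p, "t1", s) for p, s in scores_by_pid.items()]
        return pd.DataFrame(rows, columns=["patient_id", "trait", "score"])

    def test_family_size_is_clusters_times_traits(self, rng):
        n, k, t = 300, 5, 4
        pids = [f"p{i}" for i in range(n)]
        rows = [(p, f"trait{j}", rng.normal()) for p in pids for j in range(t)]
        traits = pd.DataFrame(rows, columns=["patient_id", "trait", "score"])
        c = _clustering(rng.integers(0, k, size=n))
        out = trait_tests(traits, c)
        assert len(out) == k * t

    def test_null_false_positive_rate(self, rng):
        """Permuted labels: the FDR-significant fraction stays at or below
        the nominal level across replicates."""
        n, k, t = 400, 4, 10
        pids = [f"p{i}" for i in range(n)]
        rows = [(p, f"trait{j}", rng.normal()) for p in pids for j in range(t)]
        traits = pd.DataFrame(rows, columns=["patient_id", "trait", "score"])
        n_sig = n_tests = 0
        for rep in range(10):
            c = _clustering(rng.integers(0, k, size=n))
            out = trait_tests(traits, c)
            n_sig += int(out["significant"].sum())
            n_tests += len(out)
        assert n_sig / n_tests <= 0.05

    def test_unclustered_patients_excluded(self, rng):
        labels = np.array([0] * 50 + [1] * 50 + [-1] * 20)
        pids = [f"p{i}" for i in range(120)]
        rows = [(p, "t1", rng.normal()) for p in pids]
        traits = pd.DataFrame(rows, columns=["patient_id", "trait", "score"])
        c = Clustering(np.array(pids), labels)
        out = trait_tests(traits, c)
        assert len(out) == 2  # two clusters, one trait

    def test_hodges_lehmann_matches_bruteforce(self, rng):
        x = rng.normal(size=13)
        y = rng.normal(size=7)
        brute = np.median([xi - yi for xi in x for yi in y])
        assert hodges_lehmann_shift(x, y) == pytest.approx(brute)

    def test_planted_shift_recovered(self, rng):
        x = rng.normal(0.6, 1.0, size=400)
        y = rng.normal(0.0, 1.0, size=2000)
        est = hodges_lehmann_shift(x, y)
        assert est == pytest.approx(0.6, abs=0.15)
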