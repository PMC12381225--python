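"""Count-matrix construction, index selection, tf-idf and summary arithmetic."""

import numpy as np
import pandas as pd
import pytest

from conftest import toy_diagnoses
from morbnet.cohort import (
    ExclusionConfig,
    build_count_matrix,
    cohort_summary,
    pct,
    round_half_up,
    select_index,
    tfidf_transform,
    truncate_code,
)


def test_truncate_code_level4():
    assert truncate_code("I10.9") == "I109"
    assert truncate_code("e78.0x") == "E780"
    assert truncate_code("J44") == "J44"


class TestSelectIndex:
    def procedures(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "proc_code", "proc_day", "contact_id"])

    def test_only_ihd_contact_qualifies(self):
        diag = toy_diagnoses([("p1", "I209", 100, "c1"), ("p1", "J449", 50, "c2")])
        procs = self.procedures([("p1", "CAG", 100, "c1"), ("p1", "CAG", 50, "c2")])
        idx = select_index(diag, procs)
        assert idx.loc["p1"] == 100

    def test_no_procedure_excluded(self):
        diag = toy_diagnoses([("p1", "I209", 100, "c1")])
        procs = self.procedures([("p2", "CAG", 40, "c9")])
        idx = select_index(diag, procs)
        assert "p1" not in idx.index

    def test_earliest_of_two_qualifying(self):
        diag = toy_diagnoses([("p1", "I21", 30, "c1"), ("p1", "I25", 90, "c2")])
        procs = self.procedures([("p1", "CAG", 90, "c2"), ("p1", "CCTA", 30, "c1")])
        assert select_index(diag, procs).loc["p1"] == 30

    def test_day_window_excludes(self):
        diag = toy_diagnoses([("p1", "I209", 100, "c1")])
        procs = self.procedures([("p1", "CAG", 100, "c1")])
        idx = select_index(diag, procs, day_window=(200, 400))
        assert len(idx) == 0


class TestCountMatrix:
    def test_pre_index_assignments_counted(self):
        diag = toy_diagnoses(
            [("p1", "E11", 10), ("p1", "E11", 20), ("p1", "E11", 150)]
            + [(f"q{i}", "E11", 5) for i in range(5)]
        )
        index_days = pd.Series(
            {p: 100 for p in ["p1"] + [f"q{i}" for i in range(5)]}, name="index_day"
        )
        m = build_count_matrix(diag, index_days, ExclusionConfig(min_patients_per_code=1))
        row = dict(zip(m.patient_ids, m.values.toarray()[:, list(m.code_labels).index("E11")]))
        assert row["p1"] == 2  # post-index assignment not counted

    def test_rare_code_dropped_by_carrier_threshold(self):
        rows = [(f"p{i}", "E11", 10) for i in range(4)] + [(f"p{i}", "I10", 10) for i in range(5)]
        diag = toy_diagnoses(rows)
        index_days = pd.Series({f"p{i}": 100 for i in range(5)}, name="index_day")
        m = build_count_matrix(diag, index_days, ExclusionConfig(min_patients_per_code=5))
        assert "E11" not in m.code_labels and "I10" in m.code_labels

    def test_washout_removes_recent_assignments(self):
        diag = toy_diagnoses([("p1", "E11", 70), ("p1", "E11", 5)])
        index_days = pd.Series({"p1": 100}, name="index_day")
        cfg = ExclusionConfig(min_patients_per_code=1, washout_days=90)
        m = build_count_matrix(diag, index_days, cfg)
        # assignment 30 days pre-index falls inside the washout window
        assert m.values.sum() == 1

    def test_excluded_prefixes_dropped(self):
        diag = toy_diagnoses(
            [("p1", "I21", 10), ("p1", "Z001", 10), ("p1", "O80", 10), ("p1", "E11", 10)]
        )
        index_days = pd.Series({"p1": 100}, name="index_day")
        m = build_count_matrix(diag, index_days, ExclusionConfig(min_patients_per_code=1))
        assert list(m.code_labels) == ["E11"]

    def test_malformed_codes_skipped(self):
        diag = toy_diagnoses([("p1", "??", 10), ("p1", "E11", 10)])
        index_days = pd.Series({"p1": 100}, name="index_day")
        m = build_count_matrix(diag, index_days, ExclusionConfig(min_patients_per_code=1))
        assert list(m.code_labels) == ["E11"]

    def test_empty_history_patients_keep_zero_rows(self):
        diag = toy_diagnoses([("p1", "E11", 10)])
        index_days = pd.Series({"p1": 100, "p2": 100}, name="index_day")
        m = build_count_matrix(diag, index_days, ExclusionConfig(min_patients_per_code=1))
        assert m.shape == (2, 1)
        assert m.values.toarray()[list(m.patient_ids).index("p2")].sum() == 0

    def test_column_sums_equal_bruteforce_tally(self, small_cohort, small_matrix):
        """Oracle: per-code assignment tallies by a direct scan."""
        diag = small_cohort["diagnoses"]
        index_days = small_cohort["index_days"]
        m = small_matrix
        col_sums = np.asarray(m.values.sum(axis=0)).ravel()
        for j, code in enumerate(m.code_labels):
            sub = diag[diag["code"].map(truncate_code) == code]
            expected = sum(
                1 for _, r in sub.iterrows() if r["assign_day"] < index_days[r["patient_id"]]
            )
            assert col_sums[j] == expected

    @pytest.mark.parametrize("pair", [(0, 90), (90, 180), (180, 365)])
    def test_washout_monotone(self, small_cohort, pair):
        lo, hi = pair
        index_days = small_cohort["index_days"]
        a = build_count_matrix(
            small_cohort["diagnoses"], index_days,
            ExclusionConfig(min_patients_per_code=1, washout_days=lo),
        )
        b = build_count_matrix(
            small_cohort["diagnoses"], index_days,
            ExclusionConfig(min_patients_per_code=1, washout_days=hi),
        )
        cols_a = {c: i for i, c in enumerate(a.code_labels)}
        da, db = a.values.toarray(), b.values.toarray()
        for c in b.code_labels:
            j = list(b.code_labels).index(c)
            assert (db[:, j] <= da[:, cols_a[c]]).all()

    def test_exclusion_idempotent(self, small_cohort, small_matrix):
        """Rebuilding from already-retained codes changes nothing."""
        diag = small_cohort["diagnoses"].copy()
        diag["code4"] = diag["code"].map(truncate_code)
        filtered = diag[diag["code4"].isin(small_matrix.code_labels)].drop(columns="code4")
        m2 = build_count_matrix(filtered, small_cohort["index_days"], ExclusionConfig())
        assert list(m2.code_labels) == list(small_matrix.code_labels)
        assert (m2.values != small_matrix.values).nnz == 0


class TestTfidf:
    def _matrix(self, dense, codes):
        import scipy.sparse as sp

        from morbnet.cohort import CountMatrix

        return CountMatrix(
            sp.csr_matrix(np.asarray(dense)), np.array([f"p{i}" for i in range(len(dense))]),
            np.array(codes, dtype=object),
        )

    def test_ubiquitous_code_zeroed(self):
        m = self._matrix([[1, 2], [3, 0]], ["A00", "B00"])
        out = tfidf_transform(m).toarray()
        assert np.allclose(out[:, 0], 0.0)  # carried by everyone -> idf 0

    def test_unique_code_ln_n(self):
        m = self._matrix([[1, 1], [0, 1]], ["A00", "B00"])
        out = tfidf_transform(m).toarray()
        assert out[0, 0] == pytest.approx(np.log(2))

    def test_hand_computed_toy(self):
        m = self._matrix([[2, 0], [1, 1], [0, 3]], ["A00", "B00"])
        out = tfidf_transform(m).toarray()
        expected = np.array(
            [
                [2 * np.log(3 / 2), 0.0],
                [1 * np.log(3 / 2), 1 * np.log(3 / 2)],
                [0.0, 3 * np.log(3 / 2)],
            ]
        )
        assert np.allclose(out, expected)


class TestSummaryArithmetic:
    def test_printed_male_percentage(self):
        assert pct(45_576, 72_249) == 63.1

    def test_printed_comorbidity_percentage(self):
        assert pct(68_103, 72_249) == 94.3

    def test_zero_case(self):
        assert pct(0, 1000) == 0.0
        assert pct(5, 0) == 0.0

    def test_half_up_rounding(self):
        assert round_half_up(34.35, 1) == 34.4
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(2.449, 1) == 2.4

    def test_summary_on_synthetic(self, small_cohort, small_matrix):
        s = cohort_summary(small_cohort["patients"], small_matrix)
        assert s.n_males + s.n_females == s.n_patients
        assert s.pct_male == pct(s.n_males, s.n_patients)
        top = s.code_carriers.iloc[0]
        assert top["n_carriers"] == small_matrix.carrier_counts().max()
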