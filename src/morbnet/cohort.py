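"""Cohort construction: index-date selection, exclusion rules, count matrix.

The multimorbidity signal is a patients x diagnosis-codes "bag-of-words"
count matrix of pre-index code assignments.  Codes are truncated to level 4
(first four alphanumerics), IHD codes (I20-I25) and administratively or
etiologically uninformative chapters (pregnancy, perinatal, congenital,
injury, external causes, contact codes) are excluded, and codes carried by
fewer than five patients are dropped.  Patients with empty histories are kept
as all-zero rows; they surface as singletons in the clustering.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import scipy.sparse as sp

log = logging.getLogger(__name__)

IHD_PREFIXES = ("I20", "I21", "I22", "I23", "I24", "I25")

#: Chapter analogues excluded from the comorbidity vocabulary: pregnancy (O),
#: perinatal (P), congenital (Q), injury/poisoning (S, T), external causes
#: (V, W, X, Y) and administrative contact codes (Z), plus the IHD codes.
DEFAULT_EXCLUDED_PREFIXES = IHD_PREFIXES + ("O", "P", "Q", "S", "T", "V", "W", "X", "Y", "Z")

_CODE_RE = re.compile(r"^[A-Z][A-Z0-9]{0,3}$")


@dataclass
class ExclusionConfig:
    excluded_code_prefixes: tuple = DEFAULT_EXCLUDED_PREFIXES
    min_patients_per_code: int = 5
    washout_days: int = 0

    def __post_init__(self):
        if self.min_patients_per_code < 1:
            raise ValueError("min_patients_per_code must be >= 1")
        if self.washout_days < 0:
            raise ValueError("washout_days must be >= 0")


@dataclass
class CountMatrix:
    """Sparse patients x codes count matrix with aligned labels."""

    values: sp.csr_matrix
    patient_ids: np.ndarray
    code_labels: np.ndarray

    @property
    def shape(self):
        return self.values.shape

    def carrier_counts(self) -> np.ndarray:
        """Number of patients with >=1 assignment, per code."""
        return np.asarray((self.values > 0).sum(axis=0)).ravel()

    def carriers(self) -> sp.csr_matrix:
        return (self.values > 0).astype(np.int8).tocsr()


def truncate_code(code: str) -> str:
    """Level-4 truncation: first four alphanumeric characters, upper-cased."""
    return "".join(ch for ch in str(code).upper() if ch.isalnum())[:4]


def select_index(
    diagnoses: pd.DataFrame,
    procedures: pd.DataFrame,
    ihd_prefixes: tuple = IHD_PREFIXES,
    day_window: tuple | None = None,
) -> pd.Series:
    """Per-patient index date: earliest qualifying procedure.

    A procedure qualifies when it occurs during a contact (shared
    ``contact_id``) that also carries an IHD diagnosis code.  Patients with no
    qualifying procedure, or whose earliest qualifying procedure falls outside
    ``day_window``, are excluded.  Returns a Series indexed by patient_id.
    """
    diag = diagnoses.copy()
    diag["code4"] = diag["code"].map(truncate_code)
    is_ihd = diag["code4"].str.startswith(tuple(ihd_prefixes))
    ihd_contacts = set(diag.loc[is_ihd, "contact_id"])

    procs = procedures.dropna(subset=["contact_id"])
    n_unlinked = len(procedures) - len(procs)
    if n_unlinked:
        log.warning("excluded %d procedure records without contact linkage", n_unlinked)
    qualifying = procs[procs["contact_id"].isin(ihd_contacts)]
    index = qualifying.groupby("patient_id")["proc_day"].min()
    if day_window is not None:
        lo, hi = day_window
        index = index[(index >= lo) & (index <= hi)]
    return index.rename("index_day")


def build_count_matrix(
    diagnoses: pd.DataFrame,
    index_days: pd.Series,
    exclusions: ExclusionConfig | None = None,
) -> CountMatrix:
    """Assemble the pre-index bag-of-words count matrix.

    Counts assignments of each retained code strictly before
    ``index - washout_days``.  Excluded-prefix codes are dropped first, then
    codes carried by fewer than ``min_patients_per_code`` patients.  Rows are
    all patients in ``index_days`` (all-zero rows retained).
    """
    cfg = exclusions or ExclusionConfig()
    patient_ids = np.asarray(index_days.index)
    pat_pos = {p: i for i, p in enumerate(patient_ids)}

    diag = diagnoses[diagnoses["patient_id"].isin(pat_pos)].copy()
    diag["code4"] = diag["code"].map(truncate_code)
    malformed = ~diag["code4"].map(lambda c: bool(_CODE_RE.match(c)))
    if malformed.any():
        log.warning("skipped %d records with malformed codes", int(malformed.sum()))
        diag = diag[~malformed]

    cutoff = diag["patient_id"].map(index_days) - cfg.washout_days
    diag = diag[diag["assign_day"] < cutoff]
    if cfg.excluded_code_prefixes:
        diag = diag[~diag["code4"].str.startswith(tuple(cfg.excluded_code_prefixes))]

    if len(diag) == 0:
        return CountMatrix(
            sp.csr_matrix((len(patient_ids), 0), dtype=np.int64),
            patient_ids,
            np.array([], dtype=object),
        )

    codes, code_labels = pd.factorize(diag["code4"], sort=True)
    rows = diag["patient_id"].map(pat_pos).to_numpy()
    m = sp.coo_matrix(
        (np.ones(len(diag), dtype=np.int64), (rows, codes)),
        shape=(len(patient_ids), len(code_labels)),
    ).tocsr()

    carriers = np.asarray((m > 0).sum(axis=0)).ravel()
    keep = carriers >= cfg.min_patients_per_code
    m = m[:, keep]
    code_labels = np.asarray(code_labels, dtype=object)[keep]
    return CountMatrix(m.tocsr(), patient_ids, code_labels)


def tfidf_transform(m: CountMatrix) -> sp.csr_matrix:
    """tf-idf scaling: entry = count * ln(n_patients / carrier_count).

    Codes carried by every patient get idf = ln 1 = 0 and map to zero.
    """
    if m.values.shape[1] == 0:
        raise ValueError("empty count matrix")
    n = m.values.shape[0]
    df = m.carrier_counts().astype(float)
    idf = np.log(n / df)
    out = m.values.astype(float) @ sp.diags(idf)
    out.eliminate_zeros()
    return out.tocsr()


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (the convention of printed registry tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: int, total: int, decimals: int = 1) -> float:
    """Percentage with half-up rounding to ``decimals`` places."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, decimals)


@dataclass
class CohortSummary:
    n_patients: int
    n_males: int
    n_females: int
    pct_male: float
    mean_age: float
    code_carriers: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_with_comorbidity: int = 0
    pct_with_comorbidity: float = 0.0
    outcome_counts: dict = field(default_factory=dict)


def cohort_summary(
    patients: pd.DataFrame, m: CountMatrix, events: pd.DataFrame | None = None
) -> CohortSummary:
    """Demographics, comorbidity carriage and outcome tallies."""
    pats = patients.set_index("patient_id").loc[m.patient_ids]
    n = len(pats)
    n_m = int((pats["sex"] == "M").sum())
    n_f = int((pats["sex"] == "F").sum())
    carriers = m.carrier_counts()
    order = np.argsort(-carriers, kind="stable")
    code_carriers = pd.DataFrame(
        {
            "code": m.code_labels[order],
            "n_carriers": carriers[order],
            "pct_carriers": [pct(c, n) for c in carriers[order]],
        }
    )
    per_patient = np.asarray((m.values > 0).sum(axis=1)).ravel()
    n_comorbid = int((per_patient > 0).sum())
    outcome_counts = {}
    if events is not None and len(events):
        outcome_counts = events["event_type"].value_counts().to_dict()
    return CohortSummary(
        n_patients=n,
        n_males=n_m,
        n_females=n_f,
        pct_male=pct(n_m, n),
        mean_age=float(pats["age_at_index"].mean()) if "age_at_index" in pats else float("nan"),
        code_carriers=code_carriers,
        n_with_comorbidity=n_comorbid,
        pct_with_comorbidity=pct(n_comorbid, n),
        outcome_counts=outcome_counts,
    )
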