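"""Synthetic registry-style cohort generator with planted multimorbidity clusters.

Emulates the structure of national-registry inputs (patient, diagnosis,
procedure, prescription, laboratory, outcome and trait tables) for an ischemic
heart disease cohort, with group-structured diagnosis-code propensities,
group-specific competing-risk hazards, and group-shifted laboratory and trait
distributions.  Every downstream stage of the pipeline can thus be exercised
against a known ground truth (group labels, true hazard ratios, enriched codes,
shifted traits).

Dates are integer days relative to a fixed epoch; no calendar logic is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

#: Causes simulated as independent cause-specific exponentials.
CAUSES = ("ischemic", "non_ihd_death")

#: Laboratory panel with fixed reference intervals (plausible adult plasma
#: ranges; units are nominal).  The first four are the completeness analytes.
LAB_PANEL = {
    "sodium": (137.0, 145.0, "mmol/L"),
    "potassium": (3.5, 4.6, "mmol/L"),
    "hemoglobin": (8.3, 10.5, "mmol/L"),
    "creatinine": (60.0, 105.0, "umol/L"),
    "glucose": (4.2, 6.3, "mmol/L"),
    "ldl_cholesterol": (1.2, 4.3, "mmol/L"),
    "hdl_cholesterol": (1.0, 2.1, "mmol/L"),
    "triglyceride": (0.6, 2.5, "mmol/L"),
}

COMPLETENESS_ANALYTES = ("sodium", "potassium", "hemoglobin", "creatinine")

#: Trait scores emulate standardized polygenic scores for the fourteen traits
#: tested in the characterization stage.
TRAIT_NAMES = (
    "atrial_fibrillation",
    "type2_diabetes",
    "chronic_kidney_disease",
    "hdl_cholesterol",
    "heart_failure",
    "ldl_cholesterol",
    "stroke",
    "total_cholesterol",
    "triglycerides",
    "myocardial_infarction",
    "coronary_artery_disease",
    "diastolic_bp",
    "nafld",
    "systolic_bp",
)

#: Chapter letters that survive the downstream exclusion filters (chapters
#: I-XIV plus symptoms); codes are synthetic four-character ICD-10-style.
_SAFE_LETTERS = "ABCDEFGHJKLMNR"


class SimConfigError(ValueError):
    """Raised for invalid simulation configurations."""


def _default_group_array(value, n_groups, default):
    if value is None:
        return np.full(n_groups, default, dtype=float)
    arr = np.asarray(value, dtype=float)
    if arr.shape != (n_groups,):
        raise SimConfigError(f"expected length-{n_groups} vector, got shape {arr.shape}")
    return arr


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the registry cohort the pipeline models: ~63% male, mean
    age at index ~64 y (sd ~12), a mean of ~8 pre-index diagnoses per patient,
    annual cause-specific event rates of roughly 5%/yr for new ischemic events
    and 4%/yr for non-IHD death, and administrative censoring at 5 years.
    """

    n_patients: int = 5000
    n_codes: int = 300
    n_groups: int = 4
    group_weights: np.ndarray | None = None
    codes_per_group: int = 30
    within_group_code_prob: float = 0.5
    background_code_prob: float = 0.02
    mean_codes_per_patient: float = 8.1
    sex_prob_by_group: np.ndarray | None = None  # probability of male
    age_mean_by_group: np.ndarray | None = None
    age_sd: float = 11.9
    hazard_log_hr_by_group_and_cause: np.ndarray | None = None  # groups x 2
    baseline_hazards: dict = field(
        default_factory=lambda: {"ischemic": 0.05, "non_ihd_death": 0.04}
    )
    admin_censor_years: float = 5.0
    lab_shift_by_group: np.ndarray | None = None  # groups x len(LAB_PANEL)
    trait_shift_by_group: np.ndarray | None = None  # groups x len(TRAIT_NAMES)
    polypharmacy_prob_by_group: np.ndarray | None = None
    lab_sampled_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1 or self.n_codes < 1 or self.n_groups < 1:
            raise SimConfigError("n_patients, n_codes and n_groups must be positive")
        if self.codes_per_group * self.n_groups > self.n_codes:
            raise SimConfigError("codes_per_group * n_groups exceeds n_codes")
        if self.group_weights is None:
            self.group_weights = np.full(self.n_groups, 1.0 / self.n_groups)
        else:
            self.group_weights = np.asarray(self.group_weights, dtype=float)
        if abs(self.group_weights.sum() - 1.0) > 1e-12:
            raise SimConfigError("group_weights must sum to 1")
        for p in (
            self.within_group_code_prob,
            self.background_code_prob,
            self.lab_sampled_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise SimConfigError(f"probability {p} outside [0, 1]")
        if self.mean_codes_per_patient <= 0:
            raise SimConfigError("mean_codes_per_patient must be positive")
        if any(r < 0 for r in self.baseline_hazards.values()):
            raise SimConfigError("baseline hazards must be non-negative")
        self.sex_prob_by_group = _default_group_array(
            self.sex_prob_by_group, self.n_groups, 0.631
        )
        if ((self.sex_prob_by_group < 0) | (self.sex_prob_by_group > 1)).any():
            raise SimConfigError("sex probabilities outside [0, 1]")
        self.age_mean_by_group = _default_group_array(
            self.age_mean_by_group, self.n_groups, 63.9
        )
        self.polypharmacy_prob_by_group = _default_group_array(
            self.polypharmacy_prob_by_group, self.n_groups, 0.3
        )
        if ((self.polypharmacy_prob_by_group < 0) | (self.polypharmacy_prob_by_group > 1)).any():
            raise SimConfigError("polypharmacy probabilities outside [0, 1]")
        if self.hazard_log_hr_by_group_and_cause is None:
            self.hazard_log_hr_by_group_and_cause = np.zeros((self.n_groups, len(CAUSES)))
        else:
            self.hazard_log_hr_by_group_and_cause = np.asarray(
                self.hazard_log_hr_by_group_and_cause, dtype=float
            ).reshape(self.n_groups, len(CAUSES))
        if self.lab_shift_by_group is None:
            self.lab_shift_by_group = np.zeros((self.n_groups, len(LAB_PANEL)))
        else:
            self.lab_shift_by_group = np.asarray(self.lab_shift_by_group, dtype=float).reshape(
                self.n_groups, len(LAB_PANEL)
            )
        if self.trait_shift_by_group is None:
            self.trait_shift_by_group = np.zeros((self.n_groups, len(TRAIT_NAMES)))
        else:
            self.trait_shift_by_group = np.asarray(
                self.trait_shift_by_group, dtype=float
            ).reshape(self.n_groups, len(TRAIT_NAMES))

    def code_labels(self) -> list[str]:
        """Synthetic four-character diagnosis codes, group blocks first."""
        letters = _SAFE_LETTERS
        return [f"{letters[i % len(letters)]}{i // len(letters):03d}" for i in range(self.n_codes)]

    def group_code_indices(self, g: int) -> np.ndarray:
        start = g * self.codes_per_group
        return np.arange(start, start + self.codes_per_group)

    def to_json(self) -> str:
        d = {}
        for k, v in self.__dict__.items():
            d[k] = v.tolist() if isinstance(v, np.ndarray) else v
        return json.dumps(d, indent=2)


@dataclass
class SyntheticTruth:
    """Planted structure: the answer key for recovery tests."""

    group_label: np.ndarray  # per-patient integer in [0, n_groups)
    enriched_codes_by_group: dict  # group -> set of code strings
    true_hr_by_group_and_cause: np.ndarray  # groups x causes (hazard ratios)
    shifted_traits_by_group: dict  # group -> set of trait names
    polypharmacy_flag: np.ndarray | None = None


def generate_cohort(config: SimConfig):
    """Draw patients and their pre-index diagnosis histories.

    Each patient is assigned a latent multimorbidity group; their diagnosis
    multiset is a Poisson number of assignments over a categorical code
    distribution mixing the group profile (``within_group_code_prob`` per
    group code) with a uniform background (``background_code_prob`` per other
    code).  An index-defining coronary angiography procedure is emitted for
    every patient during a contact carrying an IHD code, so the index-selection
    rule recovers the generator's index date exactly.

    Returns ``(patients, diagnoses, procedures, truth)``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    groups = rng.choice(cfg.n_groups, size=n, p=cfg.group_weights)
    is_male = rng.random(n) < cfg.sex_prob_by_group[groups]
    age = rng.normal(cfg.age_mean_by_group[groups], cfg.age_sd)
    age = np.clip(age, 25.0, 100.0)
    index_day = rng.integers(3650, 7300, size=n)
    birth_day = (index_day - age * DAYS_PER_YEAR).astype(int)

    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "sex": np.where(is_male, "M", "F"),
            "birth_day": birth_day,
            "index_day": index_day,
            "age_at_index": (index_day - birth_day) / DAYS_PER_YEAR,
        }
    )

    codes = np.array(cfg.code_labels())
    # per-group categorical code distribution
    probs_by_group = np.full((cfg.n_groups, cfg.n_codes), cfg.background_code_prob)
    for g in range(cfg.n_groups):
        probs_by_group[g, cfg.group_code_indices(g)] = cfg.within_group_code_prob
    row_sums = probs_by_group.sum(axis=1)
    if (row_sums <= 0).any():
        raise SimConfigError("code propensity rows must have positive mass")
    probs_by_group /= row_sums[:, None]

    n_assign = rng.poisson(cfg.mean_codes_per_patient, size=n)
    pat_idx = np.repeat(np.arange(n), n_assign)
    code_idx = np.empty(n_assign.sum(), dtype=int)
    # draw per group so each patient uses its group's categorical distribution
    for g in range(cfg.n_groups):
        mask = groups[pat_idx] == g
        code_idx[mask] = rng.choice(cfg.n_codes, size=mask.sum(), p=probs_by_group[g])
    assign_day = index_day[pat_idx] - rng.integers(1, 3650, size=pat_idx.size)

    diagnoses = pd.DataFrame(
        {
            "patient_id": patients["patient_id"].to_numpy()[pat_idx],
            "code": codes[code_idx],
            "assign_day": assign_day,
            "contact_id": [f"K{i:07d}" for i in range(pat_idx.size)],
            "contact_type": "inpatient",
        }
    )
    # index-defining contact: IHD diagnosis + CAG procedure sharing a contact id
    idx_contacts = [f"X{i:06d}" for i in range(n)]
    ihd_rows = pd.DataFrame(
        {
            "patient_id": patients["patient_id"],
            "code": "I209",
            "assign_day": index_day,
            "contact_id": idx_contacts,
            "contact_type": "inpatient",
        }
    )
    diagnoses = pd.concat([diagnoses, ihd_rows], ignore_index=True)
    procedures = pd.DataFrame(
        {
            "patient_id": patients["patient_id"],
            "proc_code": "CAG",
            "proc_day": index_day,
            "contact_id": idx_contacts,
        }
    )

    truth = SyntheticTruth(
        group_label=groups,
        enriched_codes_by_group={
            g: set(codes[cfg.group_code_indices(g)]) for g in range(cfg.n_groups)
        },
        true_hr_by_group_and_cause=np.exp(cfg.hazard_log_hr_by_group_and_cause),
        shifted_traits_by_group={
            g: {
                TRAIT_NAMES[t]
                for t in range(len(TRAIT_NAMES))
                if cfg.trait_shift_by_group[g, t] != 0.0
            }
            for g in range(cfg.n_groups)
        },
    )
    return patients, diagnoses, procedures, truth


class DataError(ValueError):
    """Raised for inconsistent inter-table inputs."""


def generate_survival(patients: pd.DataFrame, truth: SyntheticTruth, config: SimConfig):
    """Simulate competing-risk outcomes as cause-specific exponentials.

    For each patient the two cause-specific event times are exponential with
    rate ``baseline x exp(log HR of the patient's group)``; the earliest of the
    two (if before administrative censoring) is emitted as an outcome record.
    New ischemic events are emitted as a mix of MI/UAP hospitalization,
    revascularization and IHD-cause death records so the composite-endpoint
    rules downstream see realistic record types.
    """
    cfg = config
    n = len(patients)
    if truth.group_label is None or len(truth.group_label) != n:
        raise DataError("every patient needs a group label")
    rng = np.random.default_rng(cfg.seed + 1)
    groups = truth.group_label
    admin_days = cfg.admin_censor_years * DAYS_PER_YEAR

    times = np.full((n, len(CAUSES)), np.inf)
    for c, cause in enumerate(CAUSES):
        base = cfg.baseline_hazards[cause] / DAYS_PER_YEAR  # per-day rate
        rate = base * np.exp(cfg.hazard_log_hr_by_group_and_cause[groups, c])
        pos = rate > 0
        draws = np.full(n, np.inf)
        draws[pos] = rng.exponential(1.0 / rate[pos])
        times[:, c] = draws

    first_cause = times.argmin(axis=1)
    first_time = times.min(axis=1)
    observed = first_time < admin_days

    index_day = patients["index_day"].to_numpy()
    pid = patients["patient_id"].to_numpy()
    rows = []
    subtype = rng.random(n)
    for i in np.nonzero(observed)[0]:
        day = int(np.ceil(index_day[i] + first_time[i]))
        day = max(day, index_day[i] + 1)  # strictly after index
        if CAUSES[first_cause[i]] == "ischemic":
            u = subtype[i]
            if u < 0.45:
                rows.append((pid[i], "mi_uap_hosp", day, "I214", ""))
            elif u < 0.80:
                rows.append((pid[i], "revascularization", day, "", ""))
            else:
                rows.append((pid[i], "death", day, "I219", ""))
        else:
            rows.append((pid[i], "death", day, "C349", "J449"))
    events = pd.DataFrame(
        rows, columns=["patient_id", "event_type", "event_day", "cause_primary", "cause_secondary"]
    )
    return events


def generate_labs_prescriptions_traits(
    patients: pd.DataFrame, truth: SyntheticTruth, config: SimConfig
):
    """Simulate laboratory, prescription and trait-score tables.

    Lab values are Normal(group shift, 1) on a standardized scale centred on
    the mid-reference value (one unit = half the reference interval width), so
    with zero shift the below/within/above classifier is symmetric.  A
    ``lab_sampled_fraction`` of patients have all panel tests sampled within
    90 days pre-index; the rest are sampled outside that window and drop out
    of the completeness-filtered subcohort.  Prescriptions are drawn so that
    the polypharmacy rule (>5 distinct codes, each redeemed >=2 times within
    1 year pre-index) fires with the group-specific probability.  Trait scores
    are Normal(group shift, 1), then standardized cohort-wide.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 2)
    n = len(patients)
    groups = truth.group_label
    index_day = patients["index_day"].to_numpy()
    pid = patients["patient_id"].to_numpy()

    # --- labs ---
    sampled = rng.random(n) < cfg.lab_sampled_fraction
    lab_rows = []
    for t, (test, (low, high, unit)) in enumerate(LAB_PANEL.items()):
        mid = 0.5 * (low + high)
        half = 0.5 * (high - low)
        z = cfg.lab_shift_by_group[groups, t] + rng.normal(size=n)
        values = mid + z * half
        offs = np.where(
            sampled, rng.integers(0, 91, size=n), 91 + rng.integers(0, 300, size=n)
        )
        for i in range(n):
            lab_rows.append((pid[i], test, values[i], unit, low, high, index_day[i] - offs[i]))
    labs = pd.DataFrame(
        lab_rows,
        columns=["patient_id", "test_code", "value", "unit", "ref_low", "ref_high", "sample_day"],
    )

    # --- prescriptions ---
    poly = rng.random(n) < cfg.polypharmacy_prob_by_group[groups]
    atc_pool = np.array([f"A{j:02d}XX{j:02d}" for j in range(40)])
    rx_rows = []
    for i in range(n):
        if poly[i]:
            n_distinct = 6 + rng.poisson(2)
            n_redeem = lambda: 2 + rng.poisson(1)  # noqa: E731
        else:
            n_distinct = 1 + rng.integers(0, 4)  # 1..4 distinct, single redemptions
            n_redeem = lambda: 1  # noqa: E731
        chosen = rng.choice(atc_pool, size=min(n_distinct, len(atc_pool)), replace=False)
        for code in chosen:
            for _ in range(n_redeem()):
                day = index_day[i] - rng.integers(8, 366)
                rx_rows.append((pid[i], code, day))
    prescriptions = pd.DataFrame(rx_rows, columns=["patient_id", "atc_code", "redeem_day"])

    # --- traits ---
    raw = cfg.trait_shift_by_group[groups, :] + rng.normal(size=(n, len(TRAIT_NAMES)))
    std = (raw - raw.mean(axis=0)) / raw.std(axis=0, ddof=0)
    traits = pd.DataFrame(std, columns=list(TRAIT_NAMES))
    traits.insert(0, "patient_id", pid)
    traits = traits.melt(id_vars="patient_id", var_name="trait", value_name="score")

    truth.polypharmacy_flag = poly
    return labs, prescriptions, traits


def write_tables(outdir, patients, diagnoses, procedures, events, labs, prescriptions, traits,
                 truth: SyntheticTruth, config: SimConfig) -> None:
    """Write all tables as TSV plus truth labels and the config as JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in [
        ("patients", patients),
        ("diagnoses", diagnoses),
        ("procedures", procedures),
        ("events", events),
        ("labs", labs),
        ("prescriptions", prescriptions),
        ("traits", traits),
    ]:
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"patient_id": patients["patient_id"], "group": truth.group_label}
    ).to_csv(out / "truth_labels.tsv", sep="\t", index=False)
    (out / "sim_config.json").write_text(config.to_json())
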