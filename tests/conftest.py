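import numpy as np
import pandas as pd
import pytest

from morbnet.cohort import ExclusionConfig, build_count_matrix
from morbnet.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Three-group cohort small enough for exhaustive unit checks."""
    cfg = SimConfig(
        n_patients=400,
        n_codes=90,
        n_groups=3,
        codes_per_group=20,
        within_group_code_prob=0.5,
        background_code_prob=0.02,
        mean_codes_per_patient=6.0,
        seed=11,
    )
    patients, diagnoses, procedures, truth = generate_cohort(cfg)
    return {
        "config": cfg,
        "patients": patients,
        "diagnoses": diagnoses,
        "procedures": procedures,
        "truth": truth,
        "index_days": patients.set_index("patient_id")["index_day"],
    }


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    return build_count_matrix(
        small_cohort["diagnoses"], small_cohort["index_days"], ExclusionConfig()
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def toy_diagnoses(rows):
    """rows: (patient_id, code, assign_day[, contact_id])."""
    recs = []
    for r in rows:
        pid, code, day = r[0], r[1], r[2]
        contact = r[3] if len(r) > 3 else f"K{len(recs)}"
        recs.append((pid, code, day, contact, "inpatient"))
    return pd.DataFrame(
        recs, columns=["patient_id", "code", "assign_day", "contact_id", "contact_type"]
    )
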