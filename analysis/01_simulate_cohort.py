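"""Generate the synthetic registry cohort used by the downstream analyses.

Writes the seven registry-style tables (patients, diagnoses, procedures,
events, labs, prescriptions, traits), the planted truth labels and the
simulation config to results/data/.  The cohort uses the planted-recovery
study condition: 1,500 patients in three latent multimorbidity groups.
"""

import sys
from pathlib import Path

from morbnet import simulate as sim
from morbnet.experiments import recovery_config

OUT = Path("results/data")


def main(seed: int = 1) -> None:
    cfg = recovery_config(seed)
    patients, diagnoses, procedures, truth = sim.generate_cohort(cfg)
    events = sim.generate_survival(patients, truth, cfg)
    labs, rx, traits = sim.generate_labs_prescriptions_traits(patients, truth, cfg)
    sim.write_tables(OUT, patients, diagnoses, procedures, events, labs, rx, traits,
                     truth, cfg)
    print(f"cohort: {len(patients)} patients, {len(diagnoses)} diagnosis records, "
          f"{len(events)} outcome events -> {OUT}")
    print(f"planted groups: {cfg.n_groups}, group sizes "
          f"{[int((truth.group_label == g).sum()) for g in range(cfg.n_groups)]}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
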