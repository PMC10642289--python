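"""Simulate the two synthetic study cohorts and write their trial tables.

Generates a 40-participant cohort for each experiment template (the second
experiment's design: congruency x object membership, near flankers, 112
trials per cell, 2 s deadline, 150 ms floor) from the published group-level
DMC parameters of the mu_t-only model, and reports the exclusion summary.
"""

import json
from pathlib import Path

import numpy as np

from dmcflank import StudyDesign, apply_exclusions, generate_cohort, write_trials
from dmcflank.cohort import exp1_population, exp2_population

OUT = Path("results")
SEED = 20230929


def main() -> None:
    OUT.mkdir(exist_ok=True)
    for idx, (name, pop) in enumerate(
        (("exp1", exp1_population()), ("exp2", exp2_population()))
    ):
        design = StudyDesign(n_participants=40, trials_per_cell=112)
        rng = np.random.default_rng(np.random.SeedSequence([SEED, idx]))
        cohort = generate_cohort(design, pop, rng)
        write_trials(cohort, OUT / f"cohort_{name}.csv")
        _, report = apply_exclusions(cohort)
        (OUT / f"cohort_{name}_exclusions.json").write_text(json.dumps(report, indent=1))
        print(f"{name}: {len(cohort)} trials; "
              f"errors {report['pct_error']:.1f}%, too_slow {report['pct_too_slow']:.2f}%, "
              f"too_fast {report['pct_too_fast']:.2f}%")


if __name__ == "__main__":
    main()
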