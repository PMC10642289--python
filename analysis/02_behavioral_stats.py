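"""Behavioral analyses of the synthetic cohorts: cell means, congruency
effects, repeated-measures ANOVA, within-subject SEs.

Reads the cohorts written by 01_simulate_cohort.py and reproduces the
Table-1-style summaries: mean correct RT and percent correct per condition
and congruency, the congruency effect per object condition, and the
Congruency x Object ANOVA.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dmcflank import (
    apply_exclusions,
    cell_summaries,
    congruency_effect,
    read_trials,
    rm_anova,
    within_subject_se,
)

OUT = Path("results")


def main() -> None:
    for name in ("exp1", "exp2"):
        path = OUT / f"cohort_{name}.csv"
        if not path.exists():
            print(f"{path} missing; run 01_simulate_cohort.py first")
            continue
        included, _ = apply_exclusions(read_trials(path))
        summary = cell_summaries(included)
        summary.to_csv(OUT / f"{name}_cell_summaries.csv", index=False)

        table1 = summary.groupby(["object", "congruency"]).agg(
            mean_rt=("mean_rt", "mean"), pc=("pc", "mean")
        )
        wide = summary.pivot_table(index="participant", columns=["object", "congruency"],
                                   values="mean_rt")
        table1["rt_wse"] = within_subject_se(wide.to_numpy())
        table1.to_csv(OUT / f"{name}_table1_style.csv")
        print(f"\n{name}: cell means (RT ms / PC)")
        print((table1.round(1)).to_string())

        ce = congruency_effect(summary)
        ce.to_csv(OUT / f"{name}_congruency_effects.csv", index=False)
        print("mean CE_rt by object:",
              ce.groupby("object")["ce_rt"].mean().round(1).to_dict())

        anova = rm_anova(summary, dv="mean_rt", within=["congruency", "object"])
        anova.to_csv(OUT / f"{name}_anova_rt.csv", index=False)
        print(anova.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
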