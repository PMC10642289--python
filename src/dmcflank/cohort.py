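"""Synthetic flanker-task cohorts with the study's within-subject design.

Emulates the behavioral experiments: congruency x object membership (optionally
x proximity), ~112 trials per cell per participant, a 2000 ms response
deadline and a 150 ms fast-response floor.  Group-level generating parameters
default to the best-fitting DMC values of the model in which only the target
drift rate differs between object conditions, so default cohorts land in the
empirical regime (mean RTs roughly 520-565 ms, ~5% errors, a positive
congruency effect that is larger in the same-object condition).

Participant heterogeneity: each participant draws one standardized deviation
per parameter, applied to that parameter's group mean in every condition
(participants who are slow are slow in both conditions; the condition effect
itself is fixed at the group level).  Draws are redrawn until all implied
values lie within the fitting bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import Bounds, DEFAULT_BOUNDS, CONFLICT_PARAMS, SHARED_PARAMS
from .params import DMCParams, SimOptions
from .simulate import (
    STATUS_NONRESPONSE,
    STATUS_OK,
    STATUS_TOO_FAST,
    STATUS_TOO_SLOW,
    TRIAL_COLUMNS,
    simulate_condition,
)

__all__ = [
    "StudyDesign",
    "PopulationSpec",
    "sample_participant_params",
    "generate_cohort",
    "apply_exclusions",
    "exp1_population",
    "exp2_population",
    "exp1_design",
    "exp2_design",
]

_ALL_PARAMS = CONFLICT_PARAMS + SHARED_PARAMS


@dataclass(frozen=True)
class StudyDesign:
    """Within-subject design: congruency x object (x proximity), trial counts."""

    n_participants: int = 40
    trials_per_cell: int = 112
    object_levels: tuple[str, ...] = ("same", "different")
    proximity_levels: tuple[str, ...] = ("near",)  # add "far" for the 3-factor design
    deadline: float = 2000.0
    rt_floor: float = 150.0

    @property
    def sim_options(self) -> SimOptions:
        return SimOptions(deadline=self.deadline, rt_floor=self.rt_floor)

    @property
    def cells(self) -> list[tuple[str, str, str]]:
        return [
            (prox, obj, cong)
            for prox in self.proximity_levels
            for obj in self.object_levels
            for cong in ("congruent", "incongruent")
        ]


@dataclass(frozen=True)
class PopulationSpec:
    """Group-level generating parameters and between-participant dispersion.

    ``condition_means`` maps each (proximity, object) condition to its mean
    DMCParams; parameters outside ``effect_params`` must agree across
    conditions.  ``cv`` is the between-participant coefficient of variation
    applied to every estimated parameter (one shared standardized deviation
    per participant and parameter).  Optional contaminants: a fraction
    ``p_guess`` of trials become fast uniform guesses with chance accuracy.
    """

    condition_means: dict[tuple[str, str], DMCParams]
    effect_params: tuple[str, ...] = ("mu_t",)
    cv: float = 0.15
    p_guess: float = 0.0
    bounds: Bounds = field(default_factory=Bounds)

    def __post_init__(self):
        ps = list(self.condition_means.values())
        for name in _ALL_PARAMS:
            if name in self.effect_params:
                continue
            vals = {round(getattr(p, name), 12) for p in ps}
            if len(vals) > 1:
                raise ValueError(
                    f"parameter {name!r} differs across conditions but is not in effect_params"
                )


def _exp_means(mu_t_same: float, mu_t_diff: float, A: float, tau: float, b: float,
               mu_r: float, sigma_r: float) -> dict[tuple[str, str], DMCParams]:
    shared = dict(A=A, tau=tau, b=b, mu_r=mu_r, sigma_r=sigma_r)
    return {
        ("near", "same"): DMCParams(mu_t=mu_t_same, **shared),
        ("near", "different"): DMCParams(mu_t=mu_t_diff, **shared),
    }


def exp1_population(cv: float = 0.15, p_guess: float = 0.025) -> PopulationSpec:
    """Generating population for the first experiment's near conditions.

    Group means are the best-fitting values of the mu_t-only model: target
    drift 0.58 (same object) vs 0.62 (different object); shared A = 13.8,
    tau = 249 ms, b = 74.5, mu_r = 408 ms, sigma_r = 38 ms.  The small default
    guessing rate emulates the lapses of web-based testing and brings the
    cohort error rate into the empirical ~5% regime.
    """
    return PopulationSpec(
        condition_means=_exp_means(0.58, 0.62, 13.8, 249.0, 74.5, 408.0, 38.0),
        cv=cv, p_guess=p_guess,
    )


def exp2_population(cv: float = 0.15, p_guess: float = 0.025) -> PopulationSpec:
    """Generating population for the second experiment (near flankers only):
    mu_t 0.58 vs 0.64; shared A = 17.8, tau = 254, b = 72.8, mu_r = 413,
    sigma_r = 38."""
    return PopulationSpec(
        condition_means=_exp_means(0.58, 0.64, 17.8, 254.0, 72.8, 413.0, 38.0),
        cv=cv, p_guess=p_guess,
    )


def exp1_design(n_participants: int = 40, trials_per_cell: int = 112) -> StudyDesign:
    return StudyDesign(n_participants=n_participants, trials_per_cell=trials_per_cell)


def exp2_design(n_participants: int = 40, trials_per_cell: int = 112) -> StudyDesign:
    return StudyDesign(n_participants=n_participants, trials_per_cell=trials_per_cell)


def sample_participant_params(
    pop: PopulationSpec, rng: np.random.Generator, max_draws: int = 1000
) -> dict[tuple[str, str], DMCParams]:
    """Draw one participant's condition-specific parameters.

    For each parameter a single standard-normal deviation is drawn and scaled
    by ``cv *`` (the parameter's grand-mean magnitude), shifting that
    parameter's group mean in every condition; the draw is rejected until all
    implied values respect the bounds (truncated sampling).
    """
    conds = list(pop.condition_means)
    out = {c: {} for c in conds}
    for name in _ALL_PARAMS:
        means = {c: getattr(pop.condition_means[c], name) for c in conds}
        scale = pop.cv * abs(np.mean(list(means.values())))
        lo, hi = pop.bounds.get(name)
        for _ in range(max_draws):
            dev = rng.normal(0.0, scale) if scale > 0 else 0.0
            vals = {c: means[c] + dev for c in conds}
            if all(lo <= v <= hi for v in vals.values()):
                break
        else:
            raise RuntimeError(f"could not draw {name!r} within bounds after {max_draws} tries")
        for c in conds:
            out[c][name] = vals[c]
    ref = next(iter(pop.condition_means.values()))
    fixed = dict(sigma=ref.sigma, alpha_s=ref.alpha_s, a_shape=ref.a_shape)
    return {c: DMCParams(**kw, **fixed) for c, kw in out.items()}


def _contaminate(table: pd.DataFrame, p_guess: float, design: StudyDesign,
                 rng: np.random.Generator) -> pd.DataFrame:
    if p_guess <= 0:
        return table
    mask = rng.random(len(table)) < p_guess
    n = int(mask.sum())
    if n == 0:
        return table
    rts = rng.uniform(design.rt_floor, design.deadline, size=n)
    table.loc[mask, "rt_ms"] = rts
    table.loc[mask, "accuracy"] = rng.integers(0, 2, size=n)
    table.loc[mask, "status"] = STATUS_OK
    return table


def generate_cohort(
    design: StudyDesign, pop: PopulationSpec, rng=None
) -> pd.DataFrame:
    """Simulate a full cohort trial table; deterministic under a fixed seed.

    Conditions missing from ``pop.condition_means`` (e.g. far cells when the
    population describes only near ones) must not be requested by the design.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    needed = {(prox, obj) for prox, obj, _ in design.cells}
    missing = needed - set(pop.condition_means)
    if missing:
        raise ValueError(f"population spec lacks generating parameters for cells {sorted(missing)}")
    opts = design.sim_options
    tables = []
    for pid in range(design.n_participants):
        params = sample_participant_params(pop, rng)
        for prox, obj, cong in design.cells:
            t = simulate_condition(
                params[(prox, obj)],
                cong,
                design.trials_per_cell,
                opts,
                rng,
                participant=pid,
                proximity=prox,
                object_membership=obj,
            )
            tables.append(_contaminate(t, pop.p_guess, design, rng))
    return pd.concat(tables, ignore_index=True)[TRIAL_COLUMNS]


def apply_exclusions(trials: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Remove too-slow/too-fast/nonresponse trials; flag errors for RT analyses.

    Returns the included trials with an ``include_rt`` column (False for
    choice errors, which stay available for accuracy analyses) and a report of
    exclusion percentages per category.
    """
    n = len(trials)
    counts = trials["status"].value_counts()
    report = {
        "n_trials": int(n),
        "pct_too_slow": float(100.0 * counts.get(STATUS_TOO_SLOW, 0) / n) if n else 0.0,
        "pct_too_fast": float(100.0 * counts.get(STATUS_TOO_FAST, 0) / n) if n else 0.0,
        "pct_nonresponse": float(100.0 * counts.get(STATUS_NONRESPONSE, 0) / n) if n else 0.0,
    }
    included = trials[trials["status"] == STATUS_OK].copy()
    report["pct_error"] = (
        float(100.0 * (1.0 - included["accuracy"].mean())) if len(included) else 0.0
    )
    included["include_rt"] = included["accuracy"] == 1
    return included, report
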