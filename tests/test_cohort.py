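"""Synthetic cohorts: participant sampling, design bookkeeping, exclusions,
and calibration against the empirical regime."""

import numpy as np
import pandas as pd
import pytest

from dmcflank import (
    PopulationSpec,
    StudyDesign,
    apply_exclusions,
    generate_cohort,
    sample_participant_params,
)
from dmcflank.cohort import exp1_population, exp2_population
from dmcflank.fitting import CONFLICT_PARAMS, SHARED_PARAMS
from dmcflank.params import DMCParams


def test_zero_dispersion_reproduces_group_means():
    pop = exp1_population(cv=0.0)
    rng = np.random.default_rng(0)
    params = sample_participant_params(pop, rng)
    for cond, mean in pop.condition_means.items():
        assert params[cond] == mean


def test_effect_structure_controls_condition_differences():
    pop = exp1_population(cv=0.15)
    rng = np.random.default_rng(1)
    params = sample_participant_params(pop, rng)
    same, diff = params[("near", "same")], params[("near", "different")]
    # only mu_t differs (by exactly the fixed group-level contrast)
    assert same.mu_t != diff.mu_t
    assert diff.mu_t - same.mu_t == pytest.approx(0.62 - 0.58)
    for name in ("A", "tau", "b", "mu_r", "sigma_r"):
        assert getattr(same, name) == getattr(diff, name)
    # an empty effect structure makes both conditions identical
    base = pop.condition_means[("near", "same")]
    pop0 = PopulationSpec(
        condition_means={k: base for k in pop.condition_means}, effect_params=()
    )
    p0 = sample_participant_params(pop0, np.random.default_rng(2))
    assert p0[("near", "same")] == p0[("near", "different")]


def test_mismatched_nuisance_parameter_rejected():
    base = exp1_population().condition_means
    bad = {
        ("near", "same"): base[("near", "same")],
        ("near", "different"): base[("near", "different")].with_(A=20.0),
    }
    with pytest.raises(ValueError, match="effect_params"):
        PopulationSpec(condition_means=bad, effect_params=("mu_t",))


def test_sampled_parameters_respect_bounds():
    pop = exp2_population(cv=0.15)
    rng = np.random.default_rng(3)
    for _ in range(1000):
        for p in sample_participant_params(pop, rng).values():
            assert pop.bounds.contains(p)


def test_cohort_row_count_and_determinism():
    design = StudyDesign(n_participants=3, trials_per_cell=40)
    pop = exp2_population()
    a = generate_cohort(design, pop, np.random.default_rng(4))
    b = generate_cohort(design, pop, np.random.default_rng(4))
    assert len(a) == 3 * 4 * 40  # participants x (2 object x 2 congruency) x trials
    pd.testing.assert_frame_equal(a, b)


def test_missing_condition_parameters_is_an_error():
    design = StudyDesign(n_participants=1, proximity_levels=("near", "far"))
    with pytest.raises(ValueError, match="far"):
        generate_cohort(design, exp2_population(), np.random.default_rng(0))


def test_exclusions_identity_on_clean_table():
    t = pd.DataFrame(
        {"participant": 0, "proximity": "near", "object": "same",
         "congruency": "congruent", "rt_ms": np.linspace(300, 700, 20),
         "accuracy": 1, "status": "ok"}
    )
    inc, rep = apply_exclusions(t)
    assert len(inc) == 20
    assert rep["pct_too_slow"] == rep["pct_too_fast"] == rep["pct_nonresponse"] == 0.0
    assert rep["pct_error"] == 0.0


def test_slow_row_excluded_by_threshold():
    t = pd.DataFrame(
        {"participant": [0, 0], "proximity": "near", "object": "same",
         "congruency": "congruent", "rt_ms": [500.0, 2500.0], "accuracy": [1, 1],
         "status": ["ok", "too_slow"]}
    )
    inc, rep = apply_exclusions(t)
    assert len(inc) == 1
    assert rep["pct_too_slow"] == pytest.approx(50.0)


def test_errors_flagged_for_rt_but_kept_for_pc():
    t = pd.DataFrame(
        {"participant": 0, "proximity": "near", "object": "same",
         "congruency": "congruent", "rt_ms": np.linspace(300, 700, 10),
         "accuracy": [1, 1, 0, 1, 1, 1, 0, 1, 1, 1], "status": "ok"}
    )
    inc, rep = apply_exclusions(t)
    assert len(inc) == 10  # errors stay for accuracy analyses
    assert inc["include_rt"].sum() == 8
    assert rep["pct_error"] == pytest.approx(20.0)


def test_default_cohort_lands_in_the_empirical_regime():
    # mean RTs in the 450-650 ms band, PCs 90-98%, errors in a plausible band
    design = StudyDesign(n_participants=8, trials_per_cell=112)
    coh = generate_cohort(design, exp2_population(), np.random.default_rng(5))
    inc, rep = apply_exclusions(coh)
    mean_rt = inc.loc[inc.accuracy == 1, "rt_ms"].mean()
    assert 450.0 <= mean_rt <= 650.0
    pc = 100.0 * inc["accuracy"].mean()
    assert 90.0 <= pc <= 98.0
    assert 3.0 <= rep["pct_error"] <= 8.0


def test_cohort_ce_direction_same_exceeds_different():
    from dmcflank import cell_summaries, congruency_effect

    design = StudyDesign(n_participants=25, trials_per_cell=112)
    coh = generate_cohort(design, exp2_population(), np.random.default_rng(6))
    inc, _ = apply_exclusions(coh)
    ce = congruency_effect(cell_summaries(inc))
    by_obj = ce.groupby("object")["ce_rt"].mean()
    assert by_obj["same"] > 0
    assert by_obj["different"] > 0


def test_contaminants_inserted_at_requested_rate():
    pop = exp2_population()
    pop_guess = PopulationSpec(condition_means=pop.condition_means, p_guess=0.2)
    design = StudyDesign(n_participants=2, trials_per_cell=200)
    clean = generate_cohort(design, pop, np.random.default_rng(7))
    noisy = generate_cohort(design, pop_guess, np.random.default_rng(7))
    # guesses push accuracy toward chance
    assert noisy["accuracy"].mean() < clean["accuracy"].mean() - 0.03
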