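"""Observed summaries, the G2 statistic, BIC, model specs, and small DE fits."""

import numpy as np
import pandas as pd
import pytest

from dmcflank import (
    ModelSpec,
    all_model_specs,
    bic,
    fit_de,
    g2,
    simulate_condition,
    split_conditions,
    summarize_observed,
)
from dmcflank.fitting import Bounds, DEOptions, CDF_PERCENTILES
from tests.conftest import exp1_params


def trials_frame(rt_con, acc_con, rt_inc, acc_inc):
    rows = []
    for cong, rts, accs in (("congruent", rt_con, acc_con), ("incongruent", rt_inc, acc_inc)):
        for rt, a in zip(rts, accs):
            rows.append({"participant": 0, "proximity": "near", "object": "same",
                         "congruency": cong, "rt_ms": float(rt), "accuracy": int(a),
                         "status": "ok"})
    return pd.DataFrame(rows)


def test_cdf_bin_counts_for_100_correct_trials():
    rng = np.random.default_rng(0)
    rts = rng.gamma(9, 50, 100)
    t = trials_frame(rts, np.ones(100), rng.gamma(9, 55, 100), np.ones(100))
    s = summarize_observed(t)
    assert list(s.congruent.cdf_counts) == [10, 20, 20, 20, 20, 10]
    assert s.congruent.n_correct == 100
    assert s.congruent.caf_n.sum() == 100


def test_error_free_cell_has_zero_caf_errors():
    rng = np.random.default_rng(1)
    t = trials_frame(rng.gamma(9, 50, 60), np.ones(60), rng.gamma(9, 55, 60), np.ones(60))
    s = summarize_observed(t)
    assert np.allclose(s.incongruent.caf_correct, s.incongruent.caf_n)


def test_summary_counts_match_hand_tabulation():
    # 30 trials with known quantile structure: rt = 10, 20, ..., 300, last 5 errors
    rts = np.arange(1, 31) * 10.0
    acc = np.ones(30)
    acc[-5:] = 0
    t = trials_frame(rts, acc, rts + 5.0, acc)
    s = summarize_observed(t)
    cs = s.congruent
    # 25 correct trials -> cuts at the 10/30/50/70/90th percentiles of 10..250
    assert cs.n_correct == 25
    assert cs.cdf_counts.sum() == 25
    expected_cuts = np.quantile(rts[:25], CDF_PERCENTILES)
    assert np.allclose(cs.cdf_cuts, expected_cuts)
    # CAF bins over all 30 included trials: 6 per bin, errors all in the slowest
    assert list(cs.caf_n) == [6, 6, 6, 6, 6]
    assert list(cs.caf_correct) == [6, 6, 6, 6, 1]


def test_g2_zero_for_identical_distributions():
    rng = np.random.default_rng(2)
    acc = (rng.random(200) < 0.93).astype(int)
    t = trials_frame(rng.gamma(9, 50, 200), acc, rng.gamma(9, 55, 200), acc)
    s = summarize_observed(t)
    assert g2(s, t) == pytest.approx(0.0, abs=1e-12)


def test_g2_matches_independent_hand_computation():
    # spreadsheet-style oracle: recompute every bin term with plain Python
    rng = np.random.default_rng(3)
    obs = trials_frame(rng.gamma(9, 50, 40), (rng.random(40) < 0.9).astype(int),
                       rng.gamma(9, 55, 40), (rng.random(40) < 0.85).astype(int))
    pred = trials_frame(rng.gamma(8.5, 52, 80), (rng.random(80) < 0.95).astype(int),
                        rng.gamma(9.5, 53, 80), (rng.random(80) < 0.8).astype(int))
    s = summarize_observed(obs)
    expected = 0.0
    for cong in ("congruent", "incongruent"):
        cs = getattr(s, cong)
        o = obs[(obs.congruency == cong)]
        p = pred[(pred.congruency == cong)]
        p_rt = p["rt_ms"].to_numpy()
        p_acc = p["accuracy"].to_numpy()
        pc_rt = p_rt[p_acc == 1]
        edges = list(cs.cdf_cuts)
        pred_counts = [0] * 6
        for r in pc_rt:
            k = sum(r > e for e in edges)
            pred_counts[k] += 1
        for i in range(6):
            po = cs.cdf_counts[i] / cs.n_correct
            pp = max(pred_counts[i] / len(pc_rt), 1e-10)
            if cs.cdf_counts[i] > 0:
                expected += 2 * cs.cdf_counts[i] * np.log(po / pp)
        caf_edges = list(cs.caf_edges)
        nb = [0] * 5
        cb = [0.0] * 5
        for r, a in zip(p_rt, p_acc):
            k = sum(r >= e for e in caf_edges)
            nb[k] += 1
            cb[k] += a
        for i in range(5):
            pc = cs.caf_correct[i] / cs.caf_n[i]
            phat = min(max(cb[i] / nb[i], 1e-10), 1 - 1e-10)
            for x, q, qh in ((pc, pc, phat), (1 - pc, 1 - pc, 1 - phat)):
                if x > 0:
                    expected += 2 * cs.caf_n[i] * x * np.log(q / qh)
    assert g2(s, pred) == pytest.approx(expected, abs=1e-9)


def test_g2_nonnegative_for_mismatched_distributions():
    rng = np.random.default_rng(4)
    for _ in range(5):
        obs = trials_frame(rng.gamma(9, 50, 60), np.ones(60),
                           rng.gamma(9, 55, 60), np.ones(60))
        pred = trials_frame(rng.gamma(6, 70, 90), np.ones(90),
                            rng.gamma(12, 40, 90), np.ones(90))
        assert g2(summarize_observed(obs), pred) >= 0.0


def test_g2_empty_prediction_is_error():
    rng = np.random.default_rng(5)
    t = trials_frame(rng.gamma(9, 50, 40), np.ones(40), rng.gamma(9, 55, 40), np.ones(40))
    s = summarize_observed(t)
    with pytest.raises(ValueError, match="empty"):
        g2(s, t.iloc[0:0])


def test_insufficient_trials_error_names_cell():
    rng = np.random.default_rng(6)
    t = trials_frame(rng.gamma(9, 50, 40), np.ones(40), rng.gamma(9, 55, 10), np.ones(10))
    with pytest.raises(ValueError, match="incongruent"):
        summarize_observed(t)


def test_bic_closed_form_and_monotone_penalty():
    assert bic(5.0, 0, 100) == 5.0
    assert bic(0.0, 6, np.e) == pytest.approx(6.0, rel=1e-12)
    vals = [bic(10.0, k, 500) for k in range(6, 10)]
    assert np.all(np.diff(vals) > 0)
    with pytest.raises(ValueError):
        bic(1.0, 6, 0)


def test_model_ladder_enumerates_eight_specs():
    specs = all_model_specs()
    assert len(specs) == 8
    assert sorted(s.k for s in specs) == [6, 7, 7, 7, 8, 8, 8, 9]
    assert {s.name for s in specs} == {
        "M_null", "M_mu_t", "M_A", "M_tau", "M_mu_t+A", "M_mu_t+tau", "M_A+tau",
        "M_mu_t+A+tau",
    }
    with pytest.raises(ValueError):
        ModelSpec(("zeta",))


def test_bounds_validation():
    with pytest.raises(ValueError):
        Bounds(mu_t=(1.0, 0.5))
    b = Bounds()
    assert b.contains(exp1_params("same"))
    assert not b.contains(exp1_params("same").with_(tau=499.0, A=41.0))


@pytest.fixture(scope="module")
def two_condition_data():
    same = exp1_params("same").with_(mu_t=0.40)
    diff = exp1_params("same").with_(mu_t=0.90)
    rng = np.random.default_rng(77)
    return {
        cond: pd.concat(
            [simulate_condition(p, c, 600, rng=rng, object_membership=cond)
             for c in ("congruent", "incongruent")],
            ignore_index=True,
        )
        for cond, p in (("same", same), ("different", diff))
    }


MICRO_DE = DEOptions(popsize=4, maxiter=20, improvement_window=8,
                     common_random_numbers=True, refine_iters=5)


def test_fit_is_deterministic_under_fixed_seed(two_condition_data):
    a = fit_de(two_condition_data, ModelSpec(("mu_t",)), n_sim=400,
               de_options=MICRO_DE, seed=5, n_sim_final=800)
    b = fit_de(two_condition_data, ModelSpec(("mu_t",)), n_sim=400,
               de_options=MICRO_DE, seed=5, n_sim_final=800)
    assert a.params_by_condition == b.params_by_condition
    assert a.g2_by_condition == b.g2_by_condition
    assert a.mean_bic == b.mean_bic


def test_freeing_the_truly_varying_parameter_lowers_g2(two_condition_data):
    # a large mu_t difference: the null model cannot absorb it
    null = fit_de(two_condition_data, ModelSpec(()), n_sim=400,
                  de_options=MICRO_DE, seed=6, n_sim_final=2000)
    free = fit_de(two_condition_data, ModelSpec(("mu_t",)), n_sim=400,
                  de_options=MICRO_DE, seed=6, n_sim_final=2000)
    assert sum(free.g2_by_condition.values()) < sum(null.g2_by_condition.values())
    assert free.mean_bic < null.mean_bic


def test_fit_requires_two_conditions(two_condition_data):
    with pytest.raises(ValueError, match="2 conditions"):
        fit_de({"same": two_condition_data["same"]}, ModelSpec(()))


def test_recovery_study_report_structure():
    from dmcflank.fitting import recovery_study, recovery_summary

    truth = {
        "same": exp1_params("same").with_(mu_t=0.45),
        "different": exp1_params("same").with_(mu_t=0.80),
    }
    report = recovery_study(truth, ModelSpec(("mu_t",)), n_trials=300, n_reps=2,
                            n_sim=300, de_options=MICRO_DE, seed=3, n_sim_final=600)
    # one row per replicate x condition x parameter
    assert len(report) == 2 * 2 * 6
    assert set(report["param"]) == {"mu_t", "A", "tau", "b", "mu_r", "sigma_r"}
    assert (report.groupby("param")["rep"].nunique() == 2).all()
    summ = recovery_summary(report)
    assert {"bias", "rmse"} <= set(summ.columns)
    assert (summ["rmse"] >= summ["bias"].abs() - 1e-9).all()
    with pytest.raises(ValueError, match="bounds"):
        recovery_study({"same": exp1_params("same").with_(A=41.0, tau=499.0),
                        "different": exp1_params("different")},
                       ModelSpec(()), n_trials=100, n_reps=1)


def test_split_conditions_round_trip(two_condition_data):
    merged = pd.concat(two_condition_data.values(), ignore_index=True)
    parts = split_conditions(merged)
    assert set(parts) == {"same", "different"}
    assert sum(len(v) for v in parts.values()) == len(merged)
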