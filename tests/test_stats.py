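"""Cell summaries, congruency effects, paired t, RM-ANOVA, within-subject SE."""

import numpy as np
import pandas as pd
import pytest

from dmcflank import (
    cell_summaries,
    congruency_effect,
    paired_t,
    rm_anova,
    within_subject_se,
)
from dmcflank.stats import rm_anova_cube


def toy_trials():
    # one participant, hand-checkable values
    rows = []
    for cong, rts, accs in [
        ("congruent", [400, 500, 600, 450], [1, 1, 1, 0]),
        ("incongruent", [520, 580, 640], [1, 1, 0]),
    ]:
        for rt, a in zip(rts, accs):
            rows.append(
                {"participant": 0, "proximity": "near", "object": "same",
                 "congruency": cong, "rt_ms": rt, "accuracy": a, "status": "ok"}
            )
    return pd.DataFrame(rows)


def test_cell_summaries_match_hand_computation():
    s = cell_summaries(toy_trials()).set_index("congruency")
    # RT mean over correct trials only; PC over all included trials
    assert s.loc["congruent", "mean_rt"] == pytest.approx((400 + 500 + 600) / 3)
    assert s.loc["congruent", "pc"] == pytest.approx(3 / 4)
    assert s.loc["incongruent", "mean_rt"] == pytest.approx((520 + 580) / 2)
    assert s.loc["incongruent", "pc"] == pytest.approx(2 / 3)
    assert int(s.loc["congruent", "n_included"]) == 4


def test_empty_cell_marked_missing_not_zero():
    t = toy_trials()
    t2 = t.copy()
    t2["participant"] = 1
    t2 = t2[t2.congruency == "congruent"]  # participant 1 misses a cell
    s = cell_summaries(pd.concat([t, t2], ignore_index=True))
    cell = s[(s.participant == 1) & (s.congruency == "incongruent")]
    assert len(cell) == 1
    assert cell["mean_rt"].isna().all()


def test_congruency_effect_identity_and_shift():
    s = cell_summaries(toy_trials())
    ce = congruency_effect(s)
    assert ce["ce_rt"].iloc[0] == pytest.approx(550 - 500)
    assert ce["ce_pc"].iloc[0] == pytest.approx(3 / 4 - 2 / 3)
    # identical congruency cells -> CE exactly 0
    s2 = s.copy()
    s2.loc[:, ["mean_rt", "pc"]] = [[500.0, 0.9], [500.0, 0.9]]
    ce2 = congruency_effect(s2)
    assert ce2["ce_rt"].iloc[0] == 0.0
    assert ce2["ce_pc"].iloc[0] == 0.0


def test_paired_t_closed_form_and_guards():
    x = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
    y = np.array([2.0, 2.5, 4.0, 4.5, 7.5])
    d = x - y
    r = paired_t(x, y)
    assert r.statistic == pytest.approx(d.mean() / (d.std(ddof=1) / np.sqrt(5)))
    assert r.effect_size == pytest.approx(d.mean() / d.std(ddof=1))
    assert r.df == 4


def test_paired_t_zero_variance_is_error():
    with pytest.raises(ValueError, match="zero variance"):
        paired_t(np.array([1.0, 2, 3, 4]), np.array([2.0, 3, 4, 5]))


def test_paired_t_equal_vectors_also_degenerate():
    with pytest.raises(ValueError):
        paired_t(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))


def _random_within_data(rng, n=12, l1=2, l2=2):
    subj = rng.normal(0, 5, size=(n, 1, 1))
    eff = rng.normal(0, 1, size=(1, l1, l2))
    y = 20 + subj + eff + rng.normal(0, 2, size=(n, l1, l2))
    rows = []
    for s in range(n):
        for i in range(l1):
            for j in range(l2):
                rows.append({"participant": s, "f1": f"a{i}", "f2": f"b{j}", "y": y[s, i, j]})
    return pd.DataFrame(rows), y


def test_rm_anova_agrees_with_statsmodels():
    from statsmodels.stats.anova import AnovaRM

    df, _ = _random_within_data(np.random.default_rng(10))
    ours = rm_anova(df, dv="y", within=["f1", "f2"]).set_index("effect")
    ref = AnovaRM(df, depvar="y", subject="participant", within=["f1", "f2"]).fit()
    rtab = ref.anova_table
    for eff_ref, eff_ours in [("f1", "f1"), ("f2", "f2"), ("f1:f2", "f1:f2")]:
        assert ours.loc[eff_ours, "F"] == pytest.approx(rtab.loc[eff_ref, "F Value"], rel=1e-8)
        assert ours.loc[eff_ours, "p"] == pytest.approx(rtab.loc[eff_ref, "Pr > F"], abs=1e-10)
        assert ours.loc[eff_ours, "df1"] == rtab.loc[eff_ref, "Num DF"]
        assert ours.loc[eff_ours, "df2"] == rtab.loc[eff_ref, "Den DF"]


def test_2x2_interaction_equals_squared_paired_t():
    df, y = _random_within_data(np.random.default_rng(11))
    ours = rm_anova(df, dv="y", within=["f1", "f2"]).set_index("effect")
    dd = (y[:, 0, 0] - y[:, 0, 1]) - (y[:, 1, 0] - y[:, 1, 1])
    t = dd.mean() / (dd.std(ddof=1) / np.sqrt(len(dd)))
    assert ours.loc["f1:f2", "F"] == pytest.approx(t**2, rel=1e-10)


def test_f_invariant_to_additive_constant_and_ss_decomposition():
    df, y = _random_within_data(np.random.default_rng(12))
    a = rm_anova(df, dv="y", within=["f1", "f2"])
    df2 = df.copy()
    df2["y"] = df2["y"] + 123.4
    b = rm_anova(df2, dv="y", within=["f1", "f2"])
    assert np.allclose(a["F"], b["F"])
    # effect + error SS account for all non-subject variation
    total_ss = float(((y - y.mean()) ** 2).sum())
    subj_ss = float((y.shape[1] * y.shape[2] * (y.mean(axis=(1, 2)) - y.mean()) ** 2).sum())
    assert a["ss"].sum() + a["ss_error"].sum() + subj_ss == pytest.approx(total_ss)


def test_rm_anova_rejects_incomplete_design():
    df, _ = _random_within_data(np.random.default_rng(13))
    with pytest.raises(ValueError, match="incomplete"):
        rm_anova(df.iloc[:-1], dv="y", within=["f1", "f2"])


def test_null_p_values_uniform():
    rng = np.random.default_rng(14)
    y = rng.normal(size=(2000, 20, 2, 2))
    res = rm_anova_cube(y, ["f1", "f2"])
    for eff in ("f1", "f2", "f1:f2"):
        p = res[eff]["p"]
        assert np.mean(p) == pytest.approx(0.5, abs=0.03)
        assert np.mean(p < 0.05) == pytest.approx(0.05, abs=0.02)


def test_within_subject_se_removes_participant_offsets():
    rng = np.random.default_rng(15)
    profile = np.array([500.0, 520.0, 540.0])
    offsets = rng.normal(0, 50, size=12)
    mat = profile[None, :] + offsets[:, None]
    se = within_subject_se(mat)
    assert np.allclose(se, 0.0, atol=1e-10)


def test_within_subject_se_toy_matches_hand_value():
    mat = np.array([[1.0, 3.0], [2.0, 6.0], [3.0, 6.0]])
    centered = mat - mat.mean(axis=1, keepdims=True) + mat.mean()
    expected = centered.std(axis=0, ddof=1) / np.sqrt(3) * np.sqrt(2.0)
    assert np.allclose(within_subject_se(mat), expected)
    # and the hand value of the first condition:
    # centered col0 = [1-2, 2-4, 3-4.5] + 3.5 = [2.5, 1.5, 2.0]; sd = 0.5
    assert within_subject_se(mat)[0] == pytest.approx(0.5 / np.sqrt(3) * np.sqrt(2.0))


def test_single_condition_se_is_error():
    with pytest.raises(ValueError):
        within_subject_se(np.ones((5, 1)))
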