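"""Behavioral summary statistics: cell means, congruency effects, paired t,
repeated-measures ANOVA, and within-subject standard errors.

The ANOVA is the classical fully-within-subject decomposition for balanced
complete designs: each effect is tested against its interaction with the
subject factor.  The sums of squares are computed by Moebius inversion over
marginal means, which makes the core a handful of array reductions and lets
the same code score thousands of simulated null datasets for calibration
checks.  All design factors in the studies emulated here have two levels, so
sphericity corrections are moot (the tests are exact at two levels).

Within-subject standard errors follow the participant-mean-centering approach
with the bias correction factor sqrt(C / (C - 1)) for C conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "cell_summaries",
    "congruency_effect",
    "paired_t",
    "rm_anova",
    "rm_anova_cube",
    "within_subject_se",
]

_FACTORS = ["proximity", "object", "congruency"]


@dataclass(frozen=True)
class TestResult:
    """A single test statistic with df, p-value and effect size.

    ``effect_size`` is Cohen's d_z (mean difference / SD of differences) for
    paired t tests and partial eta squared for ANOVA effects.
    """

    statistic: float
    df: float | tuple[float, float]
    p: float
    effect_size: float
    kind: str = "t"


def _present_factors(trials: pd.DataFrame) -> list[str]:
    return [f for f in _FACTORS if f in trials.columns and trials[f].nunique() > 0]


def cell_summaries(trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant x design cell: mean correct RT, PC, included counts.

    Expects exclusions to have been applied (status-ok trials only).  PC is
    computed over all included trials, mean RT over correct trials only.
    Cells present in the design but empty for a participant appear with NaN.
    """
    factors = _present_factors(trials)
    keys = ["participant"] + factors
    g = trials.groupby(keys, sort=True, observed=True)
    out = g.agg(
        n_included=("accuracy", "size"),
        n_correct=("accuracy", "sum"),
        pc=("accuracy", "mean"),
    )
    rt = trials[trials["accuracy"] == 1].groupby(keys, sort=True, observed=True)["rt_ms"].mean()
    out["mean_rt"] = rt
    # explicit NaN markers for empty cells of the full design
    full = pd.MultiIndex.from_product(
        [trials[k].unique() for k in keys], names=keys
    )
    out = out.reindex(full)
    return out.reset_index()


def congruency_effect(summary: pd.DataFrame) -> pd.DataFrame:
    """Congruency effects per participant and cell pair.

    CE_RT = mean RT incongruent - congruent (ms); CE_PC = PC congruent -
    PC incongruent (proportion).
    """
    factors = [f for f in ("proximity", "object") if f in summary.columns]
    keys = ["participant"] + factors
    wide_rt = summary.pivot_table(index=keys, columns="congruency", values="mean_rt")
    wide_pc = summary.pivot_table(index=keys, columns="congruency", values="pc")
    for w in (wide_rt, wide_pc):
        if not {"congruent", "incongruent"} <= set(w.columns):
            raise ValueError("both congruency levels are required in every cell pair")
    out = pd.DataFrame(
        {
            "ce_rt": wide_rt["incongruent"] - wide_rt["congruent"],
            "ce_pc": wide_pc["congruent"] - wide_pc["incongruent"],
        }
    )
    return out.reset_index()


def paired_t(x, y) -> TestResult:
    """Two-sided paired t test with Cohen's d_z."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired_t expects two matched 1-d vectors")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values in paired vectors")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences: paired t is undefined")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TestResult(statistic=float(t), df=n - 1, p=float(p), effect_size=float(d.mean() / sd), kind="t")


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA (balanced, fully within-subject)
# ---------------------------------------------------------------------------


def rm_anova_cube(y: np.ndarray, factor_names: list[str]) -> dict[str, dict[str, np.ndarray]]:
    """Within-subject ANOVA on an array of cell means.

    ``y`` has shape ``(..., n_subjects, L1, ..., Lm)`` for m within factors;
    leading axes are independent replicate datasets (vectorized).  Returns a
    mapping effect-name -> dict of arrays (ss, ss_err, df1, df2, F, p, pes).
    """
    y = np.asarray(y, dtype=float)
    m = len(factor_names)
    if y.ndim < m + 1:
        raise ValueError("y must have a subject axis plus one axis per factor")
    if np.isnan(y).any():
        raise ValueError("missing cells: the design must be complete and balanced")
    design_axes = tuple(range(y.ndim - m - 1, y.ndim))  # subject + factors
    sizes = {ax: y.shape[ax] for ax in design_axes}
    n_total = int(np.prod([sizes[a] for a in design_axes]))
    subj_ax = design_axes[0]
    factor_ax = {factor_names[i]: design_axes[1 + i] for i in range(m)}

    def u(axes: frozenset) -> np.ndarray:
        comp = tuple(a for a in design_axes if a not in axes)
        means = y.mean(axis=comp, keepdims=True) if comp else y
        mult = n_total / np.prod([sizes[a] for a in axes]) if axes else float(n_total)
        return mult * np.square(means).sum(axis=design_axes)

    cache: dict[frozenset, np.ndarray] = {}

    def ss(axes: frozenset) -> np.ndarray:
        key = axes
        if key in cache:
            return cache[key]
        total = u(axes).copy()
        for r in range(len(axes)):
            for sub in combinations(sorted(axes), r):
                total -= ss(frozenset(sub))
        total -= 0.0 if axes else 0.0
        cache[key] = total
        return total

    # seed the recursion with the grand-mean term
    cache[frozenset()] = u(frozenset())

    results: dict[str, dict[str, np.ndarray]] = {}
    n_subj = sizes[subj_ax]
    for r in range(1, m + 1):
        for combo in combinations(factor_names, r):
            eff_axes = frozenset(factor_ax[f] for f in combo)
            ss_eff = ss(eff_axes)
            ss_err = ss(eff_axes | {subj_ax})
            df1 = int(np.prod([sizes[factor_ax[f]] - 1 for f in combo]))
            df2 = df1 * (n_subj - 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                f_stat = (ss_eff / df1) / (ss_err / df2)
                pes = ss_eff / (ss_eff + ss_err)
            results[":".join(combo)] = {
                "ss": ss_eff,
                "ss_err": ss_err,
                "df1": df1,
                "df2": df2,
                "F": f_stat,
                "p": sps.f.sf(f_stat, df1, df2),
                "pes": pes,
            }
    return results


def rm_anova(
    summary: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "participant",
) -> pd.DataFrame:
    """Repeated-measures ANOVA of a per-participant cell-mean table.

    Requires a complete balanced within-subject design (one value per subject
    and factor-level combination).  Returns one row per effect with F, df,
    p and partial eta squared.
    """
    levels = [np.sort(summary[f].unique()) for f in within]
    subjects = np.sort(summary[subject].unique())
    pivot = summary.pivot_table(index=subject, columns=within, values=dv)
    expected = pd.MultiIndex.from_product(levels, names=within) if len(within) > 1 else pd.Index(levels[0], name=within[0])
    pivot = pivot.reindex(index=subjects, columns=expected)
    if pivot.isna().any().any():
        raise ValueError("incomplete design: every subject needs every cell exactly once")
    cube = pivot.to_numpy().reshape(len(subjects), *[len(l) for l in levels])
    res = rm_anova_cube(cube, within)
    rows = [
        {
            "effect": name,
            "df1": r["df1"],
            "df2": r["df2"],
            "F": float(r["F"]),
            "p": float(r["p"]),
            "eta_p2": float(r["pes"]),
            "ss": float(r["ss"]),
            "ss_error": float(r["ss_err"]),
        }
        for name, r in res.items()
    ]
    return pd.DataFrame(rows)


def within_subject_se(matrix) -> np.ndarray:
    """Within-subject SE of the mean per condition (Cousineau-Morey).

    ``matrix`` is participants x conditions.  Each participant's mean is
    removed (and the grand mean restored) before computing per-condition SDs;
    the result is scaled by sqrt(C / (C - 1)) for C conditions.
    """
    y = np.asarray(matrix, dtype=float)
    if y.ndim != 2:
        raise ValueError("expected a participants x conditions matrix")
    n, c = y.shape
    if c < 2:
        raise ValueError("within-subject SE requires at least 2 conditions")
    centered = y - y.mean(axis=1, keepdims=True) + y.mean()
    morey = np.sqrt(c / (c - 1.0))
    return centered.std(axis=0, ddof=1) / np.sqrt(n) * morey
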