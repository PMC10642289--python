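"""Distributional analyses: RT deciles, delta functions, CAFs, delta regression.

The RT delta function plots the congruency effect (RT_incongruent -
RT_congruent) at the nine matched deciles against response speed; its slope is
read as the time course of distractor activation and its intercept, after
centering on the participant's mean RT, as the predicted congruency effect at
that mean RT.  The conditional accuracy function (CAF) reports accuracy in
five equal-count RT bins; fast errors show up as reduced accuracy in the
fastest bin.  All quantiles use type-7 (linear) interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DeltaFunction",
    "CAF",
    "DeltaRegression",
    "rt_deciles",
    "delta_function_rt",
    "caf",
    "delta_function_pc",
    "delta_regression",
    "DECILE_PROBS",
    "N_CAF_BINS",
]

DECILE_PROBS = np.arange(1, 10) / 10.0
N_CAF_BINS = 5
_MIN_DECILE_N = 9  # nine deciles need at least nine order statistics
_MIN_CAF_N = 25


@dataclass(frozen=True)
class DeltaFunction:
    """Per-decile congruent / incongruent RTs, their difference and midpoint."""

    decile_probs: np.ndarray
    rt_congruent: np.ndarray
    rt_incongruent: np.ndarray

    @property
    def delta(self) -> np.ndarray:
        return self.rt_incongruent - self.rt_congruent

    @property
    def xmid(self) -> np.ndarray:
        return (self.rt_incongruent + self.rt_congruent) / 2.0


@dataclass(frozen=True)
class CAF:
    """Conditional accuracy function over five equal-count RT bins."""

    bin_edges: np.ndarray  # 4 inner quintile edges (ms)
    accuracy_per_bin: np.ndarray  # 5 proportions
    counts_per_bin: np.ndarray  # 5 counts, sum to included trials


@dataclass(frozen=True)
class DeltaRegression:
    """OLS line through the nine delta points, centered on ``center_rt``."""

    slope: float
    intercept: float  # predicted congruency effect (ms) at center_rt
    center_rt: float


def rt_deciles(rts) -> np.ndarray:
    """The nine RT deciles (0.1 ... 0.9), type-7 linear interpolation."""
    rts = np.asarray(rts, dtype=float)
    if rts.size < _MIN_DECILE_N:
        raise ValueError(
            f"need at least {_MIN_DECILE_N} observations for deciles, got {rts.size}"
        )
    return np.quantile(rts, DECILE_PROBS)  # numpy default = type 7


def delta_function_rt(congruent_rts, incongruent_rts) -> DeltaFunction:
    """Delta function from correct-trial RTs of the two congruencies."""
    return DeltaFunction(
        decile_probs=DECILE_PROBS.copy(),
        rt_congruent=rt_deciles(congruent_rts),
        rt_incongruent=rt_deciles(incongruent_rts),
    )


def _quintile_bins(rts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign trials to 5 equal-count bins by their own RT quintiles."""
    edges = np.quantile(rts, np.arange(1, N_CAF_BINS) / N_CAF_BINS)
    idx = np.searchsorted(edges, rts, side="left")
    return idx, edges


def caf(trials: pd.DataFrame, bin_edges=None) -> CAF:
    """CAF for one congruency's included trials (correct and error together).

    Bins are the congruency's own RT quintiles unless explicit ``bin_edges``
    (4 inner edges) are supplied, e.g. to bin model predictions by the
    observed edges.
    """
    rts = trials["rt_ms"].to_numpy(dtype=float)
    acc = trials["accuracy"].to_numpy(dtype=float)
    if rts.size < _MIN_CAF_N:
        raise ValueError(f"need at least {_MIN_CAF_N} included trials for a CAF, got {rts.size}")
    if bin_edges is None:
        idx, edges = _quintile_bins(rts)
    else:
        edges = np.asarray(bin_edges, dtype=float)
        idx = np.searchsorted(edges, rts, side="left")
    counts = np.bincount(idx, minlength=N_CAF_BINS).astype(np.int64)
    correct = np.bincount(idx, weights=acc, minlength=N_CAF_BINS)
    with np.errstate(invalid="ignore"):
        acc_bin = np.where(counts > 0, correct / np.maximum(counts, 1), np.nan)
    return CAF(bin_edges=edges, accuracy_per_bin=acc_bin, counts_per_bin=counts)


def delta_function_pc(congruent: pd.DataFrame, incongruent: pd.DataFrame) -> np.ndarray:
    """PC congruency effect (PC_congruent - PC_incongruent) in 5 RT bins.

    Each congruency is binned by its own quintiles; the difference is taken
    between corresponding bins.
    """
    c = caf(congruent)
    i = caf(incongruent)
    return c.accuracy_per_bin - i.accuracy_per_bin


def participant_delta_analysis(
    trials: pd.DataFrame,
    by: tuple[str, ...] = ("proximity", "object"),
    center: str = "pair",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Delta functions and their regressions per participant x condition.

    ``trials`` must already be exclusion-filtered (status ok); only correct
    trials enter the RT deciles.  ``center`` picks the centering RT of the
    regression: "pair" (default) centers each delta function on the
    participant's mean correct RT over the two congruency cells entering it,
    "grand" on the participant's mean correct RT over all cells.

    Returns ``(deltas, regressions)``: one row per participant x condition x
    decile, and one row per participant x condition with slope/intercept.
    """
    by = [b for b in by if b in trials.columns]
    correct = trials[trials["accuracy"] == 1]
    delta_rows, reg_rows = [], []
    for pid, ptab in correct.groupby("participant"):
        grand_mean = ptab["rt_ms"].mean()
        for cond, cell in ptab.groupby(list(by)) if by else [((), ptab)]:
            cond = cond if isinstance(cond, tuple) else (cond,)
            con = cell.loc[cell["congruency"] == "congruent", "rt_ms"].to_numpy()
            inc = cell.loc[cell["congruency"] == "incongruent", "rt_ms"].to_numpy()
            df = delta_function_rt(con, inc)
            center_rt = cell["rt_ms"].mean() if center == "pair" else grand_mean
            reg = delta_regression(df, center_rt)
            base = {"participant": pid, **dict(zip(by, cond))}
            for p, rc, ri in zip(df.decile_probs, df.rt_congruent, df.rt_incongruent):
                delta_rows.append(
                    {**base, "decile": p, "rt_congruent": rc, "rt_incongruent": ri,
                     "delta": ri - rc, "xmid": (ri + rc) / 2.0}
                )
            reg_rows.append(
                {**base, "slope": reg.slope, "intercept": reg.intercept, "center_rt": reg.center_rt}
            )
    return pd.DataFrame(delta_rows), pd.DataFrame(reg_rows)


def delta_regression(df: DeltaFunction, center_rt: float) -> DeltaRegression:
    """OLS of delta on (xmid - center_rt); intercept = predicted CE at center_rt."""
    x = df.xmid - float(center_rt)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate delta function: all decile midpoints equal")
    res = sps.linregress(x, df.delta)
    return DeltaRegression(slope=float(res.slope), intercept=float(res.intercept), center_rt=float(center_rt))
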