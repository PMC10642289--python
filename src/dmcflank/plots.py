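"""Optional figures: cohort-mean delta functions and CAFs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_delta_functions", "plot_caf"]


def plot_delta_functions(deltas: pd.DataFrame, path) -> None:
    """Cohort-mean RT delta (ms) against mean decile RT, one line per condition."""
    fig, ax = plt.subplots(figsize=(5, 4))
    group_cols = [c for c in ("proximity", "object") if c in deltas.columns]
    agg = deltas.groupby(group_cols + ["decile"])[["xmid", "delta"]].mean().reset_index()
    for cond, sub in agg.groupby(group_cols):
        label = "-".join(map(str, cond)) if isinstance(cond, tuple) else str(cond)
        ax.plot(sub["xmid"], sub["delta"], "o-", label=label)
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.set_xlabel("mean decile RT (ms)")
    ax.set_ylabel("RT delta (ms)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_caf(caf_table: pd.DataFrame, path) -> None:
    """Cohort-mean conditional accuracy per RT bin and congruency."""
    fig, ax = plt.subplots(figsize=(5, 4))
    group_cols = [c for c in ("object", "congruency") if c in caf_table.columns]
    agg = caf_table.groupby(group_cols + ["bin"])["accuracy"].mean().reset_index()
    for cond, sub in agg.groupby(group_cols):
        label = "-".join(map(str, cond)) if isinstance(cond, tuple) else str(cond)
        ax.plot(sub["bin"] + 1, sub["accuracy"], "o-", label=label)
    ax.set_xlabel("RT bin (fast to slow)")
    ax.set_ylabel("proportion correct")
    ax.set_ylim(0.5, 1.0)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
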