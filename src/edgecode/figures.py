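"""Quick-look figures rendered from the summary tables.

Styling is utilitarian; these plots exist to eyeball the pipeline's outputs
(accuracy versus speed, kernel difference curves, the confusion matrix), not
to reproduce any publication layout.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

_TYPE_COLORS = {"FA-1": "tab:red", "SA-1": "tab:blue"}


def _ax(figsize=(5, 3.5)):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt.subplots(figsize=figsize)


def plot_accuracy_vs_speed(summary: pd.DataFrame, scheme: str, path: str | Path) -> None:
    """Mean accuracy ± SEM per neuron type as a function of core speed."""
    fig, ax = _ax()
    sub = summary[(summary["scheme"] == scheme) & summary["core_speed"].notna()]
    for ntype, g in sub.groupby("type"):
        g = g.sort_values("core_speed")
        color = _TYPE_COLORS.get(str(ntype))
        ax.plot(g["core_speed"], g["mean_accuracy"], "-o", color=color, label=str(ntype))
        ax.fill_between(
            g["core_speed"],
            g["mean_accuracy"] - g["sem"],
            g["mean_accuracy"] + g["sem"],
            alpha=0.25,
            color=color,
        )
    if len(sub):
        ax.axhline(sub["chance"].iloc[0], ls="--", c="k", lw=0.8, label="chance")
    ax.set(xlabel="scanning speed (mm/s)", ylabel="proportion correct", title=scheme)
    ax.set_xscale("log")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    _close(fig)


def plot_kernel_curves(curves: pd.DataFrame, path: str | Path) -> None:
    """Same/different-orientation correlation difference versus kernel SD."""
    fig, ax = _ax()
    for ntype, g in curves.groupby("type"):
        m = g.groupby("sigma_um")["diff"].mean()
        ax.plot(m.index, m.values, "-o", color=_TYPE_COLORS.get(str(ntype)), label=str(ntype))
    ax.set(
        xlabel="kernel SD (µm)",
        ylabel="R² same − R² different",
        xscale="log",
    )
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    _close(fig)


def plot_confusion(matrix: np.ndarray, labels, path: str | Path) -> None:
    """Orientation × speed confusion matrix (rows: stimuli, columns: choices)."""
    fig, ax = _ax(figsize=(6, 5.5))
    im = ax.imshow(matrix, cmap="viridis", vmin=0, vmax=1)
    ticks = [i for i, (v, th) in enumerate(labels) if th == labels[0][1]]
    ax.set_xticks(ticks, [f"{v:g}" for v, _ in (labels[i] for i in ticks)], fontsize=7)
    ax.set_yticks(ticks, [f"{v:g}" for v, _ in (labels[i] for i in ticks)], fontsize=7)
    ax.set(xlabel="reference speed (mm/s)", ylabel="stimulus speed (mm/s)")
    fig.colorbar(im, ax=ax, label="P(assigned orientation)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    _close(fig)


def _close(fig) -> None:
    import matplotlib.pyplot as plt

    plt.close(fig)
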