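"""Plots of the ontology kinetic profiles (independent and cumulative
panels) and a simple class-ordered expression heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .kinetics import KineticProfile

__all__ = ["plot_kinetics", "plot_heatmap"]


def plot_kinetics(profiles: list[KineticProfile], path: str | Path | None = None):
    """Two panels: per-interval mean change (left) and cumulative change
    anchored at baseline (right), one line per ontology family."""
    fig, (ax_ind, ax_cum) = plt.subplots(1, 2, figsize=(11, 4), sharex=True)
    for kp in profiles:
        x = np.arange(len(kp.transitions))
        ax_ind.plot(x, kp.mean_change, marker="o", label=kp.family)
        ax_cum.plot(x, kp.cumulative, marker="o", label=kp.family)
    for ax, title in ((ax_ind, "per interval"), (ax_cum, "cumulative")):
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_title(f"Mean expression change ({title})")
        ax.set_ylabel("mean log10 change")
        if profiles:
            ax.set_xticks(np.arange(len(profiles[0].transitions)))
            ax.set_xticklabels(profiles[0].transitions, rotation=45, ha="right")
    ax_cum.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_heatmap(heatmap, path: str | Path | None = None):
    """Proteins x conditions matrix image, rows already grouped by
    whole-protocol class."""
    fig, ax = plt.subplots(figsize=(5, 8))
    im = ax.imshow(heatmap.to_numpy(), aspect="auto", cmap="bwr",
                   vmin=-1.0, vmax=1.0)
    ax.set_xticks(np.arange(heatmap.shape[1]))
    ax.set_xticklabels(heatmap.columns)
    ax.set_yticks([])
    ax.set_xlabel("condition")
    fig.colorbar(im, ax=ax, label="mean log10 normalized ratio")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
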