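"""Minimal figure helpers (distance-map heat maps, folding curves)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_distance_map(dmap, topo=None, path=None, title=None):
    """Heat map of a mean pairwise-distance matrix, PREs marked on the axes."""
    fig, ax = plt.subplots(figsize=(5, 4.4))
    im = ax.imshow(dmap.matrix, origin="lower", cmap="viridis_r")
    fig.colorbar(im, ax=ax, label="mean 3D distance (sigma)")
    if topo is not None:
        for p in topo.pre_indices:
            ax.plot(p - 1, -1.5, marker="o", mfc="none", mec="k", ms=4, clip_on=False)
    ax.set_xlabel("bead index")
    ax.set_ylabel("bead index")
    if title:
        ax.set_title(title)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_folding_curve(summary, path=None):
    """Mean V/Vref vs pb_pre with confidence intervals."""
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    x = summary.iloc[:, 0].to_numpy()
    y = summary["mean"].to_numpy()
    yerr = np.vstack([y - summary["ci_low"], summary["ci_high"] - y])
    ax.errorbar(x, y, yerr=yerr, fmt="o-", capsize=3)
    ax.axhline(1.0, ls=":", c="gray")
    ax.set_xlabel(summary.columns[0])
    ax.set_ylabel("V / Vref")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
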