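"""Figure rendering: histogram + mixture overlays and population heatmaps."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .histmix import FretHistogram, MixtureFit
from .heatmap import Heatmap


def plot_histogram_fit(hist: FretHistogram, fit: Optional[MixtureFit],
                       path, title: str = "") -> Path:
    """Density bars with the fitted components and their sum."""
    fig, ax = plt.subplots(figsize=(4.5, 3))
    ax.bar(hist.centers, hist.densities, width=hist.widths, color="0.8",
           edgecolor="0.6", linewidth=0.3, label="data")
    if fit is not None:
        x = np.linspace(hist.bin_edges[0], hist.bin_edges[-1], 400)
        for mu, sd, w in zip(fit.means, fit.sds, fit.weights):
            comp = w * np.exp(-0.5 * ((x - mu) / sd) ** 2) / \
                (sd * np.sqrt(2 * np.pi))
            ax.plot(x, comp, lw=1, ls="--")
        ax.plot(x, fit.density(x), "k-", lw=1.5, label=f"K={fit.K} fit")
    ax.set_xlabel("FRET efficiency")
    ax.set_ylabel("density")
    ax.set_xlim(-0.1, 1.2)
    if title:
        ax.set_title(title, fontsize=10)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_heatmap(heat: Heatmap, path, normalized: bool = True,
                 title: str = "") -> Path:
    """FRET-vs-time occupancy map (column-normalized by default)."""
    fig, ax = plt.subplots(figsize=(5, 3))
    counts = heat.column_normalized() if normalized else heat.counts
    ax.pcolormesh(heat.time_edges, heat.fret_edges, counts, cmap="viridis")
    ax.set_xlabel("time (s)" + (" from sync" if heat.sync_mode != "none"
                                else ""))
    ax.set_ylabel("FRET efficiency")
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
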