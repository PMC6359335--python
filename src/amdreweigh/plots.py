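"""Minimal figure helpers (PNG output, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .amd import PMFGrid
from .convergence import KLDSeries


def plot_pmf(grid: PMFGrid, path, title: str = "") -> None:
    """Heat map of a 2D PMF (or line plot of a 1D profile)."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    if grid.ndim == 1:
        ax.plot(grid.centers[0], grid.pmf)
        ax.set_xlabel(grid.axis_names[0] if grid.axis_names else "coordinate")
        ax.set_ylabel("PMF (kcal/mol)")
    else:
        c = grid.centers
        masked = np.ma.masked_invalid(grid.pmf)
        im = ax.pcolormesh(c[0], c[1], masked.T, cmap="viridis_r", shading="auto")
        fig.colorbar(im, ax=ax, label="PMF (kcal/mol)")
        names = grid.axis_names or ("q1", "q2")
        ax.set_xlabel(names[0])
        ax.set_ylabel(names[1])
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_kld(series: KLDSeries, path, title: str = "") -> None:
    """KLD(t) lines per replica pair with the convergence cutoff."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for k, (i, j) in enumerate(series.pairs):
        ax.plot(series.times, series.values[k], label=f"KLD:{k + 1} (Sim{i + 1}-Sim{j + 1})")
    ax.axhline(series.cutoff, color="grey", ls="--", lw=1, label=f"cutoff {series.cutoff}")
    ax.set_xlabel("frames")
    ax.set_ylabel("KLD")
    ax.legend(fontsize=7)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
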