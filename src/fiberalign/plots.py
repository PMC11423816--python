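"""Figures: polar rose plots and percent-aligned box plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import RoseHistogram

__all__ = ["rose_plot", "alignment_boxplot"]


def rose_plot(rose: RoseHistogram, path: str | Path | None = None, ax=None):
    """Polar histogram of axial orientation counts.

    Statistics live on [0, 180); for display the histogram is mirrored onto
    the full circle, the usual presentation for axial data.
    """
    if ax is None:
        fig = plt.figure(figsize=(4, 4))
        ax = fig.add_subplot(111, projection="polar")
    edges = np.deg2rad(rose.bin_edges[:-1])
    width = np.deg2rad(rose.bin_width_deg)
    for offset in (0.0, np.pi):  # axial mirror
        ax.bar(edges + width / 2 + offset, rose.counts, width=width,
               color="tab:red", alpha=0.8, edgecolor="k", linewidth=0.3)
    ax.set_theta_zero_location("E")
    ax.set_yticklabels([])
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def alignment_boxplot(tidy: pd.DataFrame, path: str | Path | None = None):
    """Percent aligned per (density, level): 25-75th percentile box, median
    line, whiskers at min and max, one point per replicate."""
    fig, ax = plt.subplots(figsize=(7, 4))
    groups, labels = [], []
    for density in ("confluent", "sparse"):
        sub = tidy[tidy["density"] == density]
        for level in sub["level"].unique():
            groups.append(sub.loc[sub["level"] == level, "percent_aligned"].to_numpy())
            labels.append(f"{density}\n{level}")
    ax.boxplot(groups, tick_labels=labels, whis=(0, 100))
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for i, g in enumerate(groups, start=1):
        ax.scatter(np.full(len(g), i) + rng.uniform(-0.08, 0.08, len(g)), g,
                   s=14, color="k", zorder=3)
    ax.axhline(50.0, ls="--", color="gray", lw=0.8)
    ax.set_ylabel("% aligned fibers (<45\N{DEGREE SIGN} from flow)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return ax
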