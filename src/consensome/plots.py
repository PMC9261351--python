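"""Report figures: volcano plot, regulatory footprint scatter, and the
knockout-vs-consensome fold-change scatter."""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["volcano", "footprint_scatter", "fc_scatter", "save_figure"]


def volcano(ko_data: pd.DataFrame, p_max: float = 0.05, lfc_cut: float = None, ax=None):
    """Volcano plot of a knockout contrast (log2 FC vs -log10 p)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    d = ko_data.loc[ko_data["assayed"].astype(bool)]
    x = d["log2fc"].to_numpy()
    y = -np.log10(d["pvalue"].to_numpy())
    sig = d["pvalue"].to_numpy() < p_max
    if lfc_cut is not None:
        sig = sig & (np.abs(x) > lfc_cut)
    ax.scatter(x[~sig], y[~sig], s=4, c="0.6", linewidths=0)
    ax.scatter(x[sig], y[sig], s=4, c="crimson", linewidths=0)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    ax.set_title("knockout contrast")
    return ax


def footprint_scatter(screen_table: pd.DataFrame, direction: str = "down", ax=None):
    """Regulatory footprint plot: -log10 Q vs odds ratio, one point per node.

    Nodes with the most enriched and most significant footprints sit towards
    the top right.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    t = screen_table.loc[screen_table["direction"] == direction]
    q = np.clip(t["qvalue"].to_numpy(), 1e-300, None)
    ax.scatter(t["odds_ratio"], -np.log10(q), s=10, c="steelblue", linewidths=0)
    ax.axhline(-math.log10(0.05), color="0.3", ls="--", lw=0.8)
    ax.set_xlabel("odds ratio")
    ax.set_ylabel("-log10 Q")
    ax.set_title(f"HCT footprints ({direction}-regulated gene set)")
    return ax


def fc_scatter(x, y, xlabel="knockout log2 FC", ylabel="consensome log2 GMFC", ax=None):
    """Scatter of paired fold changes (the direct-target concordance plot)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(x, y, s=12, c="seagreen", linewidths=0)
    ax.axhline(0, color="0.7", lw=0.6)
    ax.axvline(0, color="0.7", lw=0.6)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    return ax


def save_figure(ax, path: str | Path) -> None:
    """Save a figure without embedded creation dates (reproducible output)."""
    path = Path(path)
    fig = ax.get_figure()
    metadata = {"Date": None} if path.suffix == ".svg" else {}
    fig.savefig(path, dpi=150, bbox_inches="tight", metadata=metadata)
    plt.close(fig)
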