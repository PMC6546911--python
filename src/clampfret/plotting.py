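"""Figure rendering for heat maps, TDPs and dwell histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .analysis import SyncHeatMap, TDPHistogram, _durations

__all__ = ["plot_heatmap", "plot_tdp", "plot_dwell_hist", "save_heatmap", "save_tdp"]


def plot_heatmap(hm: SyncHeatMap, ax=None):
    """Synchronized FRET population density (time on x, FRET on y)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ax.imshow(
        hm.density.T,
        origin="lower",
        aspect="auto",
        extent=(hm.time_edges[0], hm.time_edges[-1], hm.e_edges[0], hm.e_edges[-1]),
        cmap="viridis",
    )
    ax.axvline(0.0, color="w", lw=0.8, ls="--")
    ax.set_xlabel(f"time from {hm.anchor} (s)")
    ax.set_ylabel("FRET efficiency")
    ax.set_title(f"{hm.n_traces} traces")
    return ax


def plot_tdp(tdp: TDPHistogram, ax=None):
    """Transition density plot: E before vs E after."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3.6, 3.4))
    ax.imshow(
        tdp.counts.T,
        origin="lower",
        aspect="equal",
        extent=(tdp.e_edges[0], tdp.e_edges[-1], tdp.e_edges[0], tdp.e_edges[-1]),
        cmap="magma",
    )
    ax.plot([0, 1], [0, 1], color="w", lw=0.6, ls=":")
    ax.set_xlabel("FRET before")
    ax.set_ylabel("FRET after")
    ax.set_title(f"{tdp.n_transitions} transitions ({tdp.side} {tdp.window_s:g} s)")
    return ax


def plot_dwell_hist(table, fit=None, bin_s: float = 0.25, ax=None):
    """Dwell-time histogram with an optional fitted exponential overlay."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    d = _durations(table)
    edges = np.arange(0.0, d.max() + bin_s, bin_s)
    counts, _ = np.histogram(d, bins=edges)
    ax.bar(edges[:-1], counts, width=bin_s, align="edge", color="0.6")
    if fit is not None and getattr(fit, "tau", None):
        t = np.linspace(0, edges[-1], 200)
        scale = counts.max() if counts.size else 1.0
        ax.plot(t, scale * np.exp(-t / fit.tau), "r-", lw=1.2,
                label=f"tau = {fit.tau:.2f} s")
        ax.legend(frameon=False)
    ax.set_xlabel("dwell time (s)")
    ax.set_ylabel("count")
    return ax


def save_heatmap(hm: SyncHeatMap, path) -> None:
    ax = plot_heatmap(hm)
    ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(ax.figure)


def save_tdp(tdp: TDPHistogram, path) -> None:
    ax = plot_tdp(tdp)
    ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(ax.figure)
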