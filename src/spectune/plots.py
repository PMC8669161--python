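"""Figure-style summary plots: cluster overview, bulk spectral tunings by
group, zero-crossing histograms, and weight-by-depth maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from spectune.synthetic import CONE_ORDER

__all__ = [
    "plot_cluster_overview",
    "plot_bulk_tunings",
    "plot_crossing_histogram",
    "plot_weight_ipl_histogram",
]


def plot_cluster_overview(model, summary, path=None):
    """Heatmap of cluster means plus IPL-depth and region histograms."""
    n = model.n_clusters
    fig, axes = plt.subplots(1, 3, figsize=(12, max(3, 0.4 * n)),
                             gridspec_kw={"width_ratios": [3, 1, 1]})
    axes[0].imshow(model.cluster_means, aspect="auto", cmap="RdBu_r")
    axes[0].set_xlabel("time (samples)")
    axes[0].set_ylabel("cluster")
    edges = summary["ipl_bin_edges"]
    centers = (edges[:-1] + edges[1:]) / 2
    for c in range(n):
        axes[1].plot(summary["ipl_hist"][c], centers, lw=1)
    axes[1].set_xlabel("density")
    axes[1].set_ylabel("IPL depth")
    axes[1].invert_yaxis()
    im = axes[2].imshow(summary["region_hist"], aspect="auto", cmap="viridis")
    axes[2].set_xticks(range(len(summary["region_order"])),
                       summary["region_order"])
    axes[2].set_xlabel("region")
    fig.colorbar(im, ax=axes[2], shrink=0.6)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_bulk_tunings(tunings, roi_counts=None, path=None):
    """Peak-normalized bulk tunings, one panel per spectral group."""
    groups = sorted({t.spectral_group for t in tunings if t.spectral_group})
    fig, axes = plt.subplots(1, max(len(groups), 1), figsize=(3 * len(groups), 3),
                             sharey=True, squeeze=False)
    counts = np.ones(len(tunings)) if roi_counts is None else np.asarray(roi_counts)
    cmax = counts.max() if counts.size else 1.0
    for ax, g in zip(axes[0], groups):
        for t, c in zip(tunings, counts):
            if t.spectral_group != g:
                continue
            peak = np.abs(t.curve).max() or 1.0
            ax.plot(t.wavelength_grid_nm, t.curve / peak,
                    color="k", alpha=0.3 + 0.7 * c / cmax, lw=1)
        ax.axhline(0, color="gray", lw=0.5)
        ax.set_title(g, fontsize=9)
        ax.set_xlabel("wavelength (nm)")
    axes[0][0].set_ylabel("norm. amplitude")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_crossing_histogram(hist, bin_edges, null_hists=None, path=None):
    """Zero-crossing histogram, optionally overlaid with randomization nulls."""
    fig, ax = plt.subplots(figsize=(5, 3))
    centers = (bin_edges[:-1] + bin_edges[1:]) / 2
    ax.bar(centers, hist, width=np.diff(bin_edges), color="k", alpha=0.7,
           label="observed")
    if null_hists is not None:
        ax.plot(centers, np.mean(null_hists, axis=0), color="r", lw=1.5,
                label="null mean")
        ax.legend(fontsize=8)
    ax.set_xlabel("zero crossing (nm)")
    ax.set_ylabel("ROI-weighted count")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_weight_ipl_histogram(result, path=None):
    """2-D weight x IPL-depth histograms, one panel per cone."""
    fig, axes = plt.subplots(1, 4, figsize=(12, 3), sharey=True)
    for ax, cone in zip(axes, CONE_ORDER):
        h = result["hists"][cone]
        ax.imshow(
            h.T, aspect="auto", origin="lower", cmap="magma",
            extent=(result["weight_bin_edges"][0], result["weight_bin_edges"][-1],
                    0, 1),
        )
        ax.axvline(0, color="w", lw=0.5)
        ax.set_title(cone, fontsize=9)
        ax.set_xlabel("weight")
    axes[0].set_ylabel("IPL depth")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
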