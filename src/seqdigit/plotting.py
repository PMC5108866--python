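"""Matplotlib figures for the per-strain digital signatures.

Each function returns the figure; the plotted arrays are taken verbatim
from the objects passed in, so tests assert against those data rather than
pixels.  The GC plot carries the conventional three bands: red lines at
the windowed minimum and maximum, a blue line at the mean.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .cgr import CGRPointSet, FCGRMatrix, cell_labels
from .composition import GCProfile
from .ordination import PCAResult

__all__ = ["gc_profile_figure", "cgr_figure", "fcgr_figure", "pca_figure"]


def gc_profile_figure(profile: GCProfile, title: str = "GC profile"):
    """Windowed GC% with min/max (red) and mean (blue) bands."""
    if profile.values.size == 0:
        raise ValueError("empty GC profile")
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(profile.positions, profile.values, color="0.3", lw=0.8,
            label=f"GC% (window {profile.window})")
    ax.axhline(profile.max, color="red", lw=1.0, label=f"max {profile.max:.1f}")
    ax.axhline(profile.min, color="red", lw=1.0, label=f"min {profile.min:.1f}")
    ax.axhline(profile.mean, color="blue", lw=1.2, label=f"mean {profile.mean:.1f}")
    ax.set_xlabel("window start (1-based nt)")
    ax.set_ylabel("GC (%)")
    ax.set_ylim(0, 100)
    ax.set_title(title)
    ax.legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    return fig


def cgr_figure(points: CGRPointSet, title: str | None = None):
    """CGR scatter with base labels at the four corners."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(points.points[:, 0], points.points[:, 1], s=0.5, c="black")
    for base, (x, y) in points.corners.as_dict().items():
        ax.annotate(base, (x, y), fontsize=10, fontweight="bold",
                    ha="left" if x == 0 else "right",
                    va="bottom" if y == 0 else "top", color="tab:red")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(title or f"CGR: {points.record_id}")
    ax.set_aspect("equal")
    fig.tight_layout()
    return fig


def fcgr_figure(fcgr: FCGRMatrix, title: str | None = None):
    """FCGR heat grid with a colour scale bar; darker = more k-mers.

    Cell (0,0) (the A corner under the default map) is drawn bottom-left,
    matching the CGR orientation.
    """
    fig, ax = plt.subplots(figsize=(4.6, 4))
    im = ax.imshow(fcgr.counts, origin="lower", cmap="Greys")
    if fcgr.k <= 3:
        labels = cell_labels(fcgr.k, fcgr.corners)
        for r in range(labels.shape[0]):
            for c in range(labels.shape[1]):
                ax.text(c, r, labels[r, c], ha="center", va="center",
                        fontsize=8 if fcgr.k <= 2 else 5, color="tab:orange")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(title or f"FCGR k={fcgr.k}: {fcgr.record_id}")
    fig.colorbar(im, ax=ax, label="k-mer count")
    fig.tight_layout()
    return fig


def pca_figure(result: PCAResult, title: str = "PCA of strain k-mer profiles"):
    """PC1/PC2 scatter with record labels and explained-variance axes."""
    fig, ax = plt.subplots(figsize=(5, 4))
    xs = result.scores[:, 0]
    ys = result.scores[:, 1] if result.scores.shape[1] > 1 else np.zeros_like(xs)
    ax.scatter(xs, ys, c="tab:blue")
    for label, x, y in zip(result.labels, xs, ys):
        ax.annotate(label, (x, y), fontsize=7, xytext=(3, 3),
                    textcoords="offset points")
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}% variance)")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}% variance)")
    ax.set_title(title)
    fig.tight_layout()
    return fig
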