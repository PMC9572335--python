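"""Matplotlib views of latent trajectories, regions, and diagnostics.

All functions draw onto a provided axes (or create one) and return it,
so they compose into figure grids; none of them call ``show``.
"""

from __future__ import annotations

import numpy as np

from .analysis import LatentRegion
from .training import TrainHistory


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_latent_trajectory(latents, ax=None, **kwargs):
    """2-D latent trajectory as a connected line."""
    ax = _ax(ax)
    latents = np.asarray(latents)
    kwargs.setdefault("linewidth", 0.8)
    ax.plot(latents[:, 0], latents[:, 1], **kwargs)
    ax.set_xlabel("$z_1$")
    ax.set_ylabel("$z_2$")
    return ax


def plot_latent_region(region: LatentRegion, ax=None, grid: int = 200,
                       pad_bandwidths: float = 3.0, levels: int = 8,
                       **kwargs):
    """Density contours of a fitted latent region.

    The evaluation grid covers the fitting points' bounding box padded by
    ``pad_bandwidths`` kernel bandwidths on each side.
    """
    ax = _ax(ax)
    pts = region.points
    try:
        bw = float(np.sqrt(region.kde.covariance.max()))
    except AttributeError:
        bw = region.kde.h
    lo = pts.min(axis=0) - pad_bandwidths * bw
    hi = pts.max(axis=0) + pad_bandwidths * bw
    xs = np.linspace(lo[0], hi[0], grid)
    ys = np.linspace(lo[1], hi[1], grid)
    xx, yy = np.meshgrid(xs, ys)
    zz = region.density(np.column_stack([xx.ravel(), yy.ravel()]))
    ax.contour(xx, yy, zz.reshape(grid, grid), levels=levels, **kwargs)
    ax.contour(xx, yy, zz.reshape(grid, grid),
               levels=[region.threshold], colors="k", linewidths=1.5)
    ax.set_title(region.label)
    return ax


def plot_learning_curves(history: TrainHistory, ax=None):
    """Train/validation negative-ELBO traces per epoch."""
    ax = _ax(ax)
    ax.plot(history.train_loss, label="train")
    if history.val_loss:
        ax.plot(history.val_loss, label="validation")
    ax.set_xlabel("epoch")
    ax.set_ylabel("loss (-ELBO)")
    ax.legend()
    return ax


def plot_attention_heatmap(weights, ax=None, row_span=None, **kwargs):
    """Attention-weight matrix as an image (queries on rows)."""
    ax = _ax(ax)
    w = np.asarray(weights)
    extent = None
    if row_span is not None:
        extent = (0, w.shape[1], row_span[1], row_span[0])
    kwargs.setdefault("aspect", "auto")
    kwargs.setdefault("cmap", "viridis")
    im = ax.imshow(w, extent=extent, **kwargs)
    ax.figure.colorbar(im, ax=ax)
    ax.set_xlabel("key position")
    ax.set_ylabel("query position")
    return ax
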