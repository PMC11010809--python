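"""SVG figures: superimposed stacks, consensus shapes, PC shape vectors."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_aligned_stack", "plot_outline_stack", "plot_pc_shape_vectors"]


def plot_aligned_stack(aligned, path=None, ax=None):
    """Superimposed configurations with the consensus highlighted."""
    if ax is None:
        _fig, ax = plt.subplots(figsize=(5, 5))
    for shape in aligned.shapes:
        ax.plot(shape.points[:, 0], shape.points[:, 1], ".", ms=1.5,
                color="0.6", alpha=0.4)
    cons = aligned.consensus.points
    fixed = ~aligned.consensus.is_semi
    ax.plot(cons[:, 0], cons[:, 1], ".", ms=3, color="k")
    ax.plot(cons[fixed, 0], cons[fixed, 1], "o", ms=6, mfc="r", mec="k")
    ax.set_aspect("equal")
    ax.set_title(f"Procrustes superimposition (n={len(aligned.shapes)})")
    if path:
        plt.gcf().savefig(path)
        plt.close(plt.gcf())
    return ax


def plot_outline_stack(polygons, path=None, ax=None):
    """Centered-and-scaled outline overlap (stacking display)."""
    if ax is None:
        _fig, ax = plt.subplots(figsize=(5, 5))
    for poly in polygons:
        v = np.vstack((poly.vertices, poly.vertices[:1]))
        ax.plot(v[:, 0], v[:, 1], "-", lw=0.5, color="0.4", alpha=0.4)
    ax.set_aspect("equal")
    ax.set_title(f"Outline stack (n={len(polygons)})")
    if path:
        plt.gcf().savefig(path)
        plt.close(plt.gcf())
    return ax


def plot_pc_shape_vectors(model, pc, magnitude=2.0, context="procrustes_coords",
                          path=None, ax=None):
    """Shape excursions at mean -/+ magnitude*sd along one principal axis."""
    from .stats import pc_shape_vectors

    lo, hi = pc_shape_vectors(model, pc, magnitude, context=context)
    if ax is None:
        _fig, ax = plt.subplots(figsize=(5, 5))
    if context == "procrustes_coords":
        mean = model.mean.reshape(-1, 2)
        ax.plot(mean[:, 0], mean[:, 1], ".", color="0.5", ms=3, label="mean")
        ax.quiver(mean[:, 0], mean[:, 1],
                  hi[:, 0] - mean[:, 0], hi[:, 1] - mean[:, 1],
                  angles="xy", scale_units="xy", scale=1, width=0.003, color="r")
    else:
        for shape, style, lbl in ((lo, "b-", "-"), (hi, "r-", "+")):
            v = np.vstack((shape.vertices, shape.vertices[:1]))
            ax.plot(v[:, 0], v[:, 1], style, lw=1, label=lbl)
        ax.legend()
    ax.set_aspect("equal")
    ax.set_title(f"PC{pc + 1} shape vectors (±{magnitude} sd)")
    if path:
        plt.gcf().savefig(path)
        plt.close(plt.gcf())
    return ax
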