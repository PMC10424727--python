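"""Poincare diagrams of NN-interval series and their rasterization.

A Poincare diagram scatters each NN interval against its successor
(NN_i, NN_{i+1}); a tight cloud on the identity line signals a regular
rhythm while atrial fibrillation spreads the cloud.  Rasterized diagrams
feed standard 2D image classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default fixed axis limits (seconds).  Fixed limits keep absolute heart
#: rate visible to the classifier (a 0.45 s cloud means tachycardia, a 1.2 s
#: cloud bradycardia); data-adaptive limits would erase that cue.
DEFAULT_AXIS_RANGE = (0.2, 1.6)
DEFAULT_IMAGE_SIZE = 224
DEFAULT_MARKER_RADIUS = 2


@dataclass
class PoincarePoints:
    points: np.ndarray  # (n, 2) of (NN_i, NN_{i+1}) in seconds


@dataclass
class PoincareImage:
    """H x W intensity grid; ``pixels[y, x]`` with x indexing NN_i and y
    indexing NN_{i+1}, both increasing with interval value (origin at the
    lower-left corner in index terms; image export flips vertically)."""

    pixels: np.ndarray
    axis_min: float
    axis_max: float
    marker_radius_px: int


def build_points(nn) -> PoincarePoints:
    """Pair each NN interval with its successor."""
    nn = np.asarray(nn, dtype=float)
    if nn.size < 2:
        raise ValueError("need at least 2 NN intervals to build Poincare points")
    return PoincarePoints(points=np.column_stack([nn[:-1], nn[1:]]))


def sd1(nn) -> float:
    """Short-term HRV index: SD of (NN_{i+1} - NN_i) / sqrt(2), the point
    dispersion perpendicular to the identity line."""
    nn = np.asarray(nn, dtype=float)
    return float(np.std(np.diff(nn) / np.sqrt(2)))


def rasterize(points: PoincarePoints, size: int = DEFAULT_IMAGE_SIZE,
              axis_range: tuple[float, float] = DEFAULT_AXIS_RANGE,
              marker_radius_px: int = DEFAULT_MARKER_RADIUS,
              intensity_per_point: float = 0.25) -> PoincareImage:
    """Render points as filled discs on a ``size`` x ``size`` intensity grid.

    Disc intensities add (``intensity_per_point`` each), then clip at 1, so
    dense regions of the cloud stay distinguishable from single strays.
    Points outside ``axis_range`` are clipped to the border.  Deterministic.
    """
    lo, hi = axis_range
    if lo >= hi:
        raise ValueError(f"axis_min must be below axis_max, got {axis_range}")
    pts = points.points
    if pts.size == 0:
        raise ValueError("cannot rasterize empty point set")
    grid = np.zeros((size, size))
    scale = (size - 1) / (hi - lo)
    xi = np.clip(np.rint((pts[:, 0] - lo) * scale), 0, size - 1).astype(int)
    yi = np.clip(np.rint((pts[:, 1] - lo) * scale), 0, size - 1).astype(int)

    r = marker_radius_px
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    disc = (dy**2 + dx**2 <= r**2)
    offs = np.argwhere(disc) - r
    for ox, oy in offs:  # disc mask is symmetric; axis order immaterial
        xs = xi + ox
        ys = yi + oy
        ok = (xs >= 0) & (xs < size) & (ys >= 0) & (ys < size)
        np.add.at(grid, (ys[ok], xs[ok]), intensity_per_point)
    np.clip(grid, 0.0, 1.0, out=grid)
    return PoincareImage(pixels=grid, axis_min=lo, axis_max=hi,
                         marker_radius_px=r)


def to_model_input(image: PoincareImage, n_channels: int = 3) -> np.ndarray:
    """Replicate the single intensity channel for image backbones."""
    return np.repeat(image.pixels[None, :, :], n_channels, axis=0)


def export_png(image: PoincareImage, path) -> None:
    """Write the diagram for visual inspection (value axis pointing up)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3), dpi=max(75, image.pixels.shape[0] // 3))
    ax.imshow(image.pixels, origin="lower", cmap="Greys",
              extent=(image.axis_min, image.axis_max,
                      image.axis_min, image.axis_max))
    ax.set_xlabel("NN$_i$ (s)")
    ax.set_ylabel("NN$_{i+1}$ (s)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
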