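"""GradCAM saliency for the 1D signal models and the 2D Poincare models.

The class score's gradient is taken with respect to the feature maps of a
(by default the last) convolutional layer; per-channel weights are the
spatial/temporal means of that gradient, the weighted feature-map sum is
ReLU-rectified, linearly upsampled to input resolution and max-normalised.
Computed in evaluation mode, so dropout is off and the map is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn
from .nets import ModelBundle


@dataclass
class Saliency:
    heatmap: np.ndarray  # >= 0, max 1 (or all zero); input resolution
    target_class: int
    layer_id: str


def _conv_layer_names(bundle: ModelBundle) -> list[str]:
    return [name for name, m in bundle.net.root.named_modules().items()
            if isinstance(m, (nn.Conv1d, nn.Conv2d))]


def gradcam(bundle: ModelBundle, x: np.ndarray, target_class: int,
            layer: str | None = None) -> Saliency:
    """Class-activation heatmap for a single input.

    ``x`` is one model input without the batch axis — ``(leads, samples)``
    for the 1D models, ``(3, H, W)`` for the image models.  ``layer``
    defaults to the last convolutional layer of the architecture.
    """
    layer = layer or bundle.config.get("last_conv")
    available = _conv_layer_names(bundle)
    if layer not in available:
        raise KeyError(
            f"layer {layer!r} not found; convolutional layers: {available}")
    tap = nn.Tap(layer)
    logits = bundle.net.forward(x[None], training=False, tap=tap)
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    bundle.net.backward(dlogits, tap=tap)
    act = tap.activation[0].astype(np.float64)   # (C, ...) feature maps
    grad = tap.grad[0].astype(np.float64)
    spatial_axes = tuple(range(1, act.ndim))
    weights = grad.mean(axis=spatial_axes)
    cam = np.maximum(
        np.tensordot(weights, act, axes=([0], [0])), 0.0)

    if cam.ndim == 1:
        target_len = x.shape[-1]
        pos = np.linspace(0, cam.size - 1, target_len)
        heat = np.interp(pos, np.arange(cam.size), cam)
    else:
        zoom = (x.shape[-2] / cam.shape[0], x.shape[-1] / cam.shape[1])
        heat = np.maximum(ndimage.zoom(cam, zoom, order=1), 0.0)
        heat = heat[: x.shape[-2], : x.shape[-1]]
    peak = heat.max()
    if peak > 0:
        heat = heat / peak
    return Saliency(heatmap=heat, target_class=target_class, layer_id=layer)


def saliency_mass_fraction(sal: Saliency, window: tuple[int, int]) -> float:
    """Fraction of total 1D saliency mass inside [start, stop) samples."""
    total = sal.heatmap.sum()
    if total == 0:
        return 0.0
    return float(sal.heatmap[window[0] : window[1]].sum() / total)


def render_overlay(sal: Saliency, x: np.ndarray, path) -> None:
    """Write a saliency overlay: colour-graded trace (1D) or alpha-blended
    heatmap over the Poincare image (2D)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    if sal.heatmap.ndim == 1:
        trace = np.asarray(x)[-1] if np.asarray(x).ndim > 1 else np.asarray(x)
        if trace.shape[-1] != sal.heatmap.shape[0]:
            raise ValueError(
                f"saliency length {sal.heatmap.shape[0]} does not match "
                f"signal length {trace.shape[-1]}")
        t = np.arange(trace.size)
        segs = np.stack([np.column_stack([t[:-1], trace[:-1]]),
                         np.column_stack([t[1:], trace[1:]])], axis=1)
        lc = LineCollection(segs, cmap="viridis", array=sal.heatmap[:-1],
                            linewidths=1.0)
        fig, ax = plt.subplots(figsize=(10, 3))
        ax.add_collection(lc)
        ax.set_xlim(0, trace.size)
        ax.set_ylim(trace.min() - 0.1, trace.max() + 0.1)
        fig.colorbar(lc, ax=ax, label="saliency")
        ax.set_xlabel("sample")
    else:
        img = np.asarray(x)
        base = img[0] if img.ndim == 3 else img
        if base.shape != sal.heatmap.shape:
            raise ValueError("saliency and image shapes do not match")
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(base, origin="lower", cmap="Greys")
        ax.imshow(sal.heatmap, origin="lower", cmap="jet", alpha=0.4)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
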