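"""Grad-CAM saliency maps and a quantitative localization score.

Grad-CAM explains one (image, class) decision: the gradient of the class
score is taken with respect to the activations of the last convolutional
layer, spatially average-pooled into per-channel importance weights, and the
rectified weighted combination of the activation maps gives a coarse heatmap
that is bilinearly upsampled to the input size and max-normalized to [0, 1].
High values mark image regions the model relied on for that class.

On synthetic data the true lesion box is known, so the qualitative "does the
model look at the lesion" reading becomes a number: the fraction of total
heatmap mass inside the box.  A heatmap no better than uniform scores exactly
the box's area fraction, so values above that fraction indicate genuine
localization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .model import HierarchicalNetwork

__all__ = ["Heatmap", "grad_cam", "localization_score", "render_overlay"]


@dataclass
class Heatmap:
    """Upsampled, [0, 1]-normalized class activation map for one image."""

    values: np.ndarray  # (H, W) float, max 1 unless identically 0
    class_id: str
    level: int


def grad_cam(
    net: HierarchicalNetwork,
    image: np.ndarray,
    level: int,
    class_id: str,
    block_index: int = -1,
) -> Heatmap:
    """Grad-CAM heatmap of ``class_id`` (at ``level``) for one HWC image.

    ``block_index`` selects the backbone block whose output activations are
    explained; the default is the last convolutional block.
    """
    order = net.taxonomy.class_order.get(level)
    if order is None or class_id not in order:
        raise KeyError(f"class {class_id!r} is not a level-{level} class")
    j = order.index(class_id)
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected one HWC RGB image")
    x = img.transpose(2, 0, 1)[None]
    res = net.forward(x)
    fmap = res.block_maps[block_index]
    logits = res.logits[level]
    seed = np.zeros_like(logits.data)
    seed[0, j] = 1.0
    logits.backward(seed)
    grads = fmap.grad[0]  # (C, h, w)
    acts = fmap.data[0]
    weights = grads.mean(axis=(1, 2))  # neuron importance weights
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    h_in, w_in = img.shape[:2]
    zoom = (h_in / cam.shape[0], w_in / cam.shape[1])
    up = ndimage.zoom(cam.astype(np.float64), zoom, order=1)
    up = np.clip(up, 0.0, None)
    m = up.max()
    if m > 0:
        up = up / m
    return Heatmap(values=up, class_id=class_id, level=level)


def localization_score(heatmap: Heatmap, box: tuple[int, int, int, int]) -> float:
    """Fraction of total heatmap mass inside a (x0, y0, x1, y1) half-open box.

    0 for an identically-zero map; 1 when all mass lies inside the box.
    """
    x0, y0, x1, y1 = box
    h, w = heatmap.values.shape
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError(f"degenerate or out-of-bounds box {box} for map {h}x{w}")
    total = heatmap.values.sum()
    if total == 0:
        return 0.0
    return float(heatmap.values[y0:y1, x0:x1].sum() / total)


def render_overlay(image: np.ndarray, heatmap: Heatmap, alpha: float = 0.45) -> np.ndarray:
    """Blend the heatmap over the image with a blue-low/red-high colormap."""
    import matplotlib

    rgba = matplotlib.colormaps["jet"](heatmap.values)
    overlay = (1 - alpha) * np.asarray(image, dtype=np.float64) + alpha * rgba[..., :3]
    return np.clip(overlay, 0.0, 1.0)
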