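"""Interpretation: Grad-CAM heatmaps, overlays, cohort differential image.

Grad-CAM weights the final convolutional feature maps by the spatial mean
of the death-logit gradient, rectifies the weighted sum, upsamples it
bilinearly to the image grid, and scales the maximum to one. The overlay
blends the grayscale timeline with a blue-to-red attention palette (full
attention shows pure red). The differential image is the difference of
class-mean timelines — white marks the variables and hours that most
distinguish deaths from survivors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from PIL import Image
from skimage.transform import resize

from .encode import TimelineImage
from .models import TrainedModel


@dataclass
class Heatmap:
    """Attention map over a timeline image, values in [0, 1], max 1."""

    attention: np.ndarray  # (V, 48)
    admission_id: Optional[str] = None
    model_id: Optional[str] = None

    def __post_init__(self):
        a = self.attention
        if a.min() < 0 or a.max() > 1 + 1e-9:
            raise ValueError("attention must lie in [0, 1]")
        if a.max() > 0 and abs(a.max() - 1.0) > 1e-6:
            raise ValueError("nonzero attention must be max-normalized")


def grad_cam(model: TrainedModel, image) -> Heatmap:
    """Grad-CAM heatmap of the death class for one timeline image.

    Channel weights are the spatial means of d(logit)/dA_k at the final
    convolutional layer; the map is ReLU(sum_k alpha_k A_k), bilinearly
    upsampled to the image shape and divided by its maximum (an all-zero
    map stays zero). Architectures without a conv layer are rejected.
    """
    pixels = image.pixels if isinstance(image, TimelineImage) else np.asarray(image)
    A, dA = model.conv_activations_and_grads(pixels[None])
    A, dA = A[0], dA[0]  # (F, h, w)
    alpha = dA.mean(axis=(1, 2))
    cam = np.maximum((alpha[:, None, None] * A).sum(axis=0), 0.0)
    cam = resize(cam, pixels.shape, order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return Heatmap(cam,
                   admission_id=getattr(image, "admission_id", None),
                   model_id=model.config.architecture)


def _palette(a: np.ndarray) -> np.ndarray:
    """Blue (attention 0) to red (attention 1), (..., 3) floats in [0,1]."""
    return np.stack([a, np.zeros_like(a), 1.0 - a], axis=-1)


def overlay(image, heatmap: Heatmap) -> np.ndarray:
    """Blend grayscale timeline with the attention palette -> (V, 48, 3) uint8.

    Blend weight is the attention itself, so zero attention leaves pure
    grayscale and full attention shows the palette's red endpoint.
    """
    pixels = image.pixels if isinstance(image, TimelineImage) else np.asarray(image)
    a = heatmap.attention
    if a.shape != pixels.shape:
        raise ValueError(f"heatmap shape {a.shape} != image shape {pixels.shape}")
    gray = np.repeat(pixels[..., None], 3, axis=-1)
    blended = (1.0 - a[..., None]) * gray + a[..., None] * _palette(a)
    return np.round(255.0 * np.clip(blended, 0, 1)).astype(np.uint8)


def save_overlay_png(image, heatmap: Heatmap, path) -> None:
    Image.fromarray(overlay(image, heatmap), mode="RGB").save(path, format="PNG")


def save_overlay_figure(image, heatmap: Heatmap, path, row_labels=None) -> None:
    """Side-by-side original | overlay figure with axis labels."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pixels = image.pixels if isinstance(image, TimelineImage) else np.asarray(image)
    labels = row_labels or getattr(image, "row_labels", None)
    fig, axes = plt.subplots(1, 2, figsize=(10, max(4, pixels.shape[0] / 12)))
    axes[0].imshow(pixels, cmap="gray", aspect="auto", vmin=0, vmax=1)
    axes[0].set_title("visual timeline")
    axes[1].imshow(overlay(image, heatmap), aspect="auto")
    axes[1].set_title("Grad-CAM attention")
    for ax in axes:
        ax.set_xlabel("hours since admission")
    if labels is not None and len(labels) <= 60:
        axes[0].set_yticks(range(len(labels)))
        axes[0].set_yticklabels(labels, fontsize=4)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def differential_image(images: np.ndarray, labels) -> Tuple[np.ndarray, np.ndarray]:
    """Class-mean difference image.

    Returns ``(signed, display)``: ``signed = mean(alive) - mean(died)``
    (V x 48) and ``display = |signed| / max|signed|`` — white where the two
    classes differ most, black where they are similar.
    """
    y = np.asarray(labels).astype(int)
    arr = np.asarray(images, dtype=float)
    if y.min() == y.max():
        raise ValueError("need both outcome classes for a differential image")
    signed = arr[y == 0].mean(axis=0) - arr[y == 1].mean(axis=0)
    peak = np.abs(signed).max()
    display = np.abs(signed) / peak if peak > 0 else np.zeros_like(signed)
    return signed, display
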