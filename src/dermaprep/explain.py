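"""Grad-CAM saliency maps over the backbone's final conv feature maps.

The channel weight alpha_k is the spatial mean of the gradient of the
class score (pre-sigmoid logit) with respect to feature map A_k; the raw
localization map is ReLU(sum_k alpha_k A_k), min-max normalized to [0, 1]
(an identically-zero map stays all zeros) and bilinearly upsampled to the
input frame for overlay rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage import transform

from dermaprep.backbone import BackboneContract

__all__ = ["GradCAMResult", "grad_cam", "overlay"]


@dataclass
class GradCAMResult:
    heatmap: np.ndarray  # h x w, in [0, 1]
    upsampled: np.ndarray  # H x W, in [0, 1]
    class_index: int


def grad_cam(
    backbone: BackboneContract,
    img: np.ndarray,
    class_index: int = 1,
    output_size: tuple[int, int] | None = None,
) -> GradCAMResult:
    """Gradient-weighted class activation map for one image."""
    if not hasattr(backbone, "feature_maps_and_gradient"):
        raise TypeError(
            "backbone does not expose final conv feature maps and gradients"
        )
    A, dA = backbone.feature_maps_and_gradient(img, class_index)
    A = np.asarray(A, dtype=np.float64)
    dA = np.asarray(dA, dtype=np.float64)
    if A.shape != dA.shape or A.ndim != 3:
        raise ValueError("feature maps and gradients must share shape (K, h, w)")
    alphas = dA.mean(axis=(1, 2))
    raw = np.maximum(np.tensordot(alphas, A, axes=1), 0.0)
    peak = raw.max()
    heat = raw / peak if peak > 0 else raw
    if output_size is None:
        output_size = img.shape[:2] if img.ndim >= 2 else (224, 224)
    up = transform.resize(
        heat, output_size, order=1, mode="edge", anti_aliasing=False,
        preserve_range=True,
    )
    up = np.clip(up, 0.0, 1.0)
    return GradCAMResult(heatmap=heat, upsampled=up, class_index=class_index)


def overlay(img: np.ndarray, cam: GradCAMResult, alpha: float = 0.4) -> np.ndarray:
    """Alpha-blend a jet-colormapped heat map over the image (uint8)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if img.shape[:2] != cam.upsampled.shape:
        raise ValueError("image and upsampled heat map dimensions differ")
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if alpha == 0.0:
        return img.copy()
    cmap = colormaps["jet"]
    colored = (cmap(cam.upsampled)[..., :3] * 255.0)
    blended = (1.0 - alpha) * img.astype(np.float64) + alpha * colored
    return np.clip(blended, 0, 255).round().astype(np.uint8)
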