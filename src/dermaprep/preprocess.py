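"""Dermoscopy image preprocessing: resize, corner cropping, hair removal.

The hair-removal stage follows the classical morphology-based recipe
(DullRazor family): Canny edges on the grayscale frame, exclusion of
highly bright pixels (unlikely to be hair), morphological closing to fuse
the double edge response of a hair shaft into a solid band, erosion to
drop isolated noisy edge pixels, a probabilistic Hough line transform to
keep only elongated curvilinear structures, a length filter rejecting
segments that are too short or too long to be hair, and dilation of the
kept segments into the final hair mask. Masked pixels are then
interpolated with the median of their unmasked neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature, morphology, transform
from skimage.transform import probabilistic_hough_line
from skimage.draw import line as draw_line

__all__ = [
    "HairRemovalParams",
    "PreprocessConfig",
    "to_grayscale",
    "resize_image",
    "crop_black_corners",
    "detect_hair_mask",
    "inpaint_median",
    "median_denoise",
    "preprocess_pipeline",
]

# Luma weights for grayscale conversion (ITU-R BT.601).
_LUMA = np.array([0.299, 0.587, 0.114])

# skimage's Canny thresholds apply to the gradient of the [0, 1] float
# image; 8-bit-style thresholds are therefore divided by 255 and by the
# ~4x gain of the 3x3 Sobel kernel they are conventionally quoted against.
_CANNY_SCALE = 255.0 * 4.0


@dataclass(frozen=True)
class HairRemovalParams:
    canny_low: int = 50
    canny_high: int = 150
    bright_cutoff: int = 200
    close_kernel: int = 3  # structuring-element diameter, px
    erode_kernel: int = 3
    hough_threshold: int = 20
    min_line_len: int = 10
    max_line_len: int = 200
    max_line_gap: int = 5
    dilate_radius: int = 2
    inpaint_window: int = 11

    def validate(self) -> None:
        if not 0 < self.canny_low < self.canny_high <= 255:
            raise ValueError("require 0 < canny_low < canny_high <= 255")
        if self.min_line_len >= self.max_line_len:
            raise ValueError("require min_line_len < max_line_len")
        if self.inpaint_window < 3 or self.inpaint_window % 2 == 0:
            raise ValueError("inpaint_window must be odd and >= 3")


@dataclass(frozen=True)
class PreprocessConfig:
    target_size: tuple[int, int] = (224, 224)
    median_filter_window: int = 3
    corner_black_cutoff: int = 10
    hair: HairRemovalParams = field(default_factory=HairRemovalParams)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Luma grayscale (uint8). Grayscale input passes through."""
    if img.ndim == 2:
        return img.astype(np.uint8, copy=False)
    return (img.astype(np.float64) @ _LUMA).round().astype(np.uint8)


def resize_image(img: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Bilinear resize to ``target`` (height, width); channels preserved."""
    th, tw = target
    if th <= 0 or tw <= 0:
        raise ValueError("target dimensions must be positive")
    if img.size == 0:
        raise ValueError("empty input image")
    if img.shape[:2] == (th, tw):
        return img.copy()
    out = transform.resize(
        img.astype(np.float64),
        (th, tw) + img.shape[2:],
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(out, 0, 255).round().astype(np.uint8)


def crop_black_corners(img: np.ndarray, cutoff: int = 10) -> np.ndarray:
    """Crop to the tight bounding box of pixels with max channel > cutoff.

    Removes pure-black framing artifacts (microscope field stops, scanner
    borders). Raises on an all-black frame.
    """
    if img.ndim != 3:
        raise ValueError("crop_black_corners expects an RGB image")
    bright = img.max(axis=2) > cutoff
    rows = np.nonzero(bright.any(axis=1))[0]
    cols = np.nonzero(bright.any(axis=0))[0]
    if rows.size == 0:
        raise ValueError("degenerate input: every pixel is at or below the cutoff")
    return img[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def _square(diameter: int) -> np.ndarray:
    return np.ones((diameter, diameter), dtype=bool)


def detect_hair_mask(img: np.ndarray, p: HairRemovalParams | None = None) -> np.ndarray:
    """Boolean mask of pixels judged to belong to hair shafts.

    Fixed stage order: grayscale -> Canny -> bright-pixel exclusion ->
    closing -> erosion -> probabilistic Hough -> segment length filter ->
    rasterize + dilate. An empty mask is a valid result.
    """
    p = p or HairRemovalParams()
    p.validate()
    gray = to_grayscale(img)
    edges = feature.canny(
        gray.astype(np.float64) / 255.0,
        sigma=1.0,
        low_threshold=p.canny_low / _CANNY_SCALE,
        high_threshold=p.canny_high / _CANNY_SCALE,
    )
    # a Canny edge caused by a bright structure peaks on the pixel next to
    # it, so the exclusion looks at the pixel and its 8-neighbourhood
    bright = morphology.dilation(gray > p.bright_cutoff, _square(3))
    edges[bright] = False
    # square closing bridges the double edge response of a hair shaft into
    # a solid band; cross-shaped erosion then drops solitary noise pixels
    # without annihilating the thin band
    closed = morphology.closing(edges, _square(p.close_kernel))
    eroded = morphology.erosion(closed, morphology.disk(p.erode_kernel // 2))
    segments = probabilistic_hough_line(
        eroded,
        threshold=p.hough_threshold,
        line_length=p.min_line_len,
        line_gap=p.max_line_gap,
        rng=0,
    )
    mask = np.zeros(gray.shape, dtype=bool)
    for (x0, y0), (x1, y1) in segments:
        length = float(np.hypot(x1 - x0, y1 - y0))
        if not p.min_line_len <= length <= p.max_line_len:
            continue
        rr, cc = draw_line(y0, x0, y1, x1)
        keep = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
        mask[rr[keep], cc[keep]] = True
    # dilate_radius counts the line pixel itself: the final band is
    # (2 * dilate_radius - 1) px wide, wide enough to cover the shaft
    # without swallowing the surrounding skin
    if mask.any() and p.dilate_radius > 1:
        mask = morphology.dilation(mask, morphology.disk(p.dilate_radius - 1))
    return mask


def inpaint_median(img: np.ndarray, mask: np.ndarray, window: int = 11) -> np.ndarray:
    """Replace masked pixels by the median of unmasked window neighbours.

    Pixels whose window contains no unmasked neighbour are deferred to a
    later sweep (using values filled in earlier sweeps), which terminates
    whenever the mask is not the full frame. Unmasked pixels are returned
    bit-exact.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if mask.shape != img.shape[:2]:
        raise ValueError("mask must align with the image")
    if mask.all():
        raise ValueError("degenerate input: mask covers the entire image")
    out = img.copy()
    known = ~mask.astype(bool)
    pending = list(zip(*np.nonzero(mask)))
    half = window // 2
    h, w = mask.shape
    while pending:
        filled_now: list[tuple[int, int]] = []
        values: list[np.ndarray] = []
        deferred: list[tuple[int, int]] = []
        for (r, c) in pending:
            r0, r1 = max(r - half, 0), min(r + half + 1, h)
            c0, c1 = max(c - half, 0), min(c + half + 1, w)
            nbr_known = known[r0:r1, c0:c1]
            if not nbr_known.any():
                deferred.append((r, c))
                continue
            patch = out[r0:r1, c0:c1]
            med = np.median(patch[nbr_known], axis=0)
            filled_now.append((r, c))
            values.append(np.round(med))
        if not filled_now:  # pragma: no cover - guarded by full-mask check
            raise RuntimeError("inpainting failed to make progress")
        for (r, c), v in zip(filled_now, values):
            out[r, c] = v.astype(img.dtype) if img.dtype != np.float64 else v
            known[r, c] = True
        pending = deferred
    return out


def median_denoise(img: np.ndarray, window: int = 3) -> np.ndarray:
    """Channel-wise median filter with reflection padding at the borders."""
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if img.ndim == 2:
        return ndimage.median_filter(img, size=window, mode="reflect")
    out = np.empty_like(img)
    for ch in range(img.shape[2]):
        out[..., ch] = ndimage.median_filter(img[..., ch], size=window, mode="reflect")
    return out


def preprocess_pipeline(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Full preprocessing: crop corners, resize, remove hair, denoise.

    Cropping runs before resizing so that black framing never gets
    interpolated into the standardized 224x224 frame; the remaining stage
    order (hair detection, median inpainting, median denoising) follows
    the hair-removal recipe. Deterministic: no randomness anywhere.
    """
    cfg = cfg or PreprocessConfig()
    try:
        img = crop_black_corners(img, cfg.corner_black_cutoff)
    except ValueError as exc:
        if "degenerate" in str(exc):
            raise
        raise
    img = resize_image(img, cfg.target_size)
    hair_mask = detect_hair_mask(img, cfg.hair)
    if hair_mask.any():
        img = inpaint_median(img, hair_mask, cfg.hair.inpaint_window)
    return median_denoise(img, cfg.median_filter_window)
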