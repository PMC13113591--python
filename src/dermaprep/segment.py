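"""Lesion segmentation: isolate the lesion from surrounding skin.

Pigmented lesions are darker than the surrounding skin, so the
segmentation is Otsu thresholding on the grayscale frame (foreground =
below threshold), morphological opening to drop speckle, hole filling,
and retention of the largest connected component. The outer boundary of
that component is traced as a closed polygon through pixel centers
(Moore-neighbour border following), which is the convention under which a
full 224x224 foreground frame has polygon area 223^2 = 49729 and
perimeter 4*223 = 892.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from dermaprep.preprocess import to_grayscale

__all__ = ["SegmentationResult", "segment_lesion", "trace_contour", "largest_component"]


@dataclass
class SegmentationResult:
    mask: np.ndarray  # bool H x W, single connected component
    largest_contour: np.ndarray  # N x 2 array of (x, y) pixel centers
    bbox: tuple[int, int, int, int]  # (x, y, w, h), 0-based, half-open


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component."""
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        raise ValueError("mask has no foreground pixels")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


# Moore neighbourhood in clockwise screen order starting East:
# E, SE, S, SW, W, NW, N, NE as (dy, dx).
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def trace_contour(mask: np.ndarray) -> np.ndarray:
    """Closed boundary polygon of the largest component, pixel centers.

    Moore-neighbour border following with Jacob's stopping criterion,
    oriented so that a full-frame mask is traced top edge left-to-right
    first (counter-clockwise in the y-up mathematical convention).
    Returns an (N, 2) array of (x, y) vertices; a single-pixel component
    gives a 1-vertex polygon.
    """
    if not mask.any():
        raise ValueError("cannot trace an empty mask")
    comp = largest_component(mask)
    h, w = comp.shape
    ys, xs = np.nonzero(comp)
    # uppermost, then leftmost foreground pixel
    start = (int(ys.min()), int(xs[ys == ys.min()].min()))

    def fg(p: tuple[int, int]) -> bool:
        return 0 <= p[0] < h and 0 <= p[1] < w and comp[p]

    # single-pixel component
    if not any(fg((start[0] + dy, start[1] + dx)) for dy, dx in _MOORE):
        return np.array([[start[1], start[0]]], dtype=np.float64)

    # backtrack starts at the pixel above start (background, since start
    # is the uppermost foreground pixel); search clockwise from it. The
    # walk is a deterministic map on (pixel, backtrack) states, so the
    # boundary cycle is exactly the path between two visits of one state.
    backtrack_dir = _MOORE.index((-1, 0))
    cur = start
    contour: list[tuple[int, int]] = []
    seen: dict[tuple, int] = {}
    while True:
        key = (cur, backtrack_dir)
        if key in seen:
            contour = contour[seen[key] :]
            break
        seen[key] = len(contour)
        contour.append(cur)
        for k in range(1, 9):
            d = (backtrack_dir + k) % 8
            dy, dx = _MOORE[d]
            cand = (cur[0] + dy, cur[1] + dx)
            if fg(cand):
                # neighbour checked just before cand, seen from cand
                back = (
                    cur[0] + _MOORE[(d - 1) % 8][0] - cand[0],
                    cur[1] + _MOORE[(d - 1) % 8][1] - cand[1],
                )
                backtrack_dir = _MOORE.index(back)
                cur = cand
                break
    # canonical start: rotate the cycle to the uppermost-leftmost vertex
    pivot = min(range(len(contour)), key=lambda i: contour[i])
    contour = contour[pivot:] + contour[:pivot]
    return np.array([[c, r] for r, c in contour], dtype=np.float64)


def segment_lesion(img: np.ndarray) -> SegmentationResult:
    """Otsu-threshold segmentation of a (hair-removed) RGB frame."""
    gray = to_grayscale(img)
    if gray.min() == gray.max():
        raise ValueError("degenerate input: uniform image, nothing to segment")
    thresh = filters.threshold_otsu(gray)
    fore = gray <= thresh  # lesion is darker than the surrounding skin
    fore = morphology.opening(fore, morphology.disk(1))
    if not fore.any():
        raise ValueError("degenerate input: no foreground after opening")
    fore = ndimage.binary_fill_holes(fore)
    comp = largest_component(fore)
    contour = trace_contour(comp)
    ys, xs = np.nonzero(comp)
    x0, y0 = int(xs.min()), int(ys.min())
    bbox = (x0, y0, int(xs.max()) - x0 + 1, int(ys.max()) - y0 + 1)
    return SegmentationResult(mask=comp, largest_contour=contour, bbox=bbox)
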