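"""Classical descriptors: GLCM texture, contour shape, HOG, PCA, Canny.

Texture is summarized by four Haralick-style statistics of the gray-level
co-occurrence matrix (contrast, correlation, energy, homogeneity),
averaged over the four standard offsets {0, 45, 90, 135} degrees. Shape
descriptors (area, perimeter, aspect ratio) use the pixel-center polygon
convention of the segmentation module. Energy is the angular second
moment sum(P^2); homogeneity is the inverse difference moment
sum(P/(1+(i-j)^2)); correlation of a zero-variance image is defined as 1
(the degenerate perfectly-correlated limit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from skimage import feature

__all__ = [
    "GLCMParams",
    "FeatureRecord",
    "glcm_features",
    "shape_features",
    "hog_features",
    "pca_reduce",
    "canny_edges",
]

_DEFAULT_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


@dataclass(frozen=True)
class GLCMParams:
    distance: int = 1
    angles: tuple[float, ...] = _DEFAULT_ANGLES  # radians
    levels: int = 256
    symmetric: bool = True
    normalized: bool = True

    def validate(self) -> None:
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")


@dataclass
class FeatureRecord:
    contrast: float
    correlation: float
    energy: float
    homogeneity: float
    area: float
    perimeter: float
    aspect: float
    hog: np.ndarray | None = None

    def as_row(self) -> list[float]:
        return [
            self.contrast,
            self.correlation,
            self.energy,
            self.homogeneity,
            self.area,
            self.perimeter,
            self.aspect,
        ]


def _glcm_stats(P: np.ndarray) -> tuple[float, float, float, float]:
    """Contrast/correlation/energy/homogeneity of one normalized GLCM."""
    levels = P.shape[0]
    i = np.arange(levels, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = ii - jj
    contrast = float(np.sum(P * diff**2))
    energy = float(np.sum(P**2))
    homogeneity = float(np.sum(P / (1.0 + diff**2)))
    mu_i = float(np.sum(ii * P))
    mu_j = float(np.sum(jj * P))
    var_i = float(np.sum((ii - mu_i) ** 2 * P))
    var_j = float(np.sum((jj - mu_j) ** 2 * P))
    denom = np.sqrt(var_i * var_j)
    if denom == 0.0:
        correlation = 1.0
    else:
        correlation = float(np.sum(P * (ii - mu_i) * (jj - mu_j)) / denom)
    return contrast, correlation, energy, homogeneity


def glcm_features(
    gray: np.ndarray, p: GLCMParams | None = None
) -> tuple[float, float, float, float]:
    """(contrast, correlation, energy, homogeneity), averaged over angles.

    The co-occurrence matrix at offset distance*(cos a, sin a) is
    symmetrized and normalized to a joint probability P(i, j) before the
    statistics are taken.
    """
    p = p or GLCMParams()
    p.validate()
    if gray.ndim != 2:
        raise ValueError("glcm_features expects a single-channel image")
    if min(gray.shape) <= p.distance:
        raise ValueError("image smaller than the co-occurrence offset")
    if gray.max() >= p.levels:
        raise ValueError(f"gray levels must be < levels={p.levels}")
    glcm = feature.graycomatrix(
        gray.astype(np.uint8),
        distances=[p.distance],
        angles=list(p.angles),
        levels=p.levels,
        symmetric=p.symmetric,
        normed=p.normalized,
    )
    per_angle = [_glcm_stats(glcm[:, :, 0, k]) for k in range(len(p.angles))]
    return tuple(float(np.mean(col)) for col in zip(*per_angle))  # type: ignore[return-value]


def shape_features(
    contour: np.ndarray, bbox: tuple[int, int, int, int]
) -> tuple[float, float, float]:
    """(area, perimeter, aspect) of a closed pixel-center polygon.

    Area is the absolute shoelace area; perimeter is the sum of Euclidean
    edge lengths including the closing edge (axis steps contribute 1,
    diagonal steps sqrt(2)); aspect is bbox width / height.
    """
    contour = np.asarray(contour, dtype=np.float64)
    _, _, bw, bh = bbox
    if bh <= 0:
        raise ValueError("bbox height must be positive")
    aspect = float(bw) / float(bh)
    if len(contour) < 3:
        warnings.warn("contour has fewer than 3 vertices; area/perimeter set to 0")
        return 0.0, 0.0, aspect
    x, y = contour[:, 0], contour[:, 1]
    area = 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))
    edges = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    perimeter = float(np.sum(np.hypot(edges[:, 0], edges[:, 1])))
    return area, perimeter, aspect


def hog_features(
    gray: np.ndarray, orientations: int = 9, cell: int = 8, block: int = 2
) -> np.ndarray:
    """Histogram-of-oriented-gradients vector (L2 block norm, 0.2 clip)."""
    if gray.ndim != 2:
        raise ValueError("hog_features expects a single-channel image")
    h, w = gray.shape
    if h % cell or w % cell:
        raise ValueError("image dimensions must be divisible by the cell size")
    return feature.hog(
        gray.astype(np.float64),
        orientations=orientations,
        pixels_per_cell=(cell, cell),
        cells_per_block=(block, block),
        block_norm="L2-Hys",
        feature_vector=True,
    )


def pca_reduce(
    X: np.ndarray, var_target: float = 0.95
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-centered PCA keeping the smallest k with cumulative
    explained-variance ratio >= var_target.

    Returns (scores, components, explained_variance_ratio) for the k
    retained components; components are orthonormal rows.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not 0.0 < var_target <= 1.0:
        raise ValueError("var_target must lie in (0, 1]")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: constant matrix has no variance")
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(ratios), var_target - 1e-12) + 1)
    k = min(k, len(ratios))
    return scores[:, :k], pca.components_[:k], ratios[:k]


def canny_edges(gray: np.ndarray, low: int = 50, high: int = 150) -> np.ndarray:
    """Canny edge map: Gaussian smooth (sigma 1.4), Sobel gradients,
    non-maximum suppression, hysteresis thresholding. Thresholds are
    8-bit-style values (see preprocess module for the scaling)."""
    if not 0 < low < high:
        raise ValueError("require 0 < low < high")
    from dermaprep.preprocess import _CANNY_SCALE, to_grayscale

    g = to_grayscale(gray) if gray.ndim == 3 else gray
    return feature.canny(
        g.astype(np.float64) / 255.0,
        sigma=1.4,
        low_threshold=low / _CANNY_SCALE,
        high_threshold=high / _CANNY_SCALE,
    )
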