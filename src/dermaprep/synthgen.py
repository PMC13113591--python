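"""Seeded generator of synthetic dermoscopy-like images with ground truth.

Real dermoscopic archives of melanoma vs. non-melanoma skin cancer are
frequently private, so the pipeline is exercised on synthetic scenes that
emulate the statistical structure the method assumes: a skin-tone
background with a linear illumination gradient, a single elliptical lesion
whose border irregularity and internal colour variegation are
class-conditional (melanoma lesions draw several dark colour patches and a
strongly perturbed border; non-melanoma lesions are near-elliptical and
uniform), dark curvilinear hair strokes rendered as quadratic Bezier
polylines, and an optional circular field-of-view vignette with pure-black
corners.

Every output is a pure function of the spec dataclasses and an integer
seed; hair and lesion masks are exact rasterizations (no anti-aliasing).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from skimage import draw, morphology
from PIL import Image as PILImage

__all__ = [
    "SceneSpec",
    "LesionSpec",
    "HairSpec",
    "GeneratedSample",
    "DatasetManifest",
    "generate_image",
    "generate_dataset",
    "MELANOMA_PALETTE",
]

# Dark variegation palette seen inside melanocytic lesions:
# near-black, dark brown, red-brown, blue-gray.
MELANOMA_PALETTE: tuple[tuple[int, int, int], ...] = (
    (25, 20, 20),
    (70, 40, 25),
    (110, 50, 40),
    (80, 90, 110),
)


@dataclass(frozen=True)
class SceneSpec:
    """Background/acquisition parameters for one synthetic frame."""

    width: int = 224
    height: int = 224
    skin_tone: tuple[int, int, int] = (205, 165, 145)
    illum_gradient: float = 0.15
    vignette: bool = False
    noise_sigma: float = 3.0

    def validate(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("frame must be at least 64x64 px")
        if not all(120 <= c <= 230 for c in self.skin_tone):
            raise ValueError("skin_tone channels must lie in [120, 230]")
        if not 0.0 <= self.illum_gradient <= 0.3:
            raise ValueError("illum_gradient must lie in [0, 0.3]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class LesionSpec:
    """One elliptical lesion with class-conditional morphology.

    ``border_irregularity`` is the amplitude of a smooth radial
    perturbation of the ellipse boundary (fraction of the local radius);
    ``asymmetry`` shrinks one half of the lesion; ``n_color_patches``
    controls internal colour variegation (melanoma >= 3, benign <= 1).
    """

    class_label: int = 0  # 1 = melanoma, 0 = non-melanoma
    center: tuple[float, float] = (112.0, 112.0)  # (x, y)
    axes: tuple[float, float] = (45.0, 35.0)  # semi-axes (a, b), px
    border_irregularity: float = 0.05
    asymmetry: float = 0.1
    n_color_patches: int = 0
    base_color: tuple[int, int, int] = (150, 105, 85)

    def validate(self, scene: SceneSpec) -> None:
        if self.class_label not in (0, 1):
            raise ValueError("class_label must be 0 or 1")
        if not 0.0 <= self.border_irregularity <= 0.5:
            raise ValueError("border_irregularity must lie in [0, 0.5]")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ValueError("asymmetry must lie in [0, 1]")
        if self.class_label == 1 and (
            self.n_color_patches < 3 or self.border_irregularity < 0.2
        ):
            raise ValueError(
                "melanoma lesions require n_color_patches >= 3 and "
                "border_irregularity >= 0.2"
            )
        if self.class_label == 0 and (
            self.n_color_patches > 1 or self.border_irregularity > 0.1
        ):
            raise ValueError(
                "non-melanoma lesions require n_color_patches <= 1 and "
                "border_irregularity <= 0.1"
            )
        cx, cy = self.center
        reach = max(self.axes) * (1.0 + self.border_irregularity)
        if (
            cx - reach < 8
            or cy - reach < 8
            or cx + reach > scene.width - 8
            or cy + reach > scene.height - 8
        ):
            raise ValueError("lesion must fit inside the frame with >= 8 px margin")


@dataclass(frozen=True)
class HairSpec:
    """Curvilinear hair strokes drawn over the scene."""

    n_hairs: int = 8
    thickness: int = 2
    length_range: tuple[int, int] = (60, 140)
    curvature: float = 0.25  # max perpendicular bend, fraction of length
    color: tuple[int, int, int] = (35, 25, 20)
    bright_fraction: float = 0.0

    def validate(self, scene: SceneSpec) -> None:
        if self.n_hairs < 0:
            raise ValueError("n_hairs must be >= 0")
        if not 1 <= self.thickness <= 3:
            raise ValueError("thickness must lie in [1, 3] px")
        lo, hi = self.length_range
        if lo < 10 or hi > min(scene.width, scene.height) or lo > hi:
            raise ValueError("length_range must lie within [10, min(width, height)]")
        if not 0.0 <= self.bright_fraction <= 1.0:
            raise ValueError("bright_fraction must lie in [0, 1]")


@dataclass
class GeneratedSample:
    image: np.ndarray  # uint8 H x W x 3
    lesion_mask: np.ndarray  # bool H x W
    hair_mask: np.ndarray  # bool H x W
    label: int


@dataclass
class DatasetManifest:
    out_dir: str
    seed: int
    n_melanoma: int
    n_non_melanoma: int
    files: list[dict] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[str, int]:
        return {"melanoma": self.n_melanoma, "non_melanoma": self.n_non_melanoma}


def _radial_perturbation(rng: np.random.Generator, theta: np.ndarray) -> np.ndarray:
    """Smooth zero-mean 2*pi-periodic profile, normalized to max |.| = 1."""
    harmonics = np.arange(2, 7)
    amps = rng.uniform(0.3, 1.0, size=harmonics.size)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=harmonics.size)
    prof = np.zeros_like(theta)
    for k, a, p in zip(harmonics, amps, phases):
        prof += a * np.sin(k * theta + p)
    return prof / np.max(np.abs(prof))


def _rasterize_lesion(
    scene: SceneSpec, lesion: LesionSpec, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask of the (possibly perturbed, asymmetric) lesion."""
    ys, xs = np.mgrid[0 : scene.height, 0 : scene.width]
    cx, cy = lesion.center
    dx = xs - cx
    dy = ys - cy
    theta = np.arctan2(dy, dx)
    r = np.hypot(dx, dy)
    a, b = lesion.axes
    # ellipse radius along theta
    r_ell = (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    boundary = r_ell.copy()
    if lesion.border_irregularity > 0:
        boundary = boundary * (
            1.0 + lesion.border_irregularity * _radial_perturbation(rng, theta)
        )
    if lesion.asymmetry > 0:
        # shrink the right half to break bilateral symmetry
        boundary = boundary * np.where(
            np.cos(theta) > 0, 1.0 - 0.25 * lesion.asymmetry, 1.0
        )
    return r <= boundary


def _paint_color_patches(
    img: np.ndarray,
    lesion_mask: np.ndarray,
    lesion: LesionSpec,
    rng: np.random.Generator,
) -> None:
    """Small dark ellipses inside the lesion (colour variegation)."""
    ys, xs = np.nonzero(lesion_mask)
    if ys.size == 0 or lesion.n_color_patches == 0:
        return
    a, b = lesion.axes
    for _ in range(lesion.n_color_patches):
        idx = rng.integers(0, ys.size)
        pcy, pcx = ys[idx], xs[idx]
        pa = rng.uniform(0.15, 0.35) * a
        pb = rng.uniform(0.15, 0.35) * b
        rot = rng.uniform(0.0, np.pi)
        color = MELANOMA_PALETTE[rng.integers(0, len(MELANOMA_PALETTE))]
        rr, cc = draw.ellipse(
            pcy, pcx, pb, pa, rotation=rot, shape=lesion_mask.shape
        )
        inside = lesion_mask[rr, cc]
        img[rr[inside], cc[inside]] = color


def _draw_hairs(
    img: np.ndarray, hair: HairSpec, rng: np.random.Generator
) -> np.ndarray:
    """Render quadratic Bezier strokes; returns the exact stroked mask."""
    h, w = img.shape[:2]
    mask = np.zeros((h, w), dtype=bool)
    bright_color = (235, 230, 225)
    for i in range(hair.n_hairs):
        length = rng.uniform(*hair.length_range)
        x0 = rng.uniform(0, w)
        y0 = rng.uniform(0, h)
        ang = rng.uniform(0.0, 2.0 * np.pi)
        x2 = x0 + length * np.cos(ang)
        y2 = y0 + length * np.sin(ang)
        # control point offset perpendicular to the chord
        bend = rng.uniform(-hair.curvature, hair.curvature) * length
        mx, my = (x0 + x2) / 2.0, (y0 + y2) / 2.0
        x1 = mx - bend * np.sin(ang)
        y1 = my + bend * np.cos(ang)
        t = np.linspace(0.0, 1.0, max(int(2 * length), 8))
        bx = (1 - t) ** 2 * x0 + 2 * (1 - t) * t * x1 + t**2 * x2
        by = (1 - t) ** 2 * y0 + 2 * (1 - t) * t * y1 + t**2 * y2
        stroke = np.zeros((h, w), dtype=bool)
        for j in range(len(t) - 1):
            rr, cc = draw.line(
                int(round(by[j])),
                int(round(bx[j])),
                int(round(by[j + 1])),
                int(round(bx[j + 1])),
            )
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            stroke[rr[keep], cc[keep]] = True
        if hair.thickness > 1:
            stroke = morphology.dilation(
                stroke, np.ones((hair.thickness, hair.thickness), dtype=bool)
            )
        is_bright = rng.uniform() < hair.bright_fraction
        img[stroke] = bright_color if is_bright else hair.color
        mask |= stroke
    return mask


def _apply_vignette(img: np.ndarray) -> None:
    """Pure-black disk-complement corner artifact (microscope field stop)."""
    h, w = img.shape[:2]
    radius = 0.48 * min(h, w)
    ys, xs = np.mgrid[0:h, 0:w]
    outside = np.hypot(ys - (h - 1) / 2.0, xs - (w - 1) / 2.0) > radius
    img[outside] = (0, 0, 0)


def generate_image(
    scene: SceneSpec,
    lesion: LesionSpec,
    hair: HairSpec,
    seed: int,
) -> GeneratedSample:
    """Render one frame; bit-identical for identical (specs, seed).

    Render order: skin background with linear left-to-right illumination
    gradient, lesion fill + colour patches, Gaussian pixel noise, hair
    strokes (crisp, on top of the noise so truth masks stay exact), and
    finally the vignette, painted pure black.
    """
    scene.validate()
    lesion.validate(scene)
    hair.validate(scene)
    rng = np.random.default_rng(seed)

    h, w = scene.height, scene.width
    img = np.empty((h, w, 3), dtype=np.float64)
    illum = 1.0 + scene.illum_gradient * (np.linspace(0, 1, w) - 0.5)
    img[:] = np.asarray(scene.skin_tone, dtype=np.float64)
    img *= illum[None, :, None]

    lesion_mask = _rasterize_lesion(scene, lesion, rng)
    img[lesion_mask] = np.asarray(lesion.base_color, dtype=np.float64)

    img_u8 = np.clip(img, 0, 255).astype(np.uint8)
    _paint_color_patches(img_u8, lesion_mask, lesion, rng)

    if scene.noise_sigma > 0:
        noisy = img_u8.astype(np.float64) + rng.normal(
            0.0, scene.noise_sigma, size=img_u8.shape
        )
        img_u8 = np.clip(noisy, 0, 255).astype(np.uint8)

    hair_mask = _draw_hairs(img_u8, hair, rng)

    if scene.vignette:
        _apply_vignette(img_u8)

    return GeneratedSample(
        image=img_u8,
        lesion_mask=lesion_mask,
        hair_mask=hair_mask,
        label=lesion.class_label,
    )


def sample_specs(
    class_label: int,
    rng: np.random.Generator,
    *,
    width: int = 224,
    height: int = 224,
    vignette: bool = False,
    with_hair: bool = True,
) -> tuple[SceneSpec, LesionSpec, HairSpec]:
    """Draw class-conditional scene/lesion/hair specs.

    Melanoma lesions get >= 3 dark colour patches and strong border
    irregularity/asymmetry; non-melanoma lesions are near-elliptical and
    uniform. Everything else (skin tone, lesion size, hair load) is shared
    between classes so that only morphology and variegation separate them.
    """
    r = int(rng.integers(190, 213))
    g = r - int(rng.integers(28, 43))
    skin = (r, g, g - int(rng.integers(12, 26)))
    scene = SceneSpec(
        width=width,
        height=height,
        skin_tone=skin,
        illum_gradient=float(rng.uniform(0.0, 0.25)),
        vignette=vignette,
        noise_sigma=float(rng.uniform(1.0, 4.0)),
    )
    if class_label == 1:
        irregularity = float(rng.uniform(0.2, 0.45))
        asym = float(rng.uniform(0.3, 0.8))
        n_patches = int(rng.integers(3, 7))
        base = (
            int(rng.integers(90, 130)),
            int(rng.integers(55, 85)),
            int(rng.integers(40, 70)),
        )
    else:
        irregularity = float(rng.uniform(0.0, 0.1))
        asym = float(rng.uniform(0.0, 0.3))
        n_patches = int(rng.integers(0, 2))
        base = (
            int(rng.integers(130, 170)),
            int(rng.integers(90, 120)),
            int(rng.integers(70, 100)),
        )
    a = float(rng.uniform(30, 55))
    b = float(rng.uniform(0.6, 1.0)) * a
    reach = a * (1.0 + irregularity) + 8
    cx = float(rng.uniform(reach, width - reach))
    cy = float(rng.uniform(reach, height - reach))
    lesion = LesionSpec(
        class_label=class_label,
        center=(cx, cy),
        axes=(a, b),
        border_irregularity=irregularity,
        asymmetry=asym,
        n_color_patches=n_patches,
        base_color=base,
    )
    hair_cfg = HairSpec(
        n_hairs=int(rng.integers(3, 11)) if with_hair else 0,
        thickness=int(rng.integers(1, 4)),
        length_range=(60, min(width, height) - 10),
        curvature=float(rng.uniform(0.05, 0.3)),
    )
    return scene, lesion, hair_cfg


def _save_png(path: Path, arr: np.ndarray) -> None:
    PILImage.fromarray(arr).save(path)


def generate_dataset(
    n_per_class: tuple[int, int],
    seed: int,
    out_dir: str | Path,
    *,
    vignette: bool = False,
    with_hair: bool = True,
    image_size: int = 224,
) -> DatasetManifest:
    """Write a labelled synthetic dataset to ``out_dir``.

    ``n_per_class`` is ``(n_melanoma, n_non_melanoma)``; the default study
    composition this emulates is 200 melanoma vs. 1000 non-melanoma. Each
    image gets its own RNG stream spawned from ``(seed, image index)`` so
    datasets are order-independent and reproducible per image.

    Outputs: ``img_XXXXX.png``, ``lesion_XXXXX.png`` / ``hair_XXXXX.png``
    truth masks (0/255), ``labels.csv`` (``filename,label``) and
    ``manifest.yaml``.
    """
    n_mel, n_nmsc = n_per_class
    if n_mel < 1 or n_nmsc < 1:
        raise ValueError("both class counts must be >= 1")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    labels = [1] * n_mel + [0] * n_nmsc
    manifest = DatasetManifest(
        out_dir=str(out), seed=seed, n_melanoma=n_mel, n_non_melanoma=n_nmsc
    )
    rows = []
    for idx, label in enumerate(labels):
        child = np.random.default_rng(np.random.SeedSequence([seed, idx]))
        spec_rng = np.random.default_rng(np.random.SeedSequence([seed, idx, 1]))
        scene, lesion, hair_cfg = sample_specs(
            label,
            spec_rng,
            width=image_size,
            height=image_size,
            vignette=vignette,
            with_hair=with_hair,
        )
        render_seed = int(child.integers(0, 2**31 - 1))
        sample = generate_image(scene, lesion, hair_cfg, render_seed)
        name = f"img_{idx:05d}.png"
        _save_png(out / name, sample.image)
        _save_png(out / f"lesion_{idx:05d}.png", sample.lesion_mask.astype(np.uint8) * 255)
        _save_png(out / f"hair_{idx:05d}.png", sample.hair_mask.astype(np.uint8) * 255)
        rows.append((name, label))
        manifest.files.append(
            {
                "filename": name,
                "label": label,
                "lesion_mask": f"lesion_{idx:05d}.png",
                "hair_mask": f"hair_{idx:05d}.png",
                "render_seed": render_seed,
            }
        )

    with open(out / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label"])
        writer.writerows(rows)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "seed": seed,
                "n_melanoma": n_mel,
                "n_non_melanoma": n_nmsc,
                "image_size": image_size,
                "vignette": vignette,
                "with_hair": with_hair,
                "files": manifest.files,
            },
            fh,
            sort_keys=False,
        )
    return manifest
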