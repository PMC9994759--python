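"""Seeded synthetic endometrial slides with ground truth.

The generator emulates the three presentations seen in real biopsy slides:
a few large contiguous tissue pieces, many small tissue fragments, and
slides dominated by blood or mucus.  Tissue pieces are elliptical blobs
drawn on the level-5 grid; each region class paints the level-0 raster with
a class-specific mean colour plus independent Gaussian pixel noise, so the
classes are separable both by raw colour (pixel classifier) and by patch
statistics (patch classifier), while remaining non-trivial.

Everything is driven by a single integer seed: the same spec and seed
produce bit-identical pyramids and masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as draw_polygon

from .masks import (
    PolygonOverride,
    RegionClass,
    SlideAnnotation,
    SlideGroundTruth,
)
from .pyramid import DEFAULT_MPP, ImagePyramid, build_pyramid

#: default per-class RGB means and noise standard deviations (8-bit scale).
#: Background is near-white (grey > 0.85), tissue classes are H&E-like
#: purples, blood/mucus is red; all well separated in mean colour.
DEFAULT_PALETTES: dict[str, tuple[tuple[float, float, float], float]] = {
    "background": ((245.0, 243.0, 246.0), 2.0),
    "other_benign": ((182.0, 128.0, 188.0), 12.0),
    "malignant": ((120.0, 64.0, 144.0), 14.0),
    "blood_mucus": ((168.0, 48.0, 60.0), 10.0),
}

#: tissue area below this fraction of the slide marks it "insufficient"
INSUFFICIENT_TISSUE_FRACTION = 0.01

_N_POLY_VERTICES = 48


@dataclass
class SyntheticSlideSpec:
    """Parameters of one synthetic slide.

    ``fragmentation`` selects the phenotype: ``large_pieces`` draws a few
    big blobs, ``many_fragments`` draws many small ones.
    ``malignant_fraction`` is the target fraction of tissue area that is
    malignant; ``blood_fraction`` the target fraction of slide area covered
    by blood or mucus (placed off-tissue).
    """

    base_size: tuple[int, int] = (3072, 3072)  # (width, height) level-0 px
    n_tissue_pieces: int = 4
    fragmentation: str = "large_pieces"
    malignant_fraction: float = 0.0
    blood_fraction: float = 0.0
    palettes: dict = field(default_factory=lambda: dict(DEFAULT_PALETTES))
    microns_per_pixel_level0: float = DEFAULT_MPP
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.base_size, int):
            self.base_size = (self.base_size, self.base_size)
        w, h = self.base_size
        if w <= 0 or h <= 0:
            raise ValueError("base size must be positive")
        if self.fragmentation not in ("large_pieces", "many_fragments"):
            raise ValueError(f"unknown fragmentation {self.fragmentation!r}")
        if not 0.0 <= self.malignant_fraction <= 1.0:
            raise ValueError("malignant_fraction must be in [0, 1]")
        if not 0.0 <= self.blood_fraction <= 1.0:
            raise ValueError("blood_fraction must be in [0, 1]")
        if self.n_tissue_pieces < 0:
            raise ValueError("n_tissue_pieces must be non-negative")


def _ellipse_polygon(
    cx: float, cy: float, rx: float, ry: float, angle: float
) -> np.ndarray:
    """Vertices (x, y) of a rotated ellipse, counter-clockwise."""
    t = np.linspace(0.0, 2.0 * math.pi, _N_POLY_VERTICES, endpoint=False)
    x = rx * np.cos(t)
    y = ry * np.sin(t)
    ca, sa = math.cos(angle), math.sin(angle)
    return np.column_stack([cx + ca * x - sa * y, cy + sa * x + ca * y])


def _rasterize(poly_xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(poly_xy[:, 1], poly_xy[:, 0], shape=shape)
    out[rr, cc] = True
    return out


def _piece_radii(rng: np.random.Generator, fragmentation: str, dim5: int):
    if fragmentation == "large_pieces":
        lo, hi = 0.09 * dim5, 0.18 * dim5
    else:
        lo, hi = 0.028 * dim5, 0.055 * dim5
    rx = rng.uniform(lo, hi)
    ry = rx * rng.uniform(0.5, 1.0)
    return rx, ry


def generate_slide(spec: SyntheticSlideSpec) -> tuple[ImagePyramid, SlideGroundTruth]:
    """Generate one synthetic slide.

    Returns the image pyramid (levels 0-5) and its ground truth: the level-5
    class mask, the slide label and the overall-class-plus-overrides
    annotation.  The slide label follows from what was drawn: no tissue (or
    less than 1% of the slide area) is ``insufficient``, any malignant
    region makes the slide ``malignant``, otherwise ``other_or_benign``.
    """
    rng = np.random.default_rng(spec.seed)
    base_w, base_h = spec.base_size
    h5, w5 = math.ceil(base_h / 32), math.ceil(base_w / 32)
    dim5 = min(h5, w5)

    tissue = np.zeros((h5, w5), dtype=bool)
    pieces: list[np.ndarray] = []  # level-5 polygons
    for _ in range(spec.n_tissue_pieces):
        rx, ry = _piece_radii(rng, spec.fragmentation, dim5)
        cx = rng.uniform(rx + 1, w5 - rx - 1) if w5 > 2 * (rx + 1) else w5 / 2
        cy = rng.uniform(ry + 1, h5 - ry - 1) if h5 > 2 * (ry + 1) else h5 / 2
        poly = _ellipse_polygon(cx, cy, rx, ry, rng.uniform(0, math.pi))
        pieces.append(poly)
        tissue |= _rasterize(poly, (h5, w5))

    # malignant sub-regions: whole pieces (or a scaled-down inset of the
    # last piece) are marked malignant until the target tissue fraction of
    # malignant area is reached
    malignant = np.zeros_like(tissue)
    malignant_polys: list[np.ndarray] = []
    tissue_cells = int(tissue.sum())
    if spec.malignant_fraction > 0 and tissue_cells > 0:
        target = spec.malignant_fraction * tissue_cells
        order = rng.permutation(len(pieces))
        for idx in order:
            done = int(malignant.sum())
            if done >= target - 0.5:
                break
            poly = pieces[idx]
            piece_mask = _rasterize(poly, (h5, w5)) & tissue & ~malignant
            piece_area = int(piece_mask.sum())
            if piece_area == 0:
                continue
            remaining = target - done
            if piece_area <= remaining * 1.15:
                malignant |= piece_mask
                malignant_polys.append(poly)
            else:
                centre = poly.mean(axis=0)
                scale = math.sqrt(remaining / piece_area)
                inset = centre + (poly - centre) * scale
                malignant |= _rasterize(inset, (h5, w5)) & tissue
                malignant_polys.append(inset)

    # blood / mucus: elliptical clots placed on background only
    blood = np.zeros_like(tissue)
    if spec.blood_fraction > 0:
        target_blood = spec.blood_fraction * h5 * w5
        for _ in range(200):
            if blood.sum() >= target_blood:
                break
            rx = rng.uniform(0.05, 0.14) * dim5
            ry = rx * rng.uniform(0.5, 1.0)
            cx = rng.uniform(rx + 1, w5 - rx - 1) if w5 > 2 * (rx + 1) else w5 / 2
            cy = rng.uniform(ry + 1, h5 - ry - 1) if h5 > 2 * (ry + 1) else h5 / 2
            poly = _ellipse_polygon(cx, cy, rx, ry, rng.uniform(0, math.pi))
            blood |= _rasterize(poly, (h5, w5)) & ~tissue

    class_mask = np.full((h5, w5), int(RegionClass.BACKGROUND), dtype=np.uint8)
    class_mask[blood] = int(RegionClass.BLOOD_MUCUS)
    class_mask[tissue & ~malignant] = int(RegionClass.OTHER_BENIGN)
    class_mask[malignant] = int(RegionClass.MALIGNANT)

    # slide label from what was drawn
    n_tissue = int(((class_mask == RegionClass.OTHER_BENIGN) |
                    (class_mask == RegionClass.MALIGNANT)).sum())
    if n_tissue < INSUFFICIENT_TISSUE_FRACTION * h5 * w5:
        slide_label = "insufficient"
    elif int(malignant.sum()) > 0:
        slide_label = "malignant"
    else:
        slide_label = "other_or_benign"

    annotation = _build_annotation(class_mask, malignant_polys, pieces)
    pyramid = _paint_pyramid(spec, class_mask, rng, base_w, base_h)
    truth = SlideGroundTruth(slide_label, class_mask, annotation)
    return pyramid, truth


def _build_annotation(
    class_mask: np.ndarray,
    malignant_polys: list[np.ndarray],
    pieces: list[np.ndarray],
) -> SlideAnnotation:
    """Overall class = majority tissue class; the minority class is outlined.

    Matches the annotation convention for real slides: a single class for
    the whole slide plus polygon overrides only where tissue differs, which
    keeps the annotation effort low on fragmented slides.
    """
    n_mal = int((class_mask == RegionClass.MALIGNANT).sum())
    n_ben = int((class_mask == RegionClass.OTHER_BENIGN).sum())
    if n_mal > n_ben:
        overall = "malignant"
        # override polygons: benign pieces (those not fully malignant)
        overrides = []
        h5, w5 = class_mask.shape
        for poly in pieces:
            cells = _rasterize(poly, (h5, w5))
            if (class_mask[cells] == RegionClass.OTHER_BENIGN).any():
                overrides.append(PolygonOverride(poly * 32.0, "other_or_benign"))
        # carve malignant insets back out where they sit inside benign pieces
        for poly in malignant_polys:
            overrides.append(PolygonOverride(poly * 32.0, "malignant"))
    else:
        overall = "other_or_benign"
        overrides = [
            PolygonOverride(poly * 32.0, "malignant") for poly in malignant_polys
        ]
    return SlideAnnotation(overall, overrides)


def _paint_pyramid(
    spec: SyntheticSlideSpec,
    class_mask: np.ndarray,
    rng: np.random.Generator,
    base_w: int,
    base_h: int,
) -> ImagePyramid:
    """Paint the level-0 raster from the class mask and build the pyramid."""
    names = {
        int(RegionClass.BACKGROUND): "background",
        int(RegionClass.BLOOD_MUCUS): "blood_mucus",
        int(RegionClass.OTHER_BENIGN): "other_benign",
        int(RegionClass.MALIGNANT): "malignant",
    }
    means = np.zeros((4, 3), dtype=np.float32)
    stds = np.zeros(4, dtype=np.float32)
    for code, name in names.items():
        mean, std = spec.palettes[name]
        means[code] = mean
        stds[code] = std

    up = np.repeat(np.repeat(class_mask, 32, axis=0), 32, axis=1)
    up = up[:base_h, :base_w]
    base = means[up]  # (H, W, 3) float32
    noise = rng.standard_normal(size=base.shape, dtype=np.float32)
    base += noise * stds[up][..., None]
    base = np.clip(base, 0, 255).astype(np.uint8)
    return build_pyramid(base, n_levels=6,
                         microns_per_pixel_level0=spec.microns_per_pixel_level0)
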