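"""Multi-resolution image pyramids.

A whole-slide image is stored as an ordered stack of RGB rasters in which
level ``l`` is downsampled by ``2**l`` relative to the full-resolution base
(level 0).  One level-5 pixel therefore covers a 32x32 pixel footprint at
level 0.  Physical scale is carried as microns per pixel at level 0
(0.25 um for a 40x scan).

Pyramids are serialised as one PNG per level plus a YAML sidecar holding the
base dimensions and pixel size; vendor formats are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

DEFAULT_MPP = 0.25  # microns per level-0 pixel at 40x


def _level_shape(base_h: int, base_w: int, level: int) -> tuple[int, int]:
    return (math.ceil(base_h / 2**level), math.ceil(base_w / 2**level))


@dataclass
class ImagePyramid:
    """Ordered list of RGB rasters, level 0 first.

    Invariants: level ``l`` has dimensions ``ceil(base / 2**l)`` per axis,
    level 0 is present, and pixel values are uint8 in [0, 255].
    """

    levels: list[np.ndarray] = field(repr=False)
    microns_per_pixel_level0: float = DEFAULT_MPP

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("pyramid must contain at least level 0")
        base = self.levels[0]
        if base.ndim != 3 or base.shape[2] != 3:
            raise ValueError("levels must be (H, W, 3) RGB rasters")
        for l, raster in enumerate(self.levels):
            expect = _level_shape(base.shape[0], base.shape[1], l)
            if raster.shape[:2] != expect:
                raise ValueError(
                    f"level {l} has shape {raster.shape[:2]}, expected {expect}"
                )

    @property
    def base_height(self) -> int:
        return self.levels[0].shape[0]

    @property
    def base_width(self) -> int:
        return self.levels[0].shape[1]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level(self, level: int) -> np.ndarray:
        if level < 0 or level >= len(self.levels):
            raise ValueError(f"unknown level {level}")
        return self.levels[level]


def downsample2x(raster: np.ndarray) -> np.ndarray:
    """Average 2x2 blocks; odd extents are edge-replicated before pooling."""
    h, w = raster.shape[:2]
    ph, pw = h % 2, w % 2
    if ph or pw:
        raster = np.pad(raster, ((0, ph), (0, pw), (0, 0)), mode="edge")
    r = raster.astype(np.float32)
    pooled = (r[0::2, 0::2] + r[1::2, 0::2] + r[0::2, 1::2] + r[1::2, 1::2]) / 4.0
    return np.clip(np.rint(pooled), 0, 255).astype(np.uint8)


def build_pyramid(
    base: np.ndarray,
    n_levels: int = 6,
    microns_per_pixel_level0: float = DEFAULT_MPP,
) -> ImagePyramid:
    """Construct a pyramid from a level-0 raster by repeated 2x averaging."""
    if base.size == 0:
        raise ValueError("empty base raster")
    levels = [np.ascontiguousarray(base, dtype=np.uint8)]
    for _ in range(1, n_levels):
        levels.append(downsample2x(levels[-1]))
    return ImagePyramid(levels, microns_per_pixel_level0)


def read_region(
    pyramid: ImagePyramid, level: int, x: int, y: int, w: int, h: int
) -> np.ndarray:
    """Return the ``w x h`` region at ``(x, y)`` of the requested level.

    Coordinates are 0-based with a top-left origin; the interval is half-open,
    so ``x`` may range over ``[0, level_width - w]``.
    """
    raster = pyramid.level(level)
    lh, lw = raster.shape[:2]
    if w <= 0 or h <= 0:
        raise ValueError("region extent must be positive")
    if x < 0 or y < 0 or x + w > lw or y + h > lh:
        raise ValueError(
            f"region ({x},{y},{w},{h}) out of bounds for level {level} ({lw}x{lh})"
        )
    return raster[y : y + h, x : x + w]


def microns_per_pixel(pyramid: ImagePyramid, level: int) -> float:
    """Physical pixel pitch at ``level``: level-0 pitch times ``2**level``."""
    if level < 0:
        raise ValueError("negative level")
    pyramid.level(level)  # bounds check
    return pyramid.microns_per_pixel_level0 * 2**level


def write_pyramid(pyramid: ImagePyramid, path: str | Path) -> None:
    """Write one PNG per level plus a ``pyramid.yaml`` sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for l, raster in enumerate(pyramid.levels):
        Image.fromarray(raster).save(path / f"level_{l}.png")
    meta = {
        "base_width": int(pyramid.base_width),
        "base_height": int(pyramid.base_height),
        "n_levels": int(pyramid.n_levels),
        "microns_per_pixel_level0": float(pyramid.microns_per_pixel_level0),
    }
    (path / "pyramid.yaml").write_text(yaml.safe_dump(meta))


def read_pyramid(path: str | Path) -> ImagePyramid:
    path = Path(path)
    meta = yaml.safe_load((path / "pyramid.yaml").read_text())
    levels = []
    for l in range(meta["n_levels"]):
        levels.append(np.asarray(Image.open(path / f"level_{l}.png"), dtype=np.uint8))
    pyr = ImagePyramid(levels, meta["microns_per_pixel_level0"])
    if (pyr.base_width, pyr.base_height) != (meta["base_width"], meta["base_height"]):
        raise ValueError("sidecar dimensions disagree with level-0 raster")
    return pyr
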