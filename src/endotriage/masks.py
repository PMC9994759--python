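"""Region masks, slide annotations and their file formats.

A ``RegionMask`` is a level-5 raster labelling every cell as background,
blood/mucus, other-or-benign tissue or malignant tissue.  Annotations follow
the overall-class-plus-overrides convention: the whole slide carries one
tissue class and only regions that differ are outlined as polygons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.draw import polygon as draw_polygon

SLIDE_CLASSES = ("malignant", "other_or_benign", "insufficient")
#: annotation classes: "insufficient" is a slide category, not a tissue class
ANNOTATION_CLASSES = ("malignant", "other_or_benign")


class RegionClass(IntEnum):
    BACKGROUND = 0
    BLOOD_MUCUS = 1
    OTHER_BENIGN = 2
    MALIGNANT = 3


#: display palette: black background, pink blood/mucus, grey benign, red malignant
MASK_PALETTE = {
    RegionClass.BACKGROUND: (0, 0, 0),
    RegionClass.BLOOD_MUCUS: (255, 105, 180),
    RegionClass.OTHER_BENIGN: (128, 128, 128),
    RegionClass.MALIGNANT: (255, 0, 0),
}

_NO_OVERRIDE = 255


@dataclass
class PolygonOverride:
    """Closed polygon (level-0 pixel coordinates, x right / y down) whose
    interior tissue belongs to ``region_class`` instead of the overall class."""

    vertices: np.ndarray  # (N, 2) float, columns (x, y)
    region_class: str  # one of ANNOTATION_CLASSES

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be (N, 2)")
        if self.region_class not in ANNOTATION_CLASSES:
            raise ValueError(f"unknown annotation class {self.region_class!r}")


@dataclass
class SlideAnnotation:
    overall_class: str
    overrides: list[PolygonOverride] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.overall_class not in ANNOTATION_CLASSES:
            raise ValueError(f"unknown annotation class {self.overall_class!r}")


@dataclass
class SlideGroundTruth:
    slide_label: str  # one of SLIDE_CLASSES
    class_mask: np.ndarray  # level-5 uint8 raster of RegionClass values
    annotation: SlideAnnotation

    def __post_init__(self) -> None:
        if self.slide_label not in SLIDE_CLASSES:
            raise ValueError(f"unknown slide label {self.slide_label!r}")


def rasterize_overrides(
    annotation: SlideAnnotation, shape: tuple[int, int], scale: float = 32.0
) -> np.ndarray:
    """Per-cell override class at level 5 (``_NO_OVERRIDE`` where none applies).

    Polygon vertices are level-0 coordinates and are divided by ``scale``
    (32 = 2**5) to land on the level-5 grid.
    """
    out = np.full(shape, _NO_OVERRIDE, dtype=np.uint8)
    for ov in annotation.overrides:
        xs = ov.vertices[:, 0] / scale
        ys = ov.vertices[:, 1] / scale
        rr, cc = draw_polygon(ys, xs, shape=shape)
        cls = (
            RegionClass.MALIGNANT
            if ov.region_class == "malignant"
            else RegionClass.OTHER_BENIGN
        )
        out[rr, cc] = cls
    return out


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a RegionMask as an indexed PNG with the fixed display palette."""
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    palette = [0] * 768
    for cls, rgb in MASK_PALETTE.items():
        palette[3 * int(cls) : 3 * int(cls) + 3] = rgb
    img.putpalette(palette)
    img.save(Path(path))


def load_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(Path(path)), dtype=np.uint8)


def annotation_to_geojson(annotation: SlideAnnotation) -> dict:
    """GeoJSON FeatureCollection with a slide-level class property."""
    features = []
    for ov in annotation.overrides:
        ring = ov.vertices.tolist()
        if ring and ring[0] != ring[-1]:
            ring = ring + [ring[0]]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"classification": ov.region_class},
            }
        )
    return {
        "type": "FeatureCollection",
        "properties": {"overall_class": annotation.overall_class},
        "features": features,
    }


def annotation_from_geojson(doc: dict) -> SlideAnnotation:
    overrides = []
    for feat in doc.get("features", []):
        ring = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)
        if len(ring) > 1 and np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]
        overrides.append(
            PolygonOverride(ring, feat["properties"]["classification"])
        )
    return SlideAnnotation(doc["properties"]["overall_class"], overrides)


def save_annotation(annotation: SlideAnnotation, path: str | Path) -> None:
    Path(path).write_text(json.dumps(annotation_to_geojson(annotation), indent=1))


def load_annotation(path: str | Path) -> SlideAnnotation:
    return annotation_from_geojson(json.loads(Path(path).read_text()))
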