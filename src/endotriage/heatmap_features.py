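"""Heatmap segmentation and slide-level feature vectors.

Two fixed-length summaries of a slide's probability heatmaps feed the slide
classifiers:

* ``wang31`` (31 features) — the Camelyon-style recipe: tissue area; for
  each threshold in {0.5, 0.6, 0.7, 0.8, 0.9} the malignant area as a
  percentage of tissue area and the total probability inside the
  thresholded mask; then ten shape/intensity properties for each of the two
  largest malignant segments at threshold 0.5.
* ``tuned42`` (42 features) — the variant tuned for endometrial biopsies:
  tissue area; malignant and benign area percentages at thresholds
  {0.6, 0.9}; nine properties for each of the three largest malignant
  segments and five properties for each of the two largest benign segments,
  all segmented at threshold 0.5.

Segments are maximal 8-connected components (diagonal neighbours count) of
the strictly-thresholded heatmap.  Missing segments contribute zero blocks
so the vectors always have fixed length.  Region properties follow the
standard ``regionprops`` conventions: raw central moments define the
equivalent ellipse (axis lengths ``4*sqrt(eigenvalue)``), solidity uses the
pixelated convex hull, extent divides area by bounding-box area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure

WANG_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)
TUNED_THRESHOLDS = (0.6, 0.9)
SEGMENT_THRESHOLD = 0.5

#: regionprops fields per segment, in Algorithm-1 order
WANG_SEGMENT_PROPS = (
    "area", "eccentricity", "extent", "bbox_area", "major_axis_length",
    "max_prob", "min_prob", "mean_prob", "solidity", "aspect_ratio",
)
#: per-malignant-segment fields of the tuned variant
TUNED_MAL_PROPS = (
    "area", "eccentricity", "extent", "bbox_area", "major_axis_length",
    "max_prob", "mean_prob", "solidity", "minor_axis_length",
)
#: per-benign-segment fields of the tuned variant
TUNED_BEN_PROPS = (
    "area", "bbox_area", "major_axis_length", "mean_prob", "minor_axis_length",
)


def binarize(channel: np.ndarray, threshold: float) -> np.ndarray:
    """Cells strictly greater than ``threshold``."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    return np.asarray(channel) > threshold


@dataclass
class Segment:
    """Maximal 8-connected component of a thresholded heatmap channel."""

    cells: np.ndarray  # (n, 2) int rows (row, col), lexicographically sorted
    threshold: float = SEGMENT_THRESHOLD

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=int)
        if self.cells.size == 0:
            raise ValueError("segment must be non-empty")

    @property
    def area(self) -> int:
        return len(self.cells)


def connected_segments(mask: np.ndarray) -> list[Segment]:
    """8-connected components, sorted by area descending.

    Area ties are broken by the top-left-most cell (smallest row, then
    column).
    """
    labelled = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    segments = []
    for region in measure.regionprops(labelled):
        cells = region.coords[np.lexsort((region.coords[:, 1], region.coords[:, 0]))]
        segments.append(Segment(cells))
    segments.sort(key=lambda s: (-s.area, tuple(s.cells[0])))
    return segments


@dataclass
class RegionProps:
    area: float
    bbox_area: float
    extent: float
    solidity: float
    eccentricity: float
    major_axis_length: float
    minor_axis_length: float
    aspect_ratio: float  # bounding-box width / height
    max_prob: float
    min_prob: float
    mean_prob: float

    def __getitem__(self, name: str) -> float:
        return getattr(self, name)


def region_props(segment: Segment, channel: np.ndarray) -> RegionProps:
    """Shape and intensity properties of one segment.

    Shape properties are computed with ``skimage.measure.regionprops`` on
    the segment alone; intensity statistics come from the heatmap channel
    over the segment's cells.
    """
    rows, cols = segment.cells[:, 0], segment.cells[:, 1]
    rmin, cmin = rows.min(), cols.min()
    local = np.zeros((rows.max() - rmin + 1, cols.max() - cmin + 1), dtype=int)
    local[rows - rmin, cols - cmin] = 1
    region = measure.regionprops(local)[0]
    values = np.asarray(channel)[rows, cols]
    bbox_h, bbox_w = local.shape
    return RegionProps(
        area=float(region.area),
        bbox_area=float(bbox_h * bbox_w),
        extent=float(region.extent),
        solidity=float(region.solidity),
        eccentricity=float(region.eccentricity),
        major_axis_length=float(region.axis_major_length),
        minor_axis_length=float(region.axis_minor_length),
        aspect_ratio=float(bbox_w) / float(bbox_h),
        max_prob=float(values.max()),
        min_prob=float(values.min()),
        mean_prob=float(values.mean()),
    )


@dataclass
class SlideFeatureVector:
    values: np.ndarray
    names: tuple[str, ...]
    variant: str  # "wang31" or "tuned42"

    def __post_init__(self) -> None:
        expected = {"wang31": 31, "tuned42": 42}[self.variant]
        if len(self.values) != expected or len(self.names) != expected:
            raise ValueError(
                f"{self.variant} vector must have {expected} entries"
            )


def _area_pct(n_cells: int, tissue_area: float, cells_per_patch: float) -> float:
    if tissue_area <= 0:
        return 0.0
    return 100.0 * n_cells * cells_per_patch / tissue_area


def _check_tissue_area(tissue_area: float, channel: np.ndarray) -> None:
    if tissue_area < 0:
        raise ValueError("tissue_area must be non-negative")
    if tissue_area == 0 and np.any(np.asarray(channel) > 0):
        warnings.warn(
            "non-empty heatmap with zero tissue area; area percentages set to 0",
            stacklevel=3,
        )


def wang_feature_names() -> tuple[str, ...]:
    names = ["wang31_tissue_area"]
    for t in WANG_THRESHOLDS:
        tag = f"t{int(t * 100):02d}"
        names += [f"wang31_{tag}_mal_area_pct", f"wang31_{tag}_total_prob"]
    for k in (1, 2):
        names += [f"wang31_seg{k}_{p}" for p in WANG_SEGMENT_PROPS]
    return tuple(names)


def tuned_feature_names() -> tuple[str, ...]:
    names = ["tuned42_tissue_area"]
    for t in TUNED_THRESHOLDS:
        tag = f"t{int(t * 100):02d}"
        names += [f"tuned42_{tag}_mal_area_pct", f"tuned42_{tag}_ben_area_pct"]
    for k in (1, 2, 3):
        names += [f"tuned42_mal_seg{k}_{p}" for p in TUNED_MAL_PROPS]
    for k in (1, 2):
        names += [f"tuned42_ben_seg{k}_{p}" for p in TUNED_BEN_PROPS]
    return tuple(names)


def _segment_block(
    channel: np.ndarray, n_segments: int, props: tuple[str, ...]
) -> list[float]:
    mask = binarize(channel, SEGMENT_THRESHOLD)
    segments = connected_segments(mask)[:n_segments]
    block: list[float] = []
    for seg in segments:
        rp = region_props(seg, channel)
        block.extend(rp[p] for p in props)
    block.extend([0.0] * (len(props) * (n_segments - len(segments))))
    return block


def features_wang(
    mal_channel: np.ndarray,
    tissue_area: float,
    cells_per_patch: float = 1.0,
) -> SlideFeatureVector:
    """31-feature Camelyon-style heatmap summary (Algorithm-1 order).

    ``tissue_area`` is the level-5 tissue cell count; ``cells_per_patch``
    converts heatmap-cell areas to the same units (``(patch_size/32)**2``;
    1 when tissue area is already counted at heatmap resolution).
    """
    _check_tissue_area(tissue_area, mal_channel)
    values: list[float] = [float(tissue_area)]
    for t in WANG_THRESHOLDS:
        mask = binarize(mal_channel, t)
        values.append(_area_pct(int(mask.sum()), tissue_area, cells_per_patch))
        values.append(float(np.asarray(mal_channel)[mask].sum()))
    values += _segment_block(mal_channel, 2, WANG_SEGMENT_PROPS)
    return SlideFeatureVector(np.asarray(values), wang_feature_names(), "wang31")


def features_tuned(
    mal_channel: np.ndarray,
    benign_channel: np.ndarray,
    tissue_area: float,
    cells_per_patch: float = 1.0,
) -> SlideFeatureVector:
    """42-feature endometrial-tuned heatmap summary (Algorithm-2 order)."""
    mal_channel = np.asarray(mal_channel)
    benign_channel = np.asarray(benign_channel)
    if mal_channel.shape != benign_channel.shape:
        raise ValueError("heatmap channels must be aligned")
    _check_tissue_area(tissue_area, mal_channel)
    values: list[float] = [float(tissue_area)]
    for t in TUNED_THRESHOLDS:
        mal_mask = binarize(mal_channel, t)
        ben_mask = binarize(benign_channel, t)
        values.append(_area_pct(int(mal_mask.sum()), tissue_area, cells_per_patch))
        values.append(_area_pct(int(ben_mask.sum()), tissue_area, cells_per_patch))
    values += _segment_block(mal_channel, 3, TUNED_MAL_PROPS)
    values += _segment_block(benign_channel, 2, TUNED_BEN_PROPS)
    return SlideFeatureVector(np.asarray(values), tuned_feature_names(), "tuned42")
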