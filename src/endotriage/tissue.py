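"""Tissue-area detection at level 5.

Two stages: (1) background separation by grey-value thresholding followed by
morphological closing and hole filling; (2) a per-pixel random-forest
classifier that separates blood or mucus from diagnostic tissue using a
12-feature colour/texture stack.  The outputs are combined with the slide
annotation into a four-class region mask.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, disk
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .masks import RegionClass, SlideAnnotation, _NO_OVERRIDE, rasterize_overrides

#: fixed order of the 12 feature planes, per RGB channel
FEATURE_ORDER = tuple(
    f"{ch}_{feat}"
    for ch in ("r", "g", "b")
    for feat in ("raw", "gaussian", "texture_raw", "texture_gaussian")
)

GAUSSIAN_SIGMA = 2.0  # truncated at 4 sigma (scipy default)
TEXTURE_WINDOW = 3  # local standard deviation window
CLOSING_RADIUS = 2  # structuring-element radius at level 5


def _grey(thumbnail: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma in [0, 1]."""
    r, g, b = (thumbnail[..., i].astype(np.float64) for i in range(3))
    return (0.299 * r + 0.587 * g + 0.114 * b) / 255.0


def detect_background(
    thumbnail: np.ndarray, grey_threshold: float = 0.85
) -> np.ndarray:
    """Separate tissue candidates from background on a level-5 thumbnail.

    Pure-black pixels (stitching gaps between scanned areas) are first
    converted to pure white so they fall with the background.  Pixels whose
    grey value is strictly greater than ``grey_threshold`` are background;
    the remaining tissue mask is then closed (disk radius 2) and its holes
    filled.  Returns a boolean raster, True = tissue candidate.
    """
    if thumbnail.size == 0:
        raise ValueError("empty raster")
    if thumbnail.ndim != 3 or thumbnail.shape[2] != 3:
        raise ValueError("thumbnail must be an RGB raster")
    work = thumbnail.copy()
    black = (work == 0).all(axis=-1)
    work[black] = 255
    tissue = _grey(work) <= grey_threshold
    tissue = closing(tissue, disk(CLOSING_RADIUS))
    tissue = ndimage.binary_fill_holes(tissue)
    return tissue


def extract_pixel_features(image: np.ndarray) -> np.ndarray:
    """12-plane feature stack, shape ``(H, W, 12)``.

    Per RGB channel, in fixed order: raw value, Gaussian-filtered value
    (sigma 2), local-standard-deviation texture of the raw channel, and the
    same texture filter applied to the Gaussian-filtered channel.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("input must be an RGB raster")
    planes = []
    for c in range(3):
        raw = image[..., c].astype(np.float64)
        gauss = ndimage.gaussian_filter(raw, sigma=GAUSSIAN_SIGMA)
        planes.extend([raw, gauss, _local_std(raw), _local_std(gauss)])
    return np.stack(planes, axis=-1)


def _local_std(plane: np.ndarray, size: int = TEXTURE_WINDOW) -> np.ndarray:
    mean = ndimage.uniform_filter(plane, size=size)
    mean_sq = ndimage.uniform_filter(plane * plane, size=size)
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return np.sqrt(var)


@dataclass
class BloodMucusModel:
    """Random forest over 12-feature pixel rows -> {blood_mucus, tissue}."""

    forest: RandomForestClassifier
    seed: int
    holdout_accuracy: float
    feature_order: tuple[str, ...] = field(default=FEATURE_ORDER)

    def predict(self, rows: np.ndarray) -> np.ndarray:
        """True where a 12-vector is classified as blood or mucus."""
        return self.forest.predict(np.atleast_2d(rows)).astype(bool)

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @staticmethod
    def load(path: str | Path) -> "BloodMucusModel":
        return pickle.loads(Path(path).read_bytes())


def train_blood_mucus_model(
    stacks: list[np.ndarray],
    labels: list[np.ndarray],
    seed: int = 0,
    n_estimators: int = 100,
    holdout_fraction: float = 0.25,
) -> BloodMucusModel:
    """Train the pixel-level blood/mucus classifier.

    ``stacks`` are feature stacks from :func:`extract_pixel_features`,
    ``labels`` aligned boolean rasters (True = blood_mucus).  A stratified
    hold-out split reports pixel accuracy; training is deterministic for a
    fixed seed.
    """
    X = np.concatenate([s.reshape(-1, s.shape[-1]) for s in stacks])
    y = np.concatenate([l.reshape(-1) for l in labels]).astype(bool)
    if y.all() or not y.any():
        raise ValueError("training pixels must include both classes")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    forest.fit(X_tr, y_tr)
    acc = float((forest.predict(X_te) == y_te).mean())
    return BloodMucusModel(forest, seed, acc)


def detect_blood_mucus(image: np.ndarray, model: BloodMucusModel) -> np.ndarray:
    """Per-pixel blood/mucus mask (True = blood or mucus) for an RGB raster."""
    stack = extract_pixel_features(image)
    flat = model.predict(stack.reshape(-1, stack.shape[-1]))
    return flat.reshape(image.shape[:2])


def combine_masks(
    background: np.ndarray,
    blood: np.ndarray,
    annotation: SlideAnnotation,
) -> np.ndarray:
    """Combine detection masks and the annotation into a RegionMask.

    Per-cell precedence: background > blood/mucus > annotation override
    class > overall slide class.  ``background`` is the tissue-candidate
    mask from :func:`detect_background` (True = tissue candidate).
    """
    if background.shape != blood.shape:
        raise ValueError("mask dimension mismatch")
    out = np.full(background.shape, int(RegionClass.BACKGROUND), dtype=np.uint8)
    tissue = background & ~blood
    out[background & blood] = int(RegionClass.BLOOD_MUCUS)
    overall = (
        RegionClass.MALIGNANT
        if annotation.overall_class == "malignant"
        else RegionClass.OTHER_BENIGN
    )
    overrides = rasterize_overrides(annotation, background.shape)
    cls = np.where(overrides == _NO_OVERRIDE, int(overall), overrides)
    out[tissue] = cls[tissue]
    return out


def tissue_area(mask: np.ndarray) -> int:
    """Number of level-5 cells holding diagnostic tissue (benign or malignant)."""
    return int(
        ((mask == RegionClass.OTHER_BENIGN) | (mask == RegionClass.MALIGNANT)).sum()
    )


def blood_mucus_warning(mask: np.ndarray, threshold: float = 0.5) -> None:
    frac = (mask == RegionClass.BLOOD_MUCUS).mean()
    if frac > threshold:
        warnings.warn(
            f"more than {threshold:.0%} of the slide is blood or mucus", stacklevel=2
        )
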