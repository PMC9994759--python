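"""Patch-probability classifier and heatmap assembly.

The classifier contract maps an RGB patch to a probability pair
``(p_malignant, p_other_benign)`` summing to one.  The training schedule
follows the original recipe: SGD with cross-entropy, initial learning rate
0.01 halved every two epochs, and early stopping when validation accuracy
has not improved for three consecutive epochs; the returned model is the
checkpoint with the best validation accuracy.

The full-scale architecture used on clinical data (GoogLeNet on 600k
patches) is replaced here by a pluggable contract with a small desk-scale
architecture: patches are block-averaged to a low-resolution thumbnail and
classified by a compact MLP.  Any model implementing ``predict_proba`` over
preprocessed patches satisfies the contract.

Per-patch predictions are assembled into two aligned heatmaps (malignant /
other-or-benign) with one cell per patch-grid position; cells with no
processed patch are zero in both channels.
"""

from __future__ import annotations

import logging
import math
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .nnet import TinyNet
from .patching import PatchRecord, extract_patch_image
from .pyramid import ImagePyramid

logger = logging.getLogger(__name__)

PATCH_CLASSES = ("malignant", "other_or_benign")


@dataclass
class TrainingSchedule:
    """lr(epoch e) = initial_lr / 2**floor(e / halve_every), epochs 0-based."""

    initial_lr: float = 0.01
    halve_every: int = 2
    early_stop_patience: int = 3
    loss: str = "cross_entropy"

    def learning_rate(self, epoch: int) -> float:
        if epoch < 0:
            raise ValueError("negative epoch")
        return self.initial_lr / 2 ** (epoch // self.halve_every)


def downsample_patch(image: np.ndarray, input_px: int = 16) -> np.ndarray:
    """Block-average an RGB patch to ``input_px`` square, flattened to [0,1]."""
    h, w = image.shape[:2]
    if h % input_px == 0 and w % input_px == 0:
        fh, fw = h // input_px, w // input_px
        small = (
            image.astype(np.float64)
            .reshape(input_px, fh, input_px, fw, 3)
            .mean(axis=(1, 3))
        )
    else:
        small = np.asarray(
            Image.fromarray(image).resize((input_px, input_px), Image.BOX),
            dtype=np.float64,
        )
    return (small / 255.0).reshape(-1)


@dataclass
class PatchClassifier:
    """Trained patch model: RGB patch -> (p_malignant, p_other_benign)."""

    net: TinyNet
    arch: str = "tiny-mlp"
    input_px: int = 16
    seed: int = 0
    classes: tuple[str, str] = PATCH_CLASSES
    schedule: TrainingSchedule = field(default_factory=TrainingSchedule)
    training_log: pd.DataFrame | None = None
    #: per-feature standardisation fitted on the training set
    norm_mean: np.ndarray | None = None
    norm_std: np.ndarray | None = None

    def preprocess(self, image: np.ndarray) -> np.ndarray:
        return downsample_patch(image, self.input_px)

    def _normalise(self, features: np.ndarray) -> np.ndarray:
        if self.norm_mean is None:
            return features
        return (features - self.norm_mean) / self.norm_std

    def predict_proba_features(self, features: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self._normalise(np.atleast_2d(features)))

    def predict_proba_images(self, images) -> np.ndarray:
        feats = np.stack([self.preprocess(im) for im in images])
        return self.predict_proba_features(feats)

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @staticmethod
    def load(path: str | Path) -> "PatchClassifier":
        return pickle.loads(Path(path).read_bytes())


def _as_features(X, classifier: PatchClassifier) -> np.ndarray:
    X = list(X) if not isinstance(X, np.ndarray) else X
    first = X[0]
    if np.ndim(first) == 1:  # already preprocessed feature rows
        return np.stack([np.asarray(row, dtype=np.float64) for row in X])
    return np.stack([classifier.preprocess(np.asarray(im)) for im in X])


def _encode_labels(labels) -> np.ndarray:
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab not in PATCH_CLASSES:
            raise ValueError(f"unknown patch label {lab!r}")
        out[i] = PATCH_CLASSES.index(lab)
    return out


def train_patch_classifier(
    train_X,
    train_labels,
    valid_X,
    valid_labels,
    arch: str = "tiny-mlp",
    schedule: TrainingSchedule | None = None,
    seed: int = 0,
    max_epochs: int = 30,
    batch_size: int = 32,
    n_hidden: int = 32,
    input_px: int = 16,
) -> PatchClassifier:
    """Train the desk-scale patch classifier.

    ``train_X`` / ``valid_X`` are RGB patches or already-preprocessed
    feature rows.  Training stops when validation accuracy has not
    increased for ``schedule.early_stop_patience`` consecutive epochs and
    the best-validation checkpoint is returned.
    """
    schedule = schedule or TrainingSchedule()
    if len(train_X) == 0 or len(valid_X) == 0:
        raise ValueError("empty split")
    y_tr = _encode_labels(list(train_labels))
    y_va = _encode_labels(list(valid_labels))
    if len(set(y_tr.tolist())) < 2 or len(set(y_va.tolist())) < 2:
        raise ValueError("both classes must be present in train and valid splits")

    clf = PatchClassifier(
        net=TinyNet(3 * input_px * input_px, n_hidden, 2, seed=seed),
        arch=arch,
        input_px=input_px,
        seed=seed,
        schedule=schedule,
    )
    X_tr = _as_features(train_X, clf)
    X_va = _as_features(valid_X, clf)
    clf.norm_mean = X_tr.mean(axis=0)
    clf.norm_std = np.maximum(X_tr.std(axis=0), 1e-6)
    X_tr = clf._normalise(X_tr)
    X_va = clf._normalise(X_va)
    rng = np.random.default_rng(seed + 1)

    best_acc, best_epoch, best_weights = -1.0, -1, clf.net.get_weights()
    log = []
    for epoch in range(max_epochs):
        lr = schedule.learning_rate(epoch)
        train_loss = clf.net.train_epoch(X_tr, y_tr, lr, rng, batch_size)
        train_acc = clf.net.accuracy(X_tr, y_tr)
        valid_acc = clf.net.accuracy(X_va, y_va)
        log.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": train_loss,
                "train_acc": train_acc,
                "valid_acc": valid_acc,
            }
        )
        if valid_acc > best_acc:
            best_acc, best_epoch = valid_acc, epoch
            best_weights = clf.net.get_weights()
        elif epoch - best_epoch >= schedule.early_stop_patience:
            logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
            break
    clf.net.set_weights(best_weights)
    clf.training_log = pd.DataFrame(log)
    return clf


def predict_patches(
    model: PatchClassifier, records: list[PatchRecord], pyramid: ImagePyramid
) -> np.ndarray:
    """One ``(p_malignant, p_other_benign)`` pair per record."""
    if not records:
        return np.zeros((0, 2))
    feats = np.stack(
        [model.preprocess(extract_patch_image(pyramid, rec)) for rec in records]
    )
    return model.predict_proba_features(feats)


@dataclass
class Heatmap:
    """Aligned malignant / other-benign probability grids at patch pitch."""

    malignant: np.ndarray
    other_benign: np.ndarray

    def __post_init__(self) -> None:
        if self.malignant.shape != self.other_benign.shape:
            raise ValueError("heatmap channels must be aligned")

    @property
    def shape(self) -> tuple[int, int]:
        return self.malignant.shape

    def to_png(self, path_prefix: str | Path) -> None:
        """8-bit greyscale export for display (black = 0, white = 1)."""
        for name, grid in (("malignant", self.malignant),
                           ("other_benign", self.other_benign)):
            img = np.clip(np.rint(grid * 255), 0, 255).astype(np.uint8)
            Image.fromarray(img, mode="L").save(f"{path_prefix}_{name}.png")


def heatmap_shape(mask_shape: tuple[int, int], patch_size: int) -> tuple[int, int]:
    """Grid dims: one cell per patch, ceil(level-5 dims / (size/32))."""
    side = patch_size // 32
    return (math.ceil(mask_shape[0] / side), math.ceil(mask_shape[1] / side))


def assemble_heatmaps(
    predictions: np.ndarray,
    records: list[PatchRecord],
    grid_shape: tuple[int, int],
) -> Heatmap:
    """Place each record's probability pair at its grid cell.

    Requires stride = size so that each record maps to a unique cell;
    unprocessed cells are zero in both channels.
    """
    mal = np.zeros(grid_shape)
    ben = np.zeros(grid_shape)
    seen = np.zeros(grid_shape, dtype=bool)
    predictions = np.asarray(predictions).reshape(len(records), 2)
    for (p_mal, p_ben), rec in zip(predictions, records):
        r, c = rec.y // rec.size, rec.x // rec.size
        if r >= grid_shape[0] or c >= grid_shape[1]:
            raise ValueError("record outside heatmap grid")
        if seen[r, c]:
            raise ValueError(f"two records map to heatmap cell ({r}, {c})")
        seen[r, c] = True
        mal[r, c] = p_mal
        ben[r, c] = p_ben
    return Heatmap(mal, ben)
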