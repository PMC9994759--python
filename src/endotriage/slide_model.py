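"""Slide-level classifiers over heatmap features and heatmap stacks.

Three classifier families predict the final slide category (malignant /
other-or-benign / insufficient):

* a random forest (100 estimators, library defaults otherwise) on the
  31-dim Camelyon-style features;
* gradient-boosted trees (XGBoost, 200 estimators, depth 2) on the 42-dim
  tuned features, with per-class training weights.  Down-weighting the two
  non-malignant classes (0.05 for other-or-benign, 0.1 for insufficient)
  trades a little overall accuracy for malignant sensitivity;
* a small network on zero-padded 5-channel heatmap stacks (malignant
  channel, benign channel, RGB thumbnail), the desk-scale stand-in for the
  heatmap CNN.

Predicted probabilities sum to one, and slides can be ranked by malignant
probability to build a triage queue.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.ensemble import RandomForestClassifier
from xgboost import XGBClassifier

from .nnet import TinyNet

CLASS_ORDER = ("malignant", "other_or_benign", "insufficient")


@dataclass
class ClassWeights:
    """Per-class training weight; all weights must be positive."""

    malignant: float = 1.0
    other_or_benign: float = 1.0
    insufficient: float = 1.0

    def __post_init__(self) -> None:
        if min(self.malignant, self.other_or_benign, self.insufficient) <= 0:
            raise ValueError("class weights must be positive")

    @classmethod
    def sensitivity_tuned(cls) -> "ClassWeights":
        """The grid-search optimum for malignant sensitivity."""
        return cls(malignant=1.0, other_or_benign=0.05, insufficient=0.1)

    def of(self, label: str) -> float:
        return getattr(self, label)


def _encode(labels, classes: tuple[str, ...]) -> np.ndarray:
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab not in classes:
            raise ValueError(f"unknown slide label {lab!r}")
        out[i] = classes.index(lab)
    return out


def _present_classes(labels) -> tuple[str, ...]:
    present = set(labels)
    unknown = present - set(CLASS_ORDER)
    if unknown:
        raise ValueError(f"unknown slide labels {sorted(unknown)}")
    return tuple(c for c in CLASS_ORDER if c in present)


@dataclass
class SlideClassifier:
    """Feature-vector slide classifier (random forest or boosted trees)."""

    model: object
    classes: tuple[str, ...]
    kind: str
    weights: ClassWeights | None = None

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        return np.asarray(self.model.predict_proba(features), dtype=np.float64)

    def predict(self, features: np.ndarray) -> list[str]:
        proba = self.predict_proba(features)
        return [self.classes[i] for i in proba.argmax(axis=1)]

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @staticmethod
    def load(path: str | Path) -> "SlideClassifier":
        return pickle.loads(Path(path).read_bytes())


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=np.float64)
    return np.atleast_2d(np.asarray(features, dtype=np.float64))


def train_slide_rf(
    features, labels, n_estimators: int = 100, seed: int = 0
) -> SlideClassifier:
    """Seeded random forest on wang31 features; other settings at defaults."""
    X = _as_matrix(features)
    classes = _present_classes(labels)
    if len(classes) < 2:
        raise ValueError("at least two slide classes required")
    y = _encode(list(labels), classes)
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    return SlideClassifier(rf, classes, "random_forest")


def train_slide_gbt(
    features,
    labels,
    n_estimators: int = 200,
    max_depth: int = 2,
    weights: ClassWeights | None = None,
    seed: int = 0,
) -> SlideClassifier:
    """Gradient-boosted trees on tuned42 features with class weights.

    Each sample's training weight is the weight of its class; uniform
    weights reproduce the unweighted fit exactly.
    """
    X = _as_matrix(features)
    classes = _present_classes(labels)
    if len(classes) < 2:
        raise ValueError("at least two slide classes required")
    y = _encode(list(labels), classes)
    weights = weights or ClassWeights()
    sample_weight = np.array([weights.of(lab) for lab in labels], dtype=np.float64)
    booster = XGBClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="mlogloss",
    )
    booster.fit(X, y, sample_weight=sample_weight)
    return SlideClassifier(booster, classes, "gradient_boosted", weights)


def _sensitivity(preds: list[str], truth: list[str], cls: str) -> float:
    idx = [i for i, t in enumerate(truth) if t == cls]
    if not idx:
        return float("nan")
    return sum(preds[i] == cls for i in idx) / len(idx)


def weight_grid_search(
    train_features,
    train_labels,
    valid_features,
    valid_labels,
    weight_grid: list[ClassWeights],
    accuracy_floor: float = 0.0,
    seed: int = 0,
    n_estimators: int = 200,
    max_depth: int = 2,
) -> tuple[ClassWeights, pd.DataFrame]:
    """Pick the class weights maximising malignant sensitivity.

    Candidates must keep validation accuracy at or above
    ``accuracy_floor``; ties are broken by accuracy and then grid order.
    The full grid results are returned for logging.
    """
    if not weight_grid:
        raise ValueError("empty weight grid")
    if "malignant" not in set(valid_labels):
        raise ValueError("validation labels must include the malignant class")
    rows = []
    best = None
    for i, weights in enumerate(weight_grid):
        clf = train_slide_gbt(
            train_features, train_labels, n_estimators, max_depth, weights, seed
        )
        preds = clf.predict(_as_matrix(valid_features))
        truth = list(valid_labels)
        acc = float(np.mean([p == t for p, t in zip(preds, truth)]))
        sens = _sensitivity(preds, truth, "malignant")
        rows.append(
            {
                "malignant": weights.malignant,
                "other_or_benign": weights.other_or_benign,
                "insufficient": weights.insufficient,
                "accuracy": acc,
                "malignant_sensitivity": sens,
                "meets_floor": acc >= accuracy_floor,
            }
        )
        key = (sens, acc, -i)
        if acc >= accuracy_floor and (best is None or key > best[0]):
            best = (key, weights)
    results = pd.DataFrame(rows)
    if best is None:
        raise ValueError("no grid point met the accuracy floor")
    return best[1], results


@dataclass
class HeatmapStack:
    """Zero-padded 5-channel input: heatmaps + thumbnail, content centred."""

    channels: np.ndarray  # (5, H, W) float in [0, 1]
    offset: tuple[int, int]  # (row, col) of the original content
    content_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.channels.shape[0] != 5:
            raise ValueError("stack must have 5 channels")


def pad_and_stack(
    mal: np.ndarray,
    benign: np.ndarray,
    thumbnail: np.ndarray,
    target: tuple[int, int],
) -> HeatmapStack:
    """Centre the heatmaps and thumbnail in a zero-padded 5-channel stack.

    The RGB thumbnail is resampled to the heatmap dimensions by area
    averaging, all channels are scaled to [0, 1], and content is placed at
    ``floor((target - input) / 2)`` per axis.
    """
    mal = np.asarray(mal, dtype=np.float64)
    benign = np.asarray(benign, dtype=np.float64)
    if mal.shape != benign.shape:
        raise ValueError("heatmap channels must be aligned")
    h, w = mal.shape
    th, tw = target
    if th < h or tw < w:
        raise ValueError("target dims smaller than heatmap dims")
    thumb = np.asarray(
        Image.fromarray(np.asarray(thumbnail, dtype=np.uint8)).resize(
            (w, h), Image.BOX
        ),
        dtype=np.float64,
    ) / 255.0
    off = ((th - h) // 2, (tw - w) // 2)
    stack = np.zeros((5, th, tw))
    stack[0, off[0] : off[0] + h, off[1] : off[1] + w] = mal
    stack[1, off[0] : off[0] + h, off[1] : off[1] + w] = benign
    for c in range(3):
        stack[2 + c, off[0] : off[0] + h, off[1] : off[1] + w] = thumb[..., c]
    return HeatmapStack(stack, off, (h, w))


def _shift_stack(stack: HeatmapStack, dv: int, dh: int) -> np.ndarray:
    """Translate content inside the canvas; shifts are pre-clamped."""
    return np.roll(np.roll(stack.channels, dv, axis=1), dh, axis=2)


@dataclass
class SlideCNN:
    """Desk-scale network over flattened 5-channel heatmap stacks."""

    net: TinyNet
    classes: tuple[str, ...]
    input_shape: tuple[int, int]  # canvas (H, W) fixed at training time
    training_log: pd.DataFrame | None = None
    #: per-feature standardisation fitted on the (unjittered) training set
    norm_mean: np.ndarray | None = None
    norm_std: np.ndarray | None = None

    def _features(self, stacks: list[HeatmapStack]) -> np.ndarray:
        rows = []
        th, tw = self.input_shape
        for s in stacks:
            channels = s.channels
            h, w = channels.shape[1:]
            if h > th or w > tw:
                # slide larger than any training slide: centre-crop
                warnings.warn(
                    f"stack canvas ({h}, {w}) exceeds training canvas "
                    f"({th}, {tw}); centre-cropping", stacklevel=3,
                )
                oy = max((h - th) // 2, 0)
                ox = max((w - tw) // 2, 0)
                channels = channels[:, oy : oy + min(h, th),
                                    ox : ox + min(w, tw)]
                h, w = channels.shape[1:]
            if (h, w) != (th, tw):
                raise ValueError(
                    f"stack canvas ({h}, {w}) does not match training "
                    f"canvas ({th}, {tw})"
                )
            rows.append(channels.reshape(-1))
        X = np.stack(rows)
        if self.norm_mean is not None:
            X = (X - self.norm_mean) / self.norm_std
        return X

    def predict_proba(self, stacks: list[HeatmapStack]) -> np.ndarray:
        return self.net.predict_proba(self._features(stacks))

    def predict(self, stacks: list[HeatmapStack]) -> list[str]:
        proba = self.predict_proba(stacks)
        return [self.classes[i] for i in proba.argmax(axis=1)]


def slide_cnn_learning_rate(
    epoch: int, lr: float = 0.0005, halve_after: int = 5
) -> float:
    """Initial rate for the first ``halve_after`` epochs, halved once after."""
    if epoch < 0:
        raise ValueError("negative epoch")
    return lr if epoch < halve_after else lr / 2.0


def train_slide_cnn(
    stacks: list[HeatmapStack],
    labels,
    valid_stacks: list[HeatmapStack],
    valid_labels,
    epochs: int = 10,
    lr: float = 0.0005,
    halve_after: int = 5,
    jitter: tuple[int, int] = (20, 40),
    momentum: float = 0.9,
    seed: int = 0,
    n_hidden: int = 64,
    batch_size: int = 8,
) -> SlideCNN:
    """Train the heatmap-stack classifier.

    Cross-entropy with SGD; the learning rate is halved once after
    ``halve_after`` epochs.  Each training example is translated by a
    random jitter of up to ``jitter[0]`` cells vertically and ``jitter[1]``
    horizontally (clamped to the available zero padding so the content
    stays on the canvas; a zero shift is allowed).  The checkpoint from the
    epoch with the best validation accuracy is returned.
    """
    classes = _present_classes(labels)
    if len(classes) < 2:
        raise ValueError("at least two slide classes required")
    missing = set(valid_labels) - set(classes)
    if missing:
        raise ValueError(f"validation classes {sorted(missing)} absent from training")
    y_tr = _encode(list(labels), classes)
    y_va = _encode(list(valid_labels), classes)
    canvas = stacks[0].channels.shape[1:]
    net = TinyNet(5 * canvas[0] * canvas[1], n_hidden, len(classes), seed=seed)
    model = SlideCNN(net, classes, canvas)
    # global (scalar) standardisation: per-feature scaling would break the
    # spatial uniformity that makes jittered content learnable
    X_raw = np.stack([s.channels.reshape(-1) for s in stacks])
    model.norm_mean = np.full(X_raw.shape[1], X_raw.mean())
    model.norm_std = np.full(X_raw.shape[1], max(float(X_raw.std()), 1e-6))
    X_va = model._features(valid_stacks)
    rng = np.random.default_rng(seed + 1)

    best_acc, best_weights, log = -1.0, net.get_weights(), []
    for epoch in range(epochs):
        rate = slide_cnn_learning_rate(epoch, lr, halve_after)
        rows = []
        for s in stacks:
            h, w = s.content_shape
            th, tw = canvas
            up, down = s.offset[0], th - h - s.offset[0]
            left, right = s.offset[1], tw - w - s.offset[1]
            dv = int(rng.integers(-min(jitter[0], up), min(jitter[0], down) + 1))
            dh = int(rng.integers(-min(jitter[1], left), min(jitter[1], right) + 1))
            rows.append(_shift_stack(s, dv, dh).reshape(-1))
        X_tr = (np.stack(rows) - model.norm_mean) / model.norm_std
        loss = net.train_epoch(X_tr, y_tr, rate, rng, batch_size, momentum)
        valid_acc = net.accuracy(X_va, y_va)
        log.append({"epoch": epoch, "lr": rate, "train_loss": loss,
                    "valid_acc": valid_acc})
        if valid_acc > best_acc:
            best_acc = valid_acc
            best_weights = net.get_weights()
    net.set_weights(best_weights)
    model.training_log = pd.DataFrame(log)
    return model


@dataclass
class SlidePrediction:
    """3-class probabilities; the predicted class is the argmax."""

    probabilities: dict[str, float]
    predicted_class: str

    @property
    def malignant_probability(self) -> float:
        return self.probabilities.get("malignant", 0.0)


def predict_slide(classifier, x) -> SlidePrediction:
    """Predict one slide from features (forest/boosted) or a stack (CNN)."""
    if isinstance(classifier, SlideCNN):
        proba = classifier.predict_proba([x])[0]
    else:
        proba = classifier.predict_proba(np.atleast_2d(x))[0]
    probs = {c: float(p) for c, p in zip(classifier.classes, proba)}
    for c in CLASS_ORDER:
        probs.setdefault(c, 0.0)
    predicted = max(classifier.classes,
                    key=lambda c: probs[c])
    return SlidePrediction(probs, predicted)


@dataclass
class BaselineFractionClassifier:
    """Reference baseline: thresholds on patch counts and malignant fraction.

    Predicts ``insufficient`` below a minimum number of processed patches,
    ``malignant`` above a malignant-patch fraction, else benign.  Kept as a
    comparison point for the feature-based classifiers.
    """

    min_patches: int = 5
    malignant_fraction: float = 0.2
    classes: tuple[str, ...] = CLASS_ORDER

    def predict_one(self, n_patches: int, frac_malignant: float) -> str:
        if n_patches < self.min_patches:
            return "insufficient"
        return "malignant" if frac_malignant > self.malignant_fraction else "other_or_benign"
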