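"""End-to-end synthetic triage study.

Runs the whole pipeline on a seeded cohort of synthetic slides: blood/mucus
pixel-classifier training, per-slide preprocessing (background + blood
detection combined with the annotation), grid patching, desk-scale patch
classifier training, heatmap assembly, tuned 42-dim feature extraction, and
the class-weighted gradient-boosted slide classifier, evaluated on held-out
slides.  This is the study the acceptance checks and the ``run`` CLI
command execute; all randomness derives from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masks import RegionClass, SlideGroundTruth
from .metrics import ConfusionMatrix, confusion, triage_metrics
from .patch_model import (
    PatchClassifier,
    assemble_heatmaps,
    downsample_patch,
    heatmap_shape,
    train_patch_classifier,
)
from .patching import PatchRecord, extract_patch_image, grid_patches, label_patches
from .pyramid import ImagePyramid
from .heatmap_features import features_tuned, features_wang, tuned_feature_names
from .slide_model import ClassWeights, SlideClassifier, train_slide_gbt
from .synthetic import SyntheticSlideSpec, generate_slide
from .tissue import (
    BloodMucusModel,
    combine_masks,
    detect_background,
    detect_blood_mucus,
    extract_pixel_features,
    tissue_area,
    train_blood_mucus_model,
)


@dataclass
class StudyConfig:
    """Conditions of the synthetic study.

    Defaults give 150 slides (90 train / 60 eval) with the three slide
    phenotypes, 3072 px square bases, 256 px patches admitted by the
    majority-tissue rule, and the sensitivity-tuned class weights.
    """

    n_train: dict = field(
        default_factory=lambda: {"malignant": 36, "other_or_benign": 36,
                                 "insufficient": 18}
    )
    n_eval: dict = field(
        default_factory=lambda: {"malignant": 24, "other_or_benign": 24,
                                 "insufficient": 12}
    )
    base_size: int = 3072
    patch_size: int = 256
    tissue_rule: str = "majority_tissue"
    n_patches_per_class: int = 1200
    patch_max_epochs: int = 30
    patch_hidden: int = 64
    weights: ClassWeights = field(default_factory=ClassWeights.sensitivity_tuned)
    n_blood_slides: int = 2
    pixels_per_class: int = 8000
    compute_wang: bool = False

    @property
    def cells_per_patch(self) -> float:
        return (self.patch_size // 32) ** 2


def sample_spec(intended: str, base_size: int, rng: np.random.Generator) -> SyntheticSlideSpec:
    """Draw one slide spec of the intended class, covering the phenotypes."""
    seed = int(rng.integers(0, 2**31 - 1))
    if intended == "insufficient":
        return SyntheticSlideSpec(
            base_size=base_size,
            n_tissue_pieces=int(rng.integers(0, 2)),
            fragmentation="many_fragments",
            malignant_fraction=0.0,
            blood_fraction=float(rng.uniform(0.0, 0.15)),
            seed=seed,
        )
    fragmentation = "large_pieces" if rng.random() < 0.6 else "many_fragments"
    n_pieces = (
        int(rng.integers(3, 7))
        if fragmentation == "large_pieces"
        else int(rng.integers(25, 46))
    )
    blood = 0.0 if rng.random() < 0.5 else float(rng.uniform(0.05, 0.2))
    mal = float(rng.uniform(0.35, 0.9)) if intended == "malignant" else 0.0
    return SyntheticSlideSpec(
        base_size=base_size,
        n_tissue_pieces=n_pieces,
        fragmentation=fragmentation,
        malignant_fraction=mal,
        blood_fraction=blood,
        seed=seed,
    )


@dataclass
class SlideData:
    """Per-slide intermediate products kept in memory during a study."""

    slide_id: str
    label: str  # ground-truth slide label
    region_mask: np.ndarray
    records: list[PatchRecord]
    patch_features: np.ndarray  # (n_records, d) float32, preprocessed patches
    thumbnail: np.ndarray
    tissue_cells: int


def train_blood_model_from_slides(
    config: StudyConfig, rng: np.random.Generator
) -> BloodMucusModel:
    """Train the pixel classifier on dedicated blood-rich synthetic slides.

    Emulates the clinical procedure of detailed annotation on a small
    subset: ground-truth masks supply the per-pixel labels, and pixels are
    subsampled per class for speed.
    """
    stacks, labels = [], []
    for _ in range(config.n_blood_slides):
        spec = SyntheticSlideSpec(
            base_size=config.base_size,
            n_tissue_pieces=4,
            fragmentation="large_pieces",
            malignant_fraction=0.3,
            blood_fraction=0.25,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        pyramid, truth = generate_slide(spec)
        thumb = pyramid.level(5)
        feat = extract_pixel_features(thumb)
        non_bg = truth.class_mask != RegionClass.BACKGROUND
        blood = truth.class_mask == RegionClass.BLOOD_MUCUS
        stacks.append(feat[non_bg])
        labels.append(blood[non_bg])
    X = np.concatenate(stacks)
    y = np.concatenate(labels)
    keep = []
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        if len(idx) > config.pixels_per_class:
            idx = rng.choice(idx, size=config.pixels_per_class, replace=False)
        keep.append(idx)
    keep = np.concatenate(keep)
    seed = int(rng.integers(0, 2**31 - 1))
    return train_blood_mucus_model([X[keep]], [y[keep]], seed=seed)


def process_slide(
    pyramid: ImagePyramid,
    truth: SlideGroundTruth,
    blood_model: BloodMucusModel,
    config: StudyConfig,
    slide_id: str,
) -> SlideData:
    """Preprocess one slide: masks, patch records, preprocessed patch features."""
    thumb = pyramid.level(5)
    background = detect_background(thumb)
    blood = detect_blood_mucus(thumb, blood_model)
    region = combine_masks(background, blood, truth.annotation)
    records = grid_patches(
        region, config.patch_size, rule=config.tissue_rule, slide_id=slide_id
    )
    label_patches(records, region)
    feats = np.zeros((len(records), 0), dtype=np.float32)
    if records:
        feats = np.stack(
            [
                downsample_patch(extract_patch_image(pyramid, rec)).astype(np.float32)
                for rec in records
            ]
        )
    return SlideData(
        slide_id, truth.slide_label, region, records, feats, thumb,
        tissue_area(region),
    )


def _balanced_patch_training_set(
    slides: list[SlideData], n_per_class: int, rng: np.random.Generator
):
    feats, labels = [], []
    for s in slides:
        for i, rec in enumerate(s.records):
            feats.append(s.patch_features[i])
            labels.append(rec.label)
    labels = np.asarray(labels)
    chosen = []
    for cls in ("malignant", "other_or_benign"):
        idx = np.flatnonzero(labels == cls)
        if len(idx) > n_per_class:
            idx = np.sort(rng.choice(idx, size=n_per_class, replace=False))
        chosen.append(idx)
    idx = np.concatenate(chosen)
    X = np.stack([feats[i] for i in idx]).astype(np.float64)
    y = labels[idx]
    return X, y


def slide_features(
    data: SlideData, patch_clf: PatchClassifier, config: StudyConfig,
    variant: str = "tuned42",
):
    """Patch predictions -> heatmap -> fixed-length slide feature vector."""
    grid = heatmap_shape(data.region_mask.shape, config.patch_size)
    if data.records:
        probs = patch_clf.predict_proba_features(
            data.patch_features.astype(np.float64)
        )
    else:
        probs = np.zeros((0, 2))
    heatmap = assemble_heatmaps(probs, data.records, grid)
    if variant == "tuned42":
        return features_tuned(
            heatmap.malignant, heatmap.other_benign, data.tissue_cells,
            cells_per_patch=config.cells_per_patch,
        ), heatmap
    return features_wang(
        heatmap.malignant, data.tissue_cells,
        cells_per_patch=config.cells_per_patch,
    ), heatmap


@dataclass
class StudyResult:
    accuracy: float
    sensitivity: dict[str, float]
    confusion: ConfusionMatrix
    n_slides: int
    blood_holdout_accuracy: float
    patch_training_log: pd.DataFrame
    weight_trend: pd.DataFrame
    train_features: pd.DataFrame
    eval_features: pd.DataFrame
    train_labels: list[str]
    eval_labels: list[str]
    eval_predictions: list[str]
    classifier: SlideClassifier
    patch_classifier: PatchClassifier
    blood_model: BloodMucusModel


#: joint grid for the sensitivity-vs-weights trend: the two non-malignant
#: weights decrease together towards the tuned preset
WEIGHT_TREND_GRID = [
    ClassWeights(1.0, 1.0, 1.0),
    ClassWeights(1.0, 0.5, 1.0),
    ClassWeights(1.0, 0.2, 0.4),
    ClassWeights(1.0, 0.1, 0.2),
    ClassWeights(1.0, 0.05, 0.1),
]


def run_study(seed: int = 0, config: StudyConfig | None = None) -> StudyResult:
    """Run the full synthetic triage study and evaluate on held-out slides."""
    config = config or StudyConfig()
    root = np.random.default_rng(np.random.SeedSequence(seed))

    blood_model = train_blood_model_from_slides(config, root)

    cohort: list[tuple[str, SlideData]] = []
    for split, counts in (("train", config.n_train), ("eval", config.n_eval)):
        i = 0
        for intended, n in counts.items():
            for _ in range(n):
                spec = sample_spec(intended, config.base_size, root)
                pyramid, truth = generate_slide(spec)
                data = process_slide(
                    pyramid, truth, blood_model, config, f"{split}_{i:03d}"
                )
                cohort.append((split, data))
                i += 1
    train_slides = [d for s, d in cohort if s == "train"]
    eval_slides = [d for s, d in cohort if s == "eval"]

    # patch classifier on a balanced, seeded sample of training-slide patches
    Xp, yp = _balanced_patch_training_set(
        train_slides, config.n_patches_per_class, root
    )
    perm = root.permutation(len(Xp))
    n_valid = max(2, len(Xp) // 4)
    valid_idx, train_idx = perm[:n_valid], perm[n_valid:]
    patch_clf = train_patch_classifier(
        Xp[train_idx], yp[train_idx], Xp[valid_idx], yp[valid_idx],
        seed=int(root.integers(0, 2**31 - 1)),
        max_epochs=config.patch_max_epochs,
        n_hidden=config.patch_hidden,
    )

    def feature_table(slides: list[SlideData]) -> pd.DataFrame:
        rows = [slide_features(d, patch_clf, config)[0].values for d in slides]
        return pd.DataFrame(rows, columns=list(tuned_feature_names()),
                            index=[d.slide_id for d in slides])

    train_table = feature_table(train_slides)
    eval_table = feature_table(eval_slides)
    train_labels = [d.label for d in train_slides]
    eval_labels = [d.label for d in eval_slides]

    gbt_seed = int(root.integers(0, 2**31 - 1))
    clf = train_slide_gbt(train_table, train_labels, weights=config.weights,
                          seed=gbt_seed)
    preds = clf.predict(eval_table.to_numpy())
    cm = confusion(preds, eval_labels)
    accuracy, sensitivity = triage_metrics(cm)

    trend_rows = []
    for w in WEIGHT_TREND_GRID:
        clf_w = train_slide_gbt(train_table, train_labels, weights=w,
                                seed=gbt_seed)
        p_w = clf_w.predict(eval_table.to_numpy())
        cm_w = confusion(p_w, eval_labels)
        acc_w, sens_w = triage_metrics(cm_w)
        trend_rows.append(
            {
                "other_or_benign_weight": w.other_or_benign,
                "insufficient_weight": w.insufficient,
                "accuracy": acc_w,
                "malignant_sensitivity": sens_w["malignant"],
            }
        )

    return StudyResult(
        accuracy=accuracy,
        sensitivity=sensitivity,
        confusion=cm,
        n_slides=len(cohort),
        blood_holdout_accuracy=blood_model.holdout_accuracy,
        patch_training_log=patch_clf.training_log,
        weight_trend=pd.DataFrame(trend_rows),
        train_features=train_table,
        eval_features=eval_table,
        train_labels=train_labels,
        eval_labels=eval_labels,
        eval_predictions=preds,
        classifier=clf,
        patch_classifier=patch_clf,
        blood_model=blood_model,
    )
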