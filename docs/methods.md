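# Methods

This note records the models, conventions and design choices behind
`endotriage`, in the spirit of the methods documentation of mature
scientific packages: what is computed, under which assumptions, and what
the synthetic validation does and does not establish.

## Problem setting

An endometrial biopsy WSI is a multi-gigapixel RGB pyramid; level *l* is
downsampled 2^*l* from the 40× base (0.25 µm/px, so one level-5 pixel
covers a 32 × 32 px footprint, 8 µm/px).  The task is three-way slide
classification — malignant (including hyperplasia with atypia, a high-risk
preinvasive lesion), other-or-benign, insufficient — for workload triage:
slides are ranked by predicted malignant probability, so even an
uncertain, wrongly classified malignant slide should surface earlier than
confidently benign ones.

Slide annotations use the overall-class-plus-overrides convention: each
slide carries one tissue class, and only regions that differ are outlined
as polygons.  "Insufficient" is a slide category (a lack of tissue), not a
tissue class, so it never appears as an annotation class.

## Tissue and blood/mucus detection

Background separation operates on the level-5 thumbnail: pure-black
pixels (stitching gaps between separately stored image regions) are first
converted to white; grey values (ITU-R 601 luma, rescaled to [0, 1])
strictly above 0.85 are background; the tissue mask is then closed with a
disk of radius 2 and holes are filled (regions not connected to the
border).  The structuring-element radius is this package's choice — the
operations themselves are standard, their parameters are not dictated by
anything — and lowering the grey threshold can only shrink the raw tissue
mask (strict monotonicity holds before morphology).

Blood and mucus are detected per pixel by a random forest (100 trees,
otherwise library defaults) over a 12-feature stack: per RGB channel the
raw value, a Gaussian-filtered value, and a texture statistic of each.
Two parameterisations were genuinely open and are fixed as follows:

* **Texture filter** = local standard deviation in a 3 × 3 window; the
  cheapest rotation-invariant texture statistic, and identically zero on
  constant regions, which the tests exploit.
* **Gaussian "kernel size 2"** is read as σ = 2 (truncated at 4σ);
  a discrete "kernel size" of 2 has no standard meaning.

The combined region mask assigns each level-5 cell exactly one of
{background, blood_mucus, other_benign, malignant} with precedence
background > blood/mucus > annotation override > overall class.

## Patching

Patches are cut at level 0 on a grid anchored at the slide origin with
stride equal to the patch size (256/512/1024 px; the size must divide by
32 so footprints align with level-5 cells).  Partial edge patches are
discarded.  Inclusion rules: *any-tissue* (≥ 1 tissue cell in the
footprint) or *majority-tissue* (tissue at least as common as blood/mucus
and as background; ties go to tissue, since the motivating rule is
"most common class" without a stated tie-break).  A patch containing any
malignant cell is labelled malignant — deliberately asymmetric, since any
malignant tissue makes a slide malignant.

Grid misalignment on fragmented slides can exclude almost all tissue
under the majority rule.  An optional remedy (off by default) places a
minimum number of randomly positioned, cell-aligned patches inside
detected tissue when the grid yields fewer; it is intended for harvesting
training patches, not for heatmap assembly, where the stride = size
bijection between patches and cells must hold.

## Patch classifier

The classifier contract maps an RGB patch to (p_malignant, p_benign),
summing to one.  The training schedule is fixed: SGD (momentum 0.9) with
cross-entropy, initial learning rate 0.01 halved every two epochs (epochs
0-based: lr(e) = 0.01 / 2^⌊e/2⌋), early stopping once validation accuracy
has not increased for three consecutive epochs, returning the
best-validation checkpoint.

The architecture is pluggable.  The packaged desk-scale architecture
block-averages each patch to a 16 × 16 thumbnail and classifies the
flattened, per-feature-standardised 768-vector with a one-hidden-layer
ReLU network (64 hidden units) written on numpy — small enough to train
in seconds on a CPU, deterministic under a fixed seed, and entirely
sufficient for colour/texture-separable synthetic patches.  Any model
with the same probabilistic contract (e.g. a full CNN) can be substituted.
Standardisation statistics are fitted on the training split and stored
with the model; momentum 0.9 is a conventional default recorded in the
checkpoint.

Predictions for all processed patches are assembled into two aligned
heatmaps at one cell per grid position (the natural pitch when stride =
size); unprocessed cells are zero in both channels, and probabilities
near 0.5 denote patches the classifier is genuinely unsure about.

## Heatmap features

Segments are maximal 8-connected components (diagonal neighbours count)
of the strictly thresholded heatmap, ordered by area descending with ties
broken by the top-left-most cell.  Region properties follow `regionprops`
conventions: raw central moments define the equivalent ellipse (axis
lengths 4√λ, eccentricity √(1 − λ₂/λ₁), zero for degenerate segments),
extent = area / bbox area, solidity = area / pixelated-convex-hull area.
The bounding-box aspect ratio is width/height (columns/rows); the
max/min convention would be equally defensible and the field is computed
in one place if a different convention is needed.

Two fixed-length summaries are produced (zero blocks when a slide has
fewer segments than the recipe expects, so vector length never varies):

* **wang31**: tissue area; for thresholds 0.5–0.9 in steps of 0.1 the
  malignant area as % of tissue area and the total probability inside the
  mask (sum of channel values over mask cells — the natural reading of
  "total probability"); 10 properties × 2 largest malignant segments at
  threshold 0.5.  1 + 5×2 + 2×10 = 31.
* **tuned42**: tissue area; malignant and benign area % at thresholds
  0.6 and 0.9; 9 properties × 3 largest malignant segments and
  5 properties × 2 largest benign segments at 0.5.
  1 + 2×2 + 3×9 + 2×5 = 42.

Both recipes segment at 0.5 regardless of the loop thresholds.  Tissue
area is counted in level-5 cells; mask areas (heatmap cells) are converted
to the same units via `cells_per_patch` = (patch size / 32)², so the area
percentages are scale-consistent.  Malignant area % is non-increasing in
the threshold by construction.  With zero tissue area and a non-empty
heatmap the percentages are defined as 0 and a warning is raised.

## Slide classifiers

* **Random forest** on wang31: 100 estimators, seeded, all other
  hyperparameters at library defaults.
* **Gradient-boosted trees** (XGBoost) on tuned42: 200 estimators, max
  depth 2.  Per-sample weight = weight of its class; uniform weights
  reproduce the unweighted fit bit-for-bit.  The sensitivity-tuned preset
  (malignant 1.0, other-or-benign 0.05, insufficient 0.1) maximises
  malignant recall at a small accuracy cost; `weight_grid_search` selects
  weights maximising malignant sensitivity subject to an explicit
  accuracy floor, logging the full grid.
* **Heatmap-stack network**: both heatmaps plus the RGB thumbnail
  (area-averaged to heatmap scale) form a 5-channel stack, zero-padded so
  content sits centred on a training-set-wide canvas (offset
  ⌊(target − input)/2⌋).  Training: cross-entropy SGD for 10 epochs,
  lr 0.0005 halved once after epoch 5, random translation jitter of up to
  20 cells vertically and 40 horizontally per example — clamped to the
  available padding so content never leaves the canvas (a zero shift is
  always admissible) — and the best-validation-epoch checkpoint is kept.
  Inputs are standardised by a single global mean/std (per-feature
  scaling would break the spatial uniformity that makes jittered content
  learnable).  Inference slides on a larger canvas than the training
  maximum are centre-cropped with a warning.

A trivial baseline (thresholds on processed-patch count and malignant
fraction) is included as a reference point for tests; it is not a
supported output.

## Metrics

Confusion matrices are reported as counts and normalized over the true
category; rows with zero support are undefined (NaN), never 0.  Accuracy
is trace/total; sensitivity is the per-class recall.  Interobserver
agreement uses the unweighted Cohen's kappa, averaged arithmetically over
all rater pairs; the degenerate case of two identical constant raters
(chance agreement 1) is defined as κ = 1 with a warning.  The class order
(malignant, other_or_benign, insufficient) is fixed in all outputs.

## Synthetic slides and the recovery study

The generator emulates three real slide presentations — a few large
tissue pieces, many small fragments, and large blood/mucus areas — as
elliptical blobs on the level-5 grid, painted at level 0 with
class-specific mean colours plus Gaussian pixel noise (H&E-like purples
for tissue, darker for malignant, red for blood, near-white background).
Classes are separable by colour statistics by design, so every pipeline
stage is learnable without clinical data.  Malignant regions are whole
pieces or scaled insets so a requested malignant fraction of the tissue
is approximately met; blood is placed off-tissue; annotations record the
majority tissue class as the overall class and outline the minority as
polygon overrides, exactly as a pathologist annotating economically
would.  Slides with tissue below 1 % of the slide area are labelled
insufficient — the criterion separating "insufficient" from "a lack of
tissue" is this package's convention.

The recovery study (`endotriage.pipeline.run_study`, also behind
`endotriage run` and `scripts/acceptance.py`) uses 150 slides of
3072 × 3072 px base — 90 training (36/36/18 per class) and 60 evaluation
(24/24/12) — 256 px patches under the majority-tissue rule, 1200 balanced
training patches per class, and the sensitivity-tuned boosted classifier.
These sizes are the package's desk-scale study conditions: large enough
for stable training and per-class sensitivity estimates, small enough to
run in a few minutes on one CPU.  A five-point grid of jointly decreasing
non-malignant weights (ending at the 0.05/0.1 preset) traces the
sensitivity-vs-weights trend on the same cohort.

**What passing this study shows — and what it does not.**  It shows the
pipeline is correctly plumbed end to end: detection, patching, learning,
heatmap geometry, feature extraction and weighted classification recover
the slide classes when the patch signal is learnable.  It does not show
clinical performance: synthetic textures carry no nuclear morphology, no
stain variation between laboratories, no scanner artefacts, and their
class separability is far cleaner than real histology.  Known failure
modes of the approach reproduce qualitatively on synthetic data too —
fragmented slides losing patches to grid misalignment, and confusion
between benign and insufficient when heatmaps are nearly empty.

## Numerical conventions

Coordinates are 0-based, top-left origin, half-open intervals; arrays are
(row, col) with x = col.  Pyramid levels are built by iterated 2 × 2 mean
pooling (edge-replicated for odd extents), so a level-*l* pixel matches
its level-0 block mean to within ~1 grey level of rounding drift.
Heatmap thresholding is strict (>).  All trainers are bit-reproducible
given a seed; derived seeds stay below 2³¹.  Model files are Python
pickles containing the seed, feature order and training log alongside the
fitted estimator.

## Known limitations

Stain normalisation and colour augmentation are deliberately out of
scope.  The blood/mucus detector is only as good as its small annotated
training subset; on real data it is known to over-call pale-stained
tissue.  The heatmap-stack classifier is data-hungry relative to the
boosted-tree route and underperforms when one class (insufficient) is
rare.  Vendor WSI formats are not read; pyramids are plain PNG stacks
with a YAML sidecar.
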