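# endotriage

Triage of endometrial-biopsy whole-slide images (WSI). The package
classifies each H&E-stained slide as **malignant**, **other or benign** or
**insufficient** (too little tissue to diagnose), so that a pathology
service can review likely-malignant slides first and shorten time to
diagnosis for cancer patients.

## How it works

The pipeline has three stages:

1. **Tissue detection** (level 5 of the image pyramid, 8 µm/px).
   Pure-black stitching gaps are whitened, the thumbnail is converted to
   grey (ITU-R 601) and pixels with grey > 0.85 are background; the tissue
   mask is then morphologically closed and hole-filled.  A per-pixel
   random forest over a 12-feature stack (per RGB channel: raw, Gaussian
   σ=2, local-std texture of each) separates blood/mucus from diagnostic
   tissue.  Detection masks and the slide annotation (overall class plus
   polygon overrides) combine into a four-class region mask with
   precedence background > blood/mucus > override > overall class.
2. **Patch classification.**  The slide is cut into level-0 patches on a
   regular grid (stride = patch size); a patch is processed when tissue is
   the most common class in its level-5 footprint (or, optionally, when it
   contains any tissue).  A patch containing any malignant cell is
   labelled malignant.  A classifier maps each patch to
   (p_malignant, p_benign); training uses SGD with cross-entropy, initial
   learning rate 0.01 halved every 2 epochs, early stopping after 3
   epochs without validation improvement.  Predictions are reassembled
   into two probability heatmaps, one cell per patch.
3. **Slide classification.**  The heatmaps are summarised into fixed
   feature vectors: the 31-feature Camelyon-style recipe (tissue area;
   malignant area % and total probability at thresholds 0.5–0.9; 10
   region properties for the 2 largest segments at 0.5) feeding a random
   forest (100 trees), and a 42-feature tuned variant (areas at 0.6/0.9
   for both channels; 9 properties × 3 malignant segments; 5 properties ×
   2 benign segments) feeding gradient-boosted trees (200 estimators,
   depth 2).  Down-weighting the non-malignant classes during training
   (0.05 for other-or-benign, 0.1 for insufficient) trades a little
   accuracy for malignant sensitivity.  A 5-channel heatmap-stack
   classifier (both heatmaps + RGB thumbnail, zero-padded and centred) is
   also provided.

A segment is a maximal 8-connected component of the thresholded heatmap;
region properties (area, eccentricity, extent, solidity, axis lengths,
bounding-box statistics, probability statistics) follow the standard
`regionprops` conventions.

Because clinical WSIs cannot ship with a package, a seeded generator
produces synthetic slides that emulate the three real presentations — few
large tissue pieces, many small fragments, large blood/mucus areas — with
pixel-exact ground truth, so the full pipeline is exercisable end to end.

## Worked example

```python
from endotriage.pipeline import StudyConfig, run_study
from endotriage.slide_model import ClassWeights

config = StudyConfig(
    n_train={"malignant": 6, "other_or_benign": 6, "insufficient": 3},
    n_eval={"malignant": 4, "other_or_benign": 4, "insufficient": 2},
    base_size=1536, n_patches_per_class=150, patch_max_epochs=15,
    weights=ClassWeights(),   # uniform; the tuned preset needs a larger cohort
)
result = run_study(seed=1, config=config)
print(f"accuracy {result.accuracy:.3f}")
print(f"malignant sensitivity {result.sensitivity['malignant']:.3f}")
print(result.confusion.to_frame())
```

prints (a deliberately small 25-slide study):

```
accuracy 1.000
malignant sensitivity 1.000
                 malignant  other_or_benign  insufficient
malignant                4                0             0
other_or_benign          0                4             0
insufficient             0                0             2
```

All ten held-out slides are recovered; rows of the confusion matrix are
true classes, columns predictions.  With the sensitivity-tuned preset
(`ClassWeights.sensitivity_tuned()`, weights 0.05 / 0.1 on the two
non-malignant classes) the classifier trades a few benign slides into the
malignant queue for maximal malignant recall — the intended behaviour of
a triage tool, visible on the full 150-slide study below.  The same
pipeline is available stage by stage from the shell:

```sh
endotriage synth --out slides --n-malignant 3 --n-benign 3 --n-insufficient 1
endotriage preprocess --slides slides --blood-model blood.pkl
endotriage patch --slides slides --out manifest.csv
endotriage train-patch --slides slides --manifest manifest.csv --out patch.pkl
endotriage heatmap --slides slides --manifest manifest.csv --model patch.pkl --out heatmaps
endotriage features --heatmaps heatmaps --slides slides --out features.csv
endotriage train-slide --features features.csv --labels slides/labels.csv --out slide.pkl
endotriage predict --features features.csv --model slide.pkl --out predictions.csv
endotriage evaluate --predictions predictions.csv --labels slides/labels.csv --out eval
```

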