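import numpy as np
import pandas as pd
import pytest

from endotriage.slide_model import (
    CLASS_ORDER,
    ClassWeights,
    HeatmapStack,
    pad_and_stack,
    predict_slide,
    slide_cnn_learning_rate,
    train_slide_cnn,
    train_slide_gbt,
    train_slide_rf,
    weight_grid_search,
)


def _separable_features(n_per_class, seed=0, overlap=0.0):
    """3-class feature table: class means far apart unless overlap > 0."""
    rng = np.random.default_rng(seed)
    means = {"malignant": 5.0, "other_or_benign": 0.0, "insufficient": -5.0}
    X, y = [], []
    for cls, mu in means.items():
        X.append(rng.normal(mu, 1.0 + 4.0 * overlap, size=(n_per_class, 6)))
        y += [cls] * n_per_class
    return np.concatenate(X), y


class TestRandomForest:
    def test_separable_features_fit_perfectly(self):
        X, y = _separable_features(100)
        clf = train_slide_rf(X, y, seed=0)
        assert clf.predict(X) == y

    def test_same_seed_identical_predictions(self):
        X, y = _separable_features(50, overlap=0.8)
        probe, _ = _separable_features(10, seed=9, overlap=0.8)
        a = train_slide_rf(X, y, seed=1).predict_proba(probe)
        b = train_slide_rf(X, y, seed=1).predict_proba(probe)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        X = np.zeros((5, 3))
        with pytest.raises(ValueError):
            train_slide_rf(X, ["malignant"] * 5)

    def test_unknown_label_rejected(self):
        X, y = _separable_features(10)
        with pytest.raises(ValueError):
            train_slide_rf(X, y[:-1] + ["mystery"])


class TestGradientBoosted:
    def test_uniform_weights_equal_unweighted_fit(self):
        X, y = _separable_features(40, overlap=0.5)
        probe, _ = _separable_features(10, seed=5, overlap=0.5)
        weighted = train_slide_gbt(X, y, weights=ClassWeights(1, 1, 1), seed=2)
        unweighted = train_slide_gbt(X, y, weights=None, seed=2)
        assert np.array_equal(weighted.predict_proba(probe),
                              unweighted.predict_proba(probe))

    def test_downweighting_benign_does_not_hurt_malignant_recall(self):
        """On overlapping classes, cutting the benign weight to 0.05 must
        not reduce recall of the malignant class."""
        X, y = _separable_features(60, seed=3, overlap=1.0)
        Xv, yv = _separable_features(40, seed=4, overlap=1.0)

        def recall(weights):
            clf = train_slide_gbt(X, y, weights=weights, seed=0)
            preds = clf.predict(Xv)
            idx = [i for i, t in enumerate(yv) if t == "malignant"]
            return np.mean([preds[i] == "malignant" for i in idx])

        assert recall(ClassWeights(1, 0.05, 1)) >= recall(ClassWeights(1, 1, 1))

    def test_non_positive_weights_rejected(self):
        with pytest.raises(ValueError):
            ClassWeights(1.0, 0.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_slide_gbt(np.zeros((4, 2)), ["insufficient"] * 4)

    def test_accepts_dataframe_features(self):
        X, y = _separable_features(30)
        table = pd.DataFrame(X, columns=[f"f{i}" for i in range(6)])
        clf = train_slide_gbt(table, y, seed=0)
        assert clf.predict(X[:3]) == y[:3]


class TestWeightGridSearch:
    def test_single_point_grid_returns_it(self):
        X, y = _separable_features(30)
        w = ClassWeights(1, 0.5, 0.5)
        best, results = weight_grid_search(X, y, X, y, [w])
        assert best is w
        assert len(results) == 1

    def test_zero_floor_maximises_sensitivity_alone(self):
        X, y = _separable_features(50, seed=1, overlap=1.2)
        Xv, yv = _separable_features(30, seed=2, overlap=1.2)
        grid = [ClassWeights(1, 1, 1), ClassWeights(1, 0.05, 0.1)]
        best, results = weight_grid_search(X, y, Xv, yv, grid,
                                           accuracy_floor=0.0)
        sens = results.malignant_sensitivity
        assert sens[results.index[
            (results.other_or_benign == best.other_or_benign)
            & (results.insufficient == best.insufficient)
        ][0]] == sens.max()

    def test_rerun_is_deterministic(self):
        X, y = _separable_features(30, overlap=0.5)
        grid = [ClassWeights(1, w, w) for w in (1.0, 0.3, 0.05)]
        a, _ = weight_grid_search(X, y, X, y, grid, seed=7)
        b, _ = weight_grid_search(X, y, X, y, grid, seed=7)
        assert (a.other_or_benign, a.insufficient) == \
            (b.other_or_benign, b.insufficient)

    def test_empty_grid_rejected(self):
        X, y = _separable_features(10)
        with pytest.raises(ValueError):
            weight_grid_search(X, y, X, y, [])


class TestPadAndStack:
    def _inputs(self, h, w):
        rng = np.random.default_rng(0)
        mal = rng.random((h, w))
        ben = 1 - mal
        thumb = rng.integers(0, 256, size=(h * 4, w * 4, 3), dtype=np.uint8)
        return mal, ben, thumb

    def test_equal_dims_content_unchanged(self):
        mal, ben, thumb = self._inputs(6, 6)
        stack = pad_and_stack(mal, ben, thumb, (6, 6))
        assert stack.offset == (0, 0)
        assert np.array_equal(stack.channels[0], mal)

    def test_channel_sums_preserved_by_padding(self):
        mal, ben, thumb = self._inputs(5, 7)
        stack = pad_and_stack(mal, ben, thumb, (11, 13))
        assert stack.channels[0].sum() == pytest.approx(mal.sum())
        assert stack.channels[1].sum() == pytest.approx(ben.sum())

    def test_centred_offsets(self):
        mal, ben, thumb = self._inputs(10, 10)
        stack = pad_and_stack(mal, ben, thumb, (20, 16))
        assert stack.offset == (5, 3)

    def test_five_channels_in_unit_range(self):
        mal, ben, thumb = self._inputs(4, 4)
        stack = pad_and_stack(mal, ben, thumb, (8, 8))
        assert stack.channels.shape == (5, 8, 8)
        assert stack.channels.min() >= 0 and stack.channels.max() <= 1

    def test_target_smaller_than_input_rejected(self):
        mal, ben, thumb = self._inputs(6, 6)
        with pytest.raises(ValueError):
            pad_and_stack(mal, ben, thumb, (4, 8))


def _stack_cohort(n_per_class, canvas=(12, 12), seed=0):
    """Synthetic stacks: malignant slides carry a bright channel-0 block,
    benign a bright channel-1 block, insufficient almost nothing."""
    rng = np.random.default_rng(seed)
    stacks, labels = [], []
    for cls in CLASS_ORDER:
        for _ in range(n_per_class):
            h, w = int(rng.integers(5, 9)), int(rng.integers(5, 9))
            mal = rng.random((h, w)) * 0.1
            ben = rng.random((h, w)) * 0.1
            if cls == "malignant":
                mal[1:4, 1:4] = rng.uniform(0.8, 1.0, (3, 3))
            elif cls == "other_or_benign":
                ben[1:4, 1:4] = rng.uniform(0.8, 1.0, (3, 3))
            else:
                mal *= 0.1
                ben *= 0.1
            thumb = rng.integers(200, 256, size=(h, w, 3), dtype=np.uint8)
            stacks.append(pad_and_stack(mal, ben, thumb, canvas))
            labels.append(cls)
    return stacks, labels


class TestSlideCNN:
    @pytest.mark.parametrize("epoch,expected", [
        (0, 0.0005), (4, 0.0005), (5, 0.00025), (7, 0.00025), (9, 0.00025),
    ])
    def test_learning_rate_halves_once_after_five_epochs(self, epoch, expected):
        assert slide_cnn_learning_rate(epoch) == pytest.approx(expected)

    def test_zero_jitter_permitted_by_sampler(self):
        """With no padding margin the jitter must clamp to (0, 0)."""
        stacks, labels = _stack_cohort(4, canvas=(8, 8), seed=1)
        tight = [s for s in stacks if s.content_shape == (8, 8)]
        clf = train_slide_cnn(stacks, labels, stacks, labels, epochs=2, seed=0)
        assert clf.predict_proba(stacks).shape == (len(stacks), 3)

    def test_learns_separable_stacks(self):
        train_s, train_y = _stack_cohort(12, seed=2)
        valid_s, valid_y = _stack_cohort(6, seed=3)
        clf = train_slide_cnn(train_s, train_y, valid_s, valid_y,
                              epochs=10, lr=0.01, seed=0)
        acc = np.mean([p == t for p, t in zip(clf.predict(valid_s), valid_y)])
        assert acc >= 0.9

    def test_missing_class_rejected(self):
        stacks, labels = _stack_cohort(3)
        only_two = [s for s, l in zip(stacks, labels) if l != "insufficient"]
        lbl_two = [l for l in labels if l != "insufficient"]
        with pytest.raises(ValueError):
            train_slide_cnn(only_two, lbl_two, stacks, labels, epochs=1)

    def test_oversized_inference_stack_centre_cropped_with_warning(self):
        stacks, labels = _stack_cohort(4, canvas=(12, 12), seed=6)
        clf = train_slide_cnn(stacks, labels, stacks, labels, epochs=2, seed=0)
        big, _ = _stack_cohort(1, canvas=(16, 20), seed=7)
        with pytest.warns(UserWarning, match="centre-crop"):
            proba = clf.predict_proba(big[:1])
        assert proba.shape == (1, 3)

    def test_bit_reproducible_under_fixed_seed(self):
        stacks, labels = _stack_cohort(4, seed=5)
        a = train_slide_cnn(stacks, labels, stacks, labels, epochs=3, seed=9)
        b = train_slide_cnn(stacks, labels, stacks, labels, epochs=3, seed=9)
        assert np.array_equal(a.predict_proba(stacks), b.predict_proba(stacks))


class TestPredictSlide:
    def test_probabilities_sum_to_one_and_argmax_reported(self):
        X, y = _separable_features(30)
        clf = train_slide_gbt(X, y, seed=0)
        pred = predict_slide(clf, X[0])
        assert sum(pred.probabilities.values()) == pytest.approx(1.0, abs=1e-6)
        assert pred.predicted_class == max(pred.probabilities,
                                           key=pred.probabilities.get)

    def test_feature_pipeline_beats_trivial_baseline_contract(self):
        """The packaged baseline encodes the simple patch-count rules; it
        must at least behave as documented on its own terms."""
        from endotriage.slide_model import BaselineFractionClassifier
        base = BaselineFractionClassifier(min_patches=5, malignant_fraction=0.2)
        assert base.predict_one(2, 0.9) == "insufficient"
        assert base.predict_one(50, 0.5) == "malignant"
        assert base.predict_one(50, 0.05) == "other_or_benign"

    def test_near_tie_still_ranks_above_confident_benign(self):
        """A slide with malignant probability 0.455 sorts above slides the
        model is confident are benign in the triage queue."""
        near_tie = {"malignant": 0.455, "other_or_benign": 0.456,
                    "insufficient": 0.089}
        confident = {"malignant": 0.02, "other_or_benign": 0.95,
                     "insufficient": 0.03}
        from endotriage.slide_model import SlidePrediction
        a = SlidePrediction(near_tie, "other_or_benign")
        b = SlidePrediction(confident, "other_or_benign")
        queue = sorted([b, a], key=lambda p: -p.malignant_probability)
        assert queue[0] is a
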