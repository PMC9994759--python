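import logging

import numpy as np
import pytest

from endotriage.masks import RegionClass
from endotriage.patching import (
    PatchRecord,
    extract_patch_image,
    grid_patches,
    label_patch,
    label_patches,
    records_from_frame,
    records_to_frame,
    sample_balanced,
)
from endotriage.pyramid import read_region

B, BM, OB, M = (int(RegionClass.BACKGROUND), int(RegionClass.BLOOD_MUCUS),
                int(RegionClass.OTHER_BENIGN), int(RegionClass.MALIGNANT))


class TestGridPatches:
    def test_all_tissue_8x8_mask_gives_one_patch(self):
        mask = np.full((8, 8), OB, dtype=np.uint8)
        records = grid_patches(mask, 256, rule="any_tissue")
        assert len(records) == 1
        assert (records[0].x, records[0].y) == (0, 0)
        assert records[0].tissue_fraction == 1.0

    def test_majority_rule_counting(self):
        """33 tissue vs 31 background cells: tissue is the most common."""
        mask = np.full((8, 8), B, dtype=np.uint8)
        mask.flat[:33] = OB
        assert len(grid_patches(mask, 256, rule="majority_tissue")) == 1
        mask.flat[:33] = B
        mask.flat[:31] = OB  # now background dominates
        assert len(grid_patches(mask, 256, rule="majority_tissue")) == 0

    def test_tissue_wins_ties(self):
        mask = np.full((8, 8), B, dtype=np.uint8)
        mask.flat[:32] = OB
        assert len(grid_patches(mask, 256, rule="majority_tissue")) == 1

    def test_any_rule_superset_of_majority_rule(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mask = rng.choice([B, BM, OB, M], size=(24, 24)).astype(np.uint8)
            keys = lambda recs: {(r.x, r.y) for r in recs}
            any_set = keys(grid_patches(mask, 256, rule="any_tissue"))
            maj_set = keys(grid_patches(mask, 256, rule="majority_tissue"))
            assert maj_set <= any_set

    def test_patch_count_bound(self):
        rng = np.random.default_rng(1)
        mask = rng.choice([B, OB], size=(32, 32)).astype(np.uint8)
        records = grid_patches(mask, 256, stride=256)
        assert len(records) <= 16  # ceil(32/8)^2

    def test_partial_edge_patches_discarded(self):
        mask = np.full((10, 10), OB, dtype=np.uint8)  # 10 cells, side 8
        records = grid_patches(mask, 256, stride=256)
        assert len(records) == 1

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        mask = rng.choice([B, BM, OB, M], size=(16, 16)).astype(np.uint8)
        for rec in grid_patches(mask, 256, rule="any_tissue"):
            assert rec.tissue_fraction + rec.blood_fraction \
                + rec.background_fraction == pytest.approx(1.0)

    def test_patch_size_not_multiple_of_32_rejected(self):
        with pytest.raises(ValueError):
            grid_patches(np.full((8, 8), OB, np.uint8), 100)

    def test_min_patches_random_placement_remedy(self):
        """A fragmented mask that loses everything to the majority rule
        still yields patches when the minimum-patch remedy is enabled."""
        mask = np.full((24, 24), B, dtype=np.uint8)
        mask[3:6, 3:6] = OB  # small fragment straddling grid lines
        mask[13:16, 13:16] = OB
        none = grid_patches(mask, 256, rule="majority_tissue")
        assert len(none) == 0
        some = grid_patches(mask, 256, rule="majority_tissue",
                            min_patches=4, seed=0)
        assert len(some) == 4
        assert all(r.tissue_fraction > 0 for r in some)
        again = grid_patches(mask, 256, rule="majority_tissue",
                             min_patches=4, seed=0)
        assert [(r.x, r.y) for r in again] == [(r.x, r.y) for r in some]


class TestLabelPatch:
    def test_single_malignant_cell_labels_malignant(self):
        mask = np.full((8, 8), OB, dtype=np.uint8)
        mask[3, 3] = M
        rec = PatchRecord("s", 0, 0, 256, 1.0, 0.0, 0.0)
        assert label_patch(rec, mask) == "malignant"

    def test_no_malignant_cell_labels_benign(self):
        mask = np.full((8, 8), OB, dtype=np.uint8)
        rec = PatchRecord("s", 0, 0, 256, 1.0, 0.0, 0.0)
        assert label_patch(rec, mask) == "other_or_benign"

    def test_all_malignant_labels_malignant(self):
        mask = np.full((8, 8), M, dtype=np.uint8)
        rec = PatchRecord("s", 0, 0, 256, 1.0, 0.0, 0.0)
        assert label_patch(rec, mask) == "malignant"

    def test_out_of_bounds_footprint_rejected(self):
        mask = np.full((8, 8), OB, dtype=np.uint8)
        rec = PatchRecord("s", 256, 0, 256, 1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            label_patch(rec, mask)

    def test_benign_slide_yields_no_malignant_labels(self, benign_slide):
        _, truth = benign_slide
        records = grid_patches(truth.class_mask, 256, rule="any_tissue")
        label_patches(records, truth.class_mask)
        assert all(r.label == "other_or_benign" for r in records)


def _records(n, label):
    return [PatchRecord("s", 256 * i, 0, 256, 1.0, 0.0, 0.0, label)
            for i in range(n)]


class TestSampleBalanced:
    def test_exact_counts_per_class(self):
        recs = _records(50, "malignant") + _records(80, "other_or_benign")
        out = sample_balanced(recs, 20, seed=0)
        labels = [r.label for r in out]
        assert labels.count("malignant") == 20
        assert labels.count("other_or_benign") == 20

    def test_same_seed_same_selection(self):
        recs = _records(50, "malignant") + _records(80, "other_or_benign")
        a = sample_balanced(recs, 20, seed=3)
        b = sample_balanced(recs, 20, seed=3)
        assert [(r.x, r.label) for r in a] == [(r.x, r.label) for r in b]

    def test_shortfall_takes_all_with_warning(self, caplog):
        recs = _records(5, "malignant") + _records(80, "other_or_benign")
        with caplog.at_level(logging.WARNING):
            out = sample_balanced(recs, 20, seed=0)
        labels = [r.label for r in out]
        assert labels.count("malignant") == 5
        assert labels.count("other_or_benign") == 20
        assert any("available" in r.message for r in caplog.records)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            sample_balanced(_records(5, "malignant"), 2, seed=0)


class TestExtractPatchImage:
    def test_matches_read_region(self, malignant_slide):
        pyramid, _ = malignant_slide
        rec = PatchRecord("s", 256, 512, 256, 1.0, 0.0, 0.0)
        img = extract_patch_image(pyramid, rec)
        assert np.array_equal(img, read_region(pyramid, 0, 256, 512, 256, 256))

    def test_footprint_maps_to_level5_block(self):
        rec = PatchRecord("s", 512, 1024, 256, 1.0, 0.0, 0.0)
        assert rec.footprint == (32, 16, 8)

    def test_overlapping_stride_shares_pixels(self, malignant_slide):
        pyramid, truth = malignant_slide
        records = grid_patches(truth.class_mask, 256, stride=128,
                               rule="any_tissue")
        xs = sorted({r.x for r in records})
        assert any(b - a == 128 for a, b in zip(xs, xs[1:]))


def test_manifest_round_trip():
    recs = _records(3, "malignant") + _records(2, "other_or_benign")
    back = records_from_frame(records_to_frame(recs))
    assert [(r.x, r.y, r.size, r.label) for r in back] == \
        [(r.x, r.y, r.size, r.label) for r in recs]
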