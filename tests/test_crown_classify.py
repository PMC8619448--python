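import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orchardmap.crown_classify import (ClassThresholds, TreeClass, build_boxes,
                                       classify_boxes, classify_tree,
                                       compute_thresholds, count_canopy,
                                       tree_table)
from orchardmap.localization import TreeGrid, localize_trees
from orchardmap.segmentation import CanopyMask
from orchardmap.synthetic import OrchardScenario, generate_orchard

from conftest import brute_force_box_count, make_image


def _grid(*centers):
    return TreeGrid(positions=[(0, i, c) for i, c in enumerate(centers)])


class TestBuildBoxes:
    def test_study_geometry_six_pixel_boxes_two_pixel_overlap(self, study_truth):
        """3 m boxes at 0.5 m GSD are 6 px; 2 m spacing leaves a 2 px
        (= 1 m) overlap between in-row neighbors."""
        grid = localize_trees(study_truth.pattern, study_truth.image)
        boxes = build_boxes(grid, 3.0, study_truth.image)
        by_key = {(b.row_index, b.tree_index): b for b in boxes}
        b0, b1 = by_key[(0, 0)], by_key[(0, 1)]
        assert b1.window[3] - b1.window[2] == 6
        assert b1.window[1] - b1.window[0] == 6
        overlap_cols = min(b0.window[3], b1.window[3]) - max(b0.window[2],
                                                             b1.window[2])
        assert overlap_cols == 2
        assert overlap_cols * study_truth.image.resolution == 1.0

    def test_corner_center_clipped(self):
        img = make_image(np.zeros((4, 10, 10)))
        boxes = build_boxes(_grid((0, 0)), 3.0, img)
        r0, r1, c0, c1 = boxes[0].window
        assert (r0, c0) == (0, 0)
        assert boxes[0].area_px < 36

    def test_one_pixel_image(self):
        img = make_image(np.zeros((4, 1, 1)))
        boxes = build_boxes(_grid((0, 0)), 3.0, img)
        assert boxes[0].window == (0, 1, 0, 1)

    def test_nonpositive_diameter(self, small_truth):
        with pytest.raises(ValueError):
            build_boxes(small_truth.centers, 0.0, small_truth.image)


class TestCountCanopy:
    def test_full_and_empty_masks(self):
        img = make_image(np.zeros((4, 20, 20)))
        boxes = build_boxes(_grid((10, 10)), 3.0, img)
        ones = CanopyMask(mask=np.ones((20, 20), np.uint8),
                          nodata_mask=np.zeros((20, 20), bool))
        assert count_canopy(ones, boxes)[0].canopy_pixels == 36
        zeros = CanopyMask(mask=np.zeros((20, 20), np.uint8),
                           nodata_mask=np.zeros((20, 20), bool))
        assert count_canopy(zeros, boxes)[0].canopy_pixels == 0

    def test_overlap_pixels_counted_in_every_box(self):
        img = make_image(np.zeros((4, 12, 20)))
        mask = np.zeros((12, 20), np.uint8)
        mask[4:8, 8:12] = 1  # blob inside the shared strip
        cm = CanopyMask(mask=mask, nodata_mask=np.zeros((12, 20), bool))
        boxes = build_boxes(_grid((6, 8), (6, 12)), 3.0, img)
        count_canopy(cm, boxes)
        total_brute = sum(brute_force_box_count(mask, b.window) for b in boxes)
        assert sum(b.canopy_pixels for b in boxes) == total_brute
        assert total_brute > mask.sum()  # double counting in the overlap

    def test_counts_match_brute_force_on_synthetic_scenes(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            sc = OrchardScenario(n_rows=3, trees_per_row=5,
                                 row_angle=float(rng.uniform(0, 90)),
                                 noise_sd=0.0, seed=100 + trial)
            truth = generate_orchard(sc)
            boxes = build_boxes(truth.centers, 3.0, truth.image)
            count_canopy(truth.canopy_truth, boxes)
            for b in boxes:
                assert b.canopy_pixels == brute_force_box_count(
                    truth.canopy_truth.mask, b.window)

    def test_shape_mismatch(self):
        img = make_image(np.zeros((4, 10, 10)))
        boxes = build_boxes(_grid((9, 9)), 3.0, img)
        small = CanopyMask(mask=np.zeros((5, 5), np.uint8),
                           nodata_mask=np.zeros((5, 5), bool))
        with pytest.raises(ValueError, match="outside"):
            count_canopy(small, boxes)


class TestThresholds:
    def test_worked_example(self):
        th = compute_thresholds([0, 20, 36, 24])
        assert (th.min_value, th.avg_value, th.max_value) == (0, 20, 36)
        assert th.t1 == 4.0
        assert th.t2 == 32.0

    def test_single_count(self):
        with pytest.warns(UserWarning, match="degenerate"):
            th = compute_thresholds([17])
        assert th.min_value == th.avg_value == th.max_value == 17

    def test_all_equal_counts_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            th = compute_thresholds([10, 10, 10])
        assert th.t1 == 12.0 and th.t2 == 8.0 and th.degenerate

    def test_empty_counts(self):
        with pytest.raises(ValueError):
            compute_thresholds([])

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            ClassThresholds(min_value=5, avg_value=2, max_value=10)


class TestClassifyTree:
    TH = ClassThresholds(min_value=0, avg_value=20, max_value=36)

    @pytest.mark.parametrize("count, expected", [
        (0, TreeClass.MISSING_OR_WEAK),
        (3, TreeClass.MISSING_OR_WEAK),
        (4, TreeClass.NORMAL),      # boundary t1 inclusive for class 2
        (24, TreeClass.NORMAL),
        (31, TreeClass.NORMAL),
        (32, TreeClass.BIG),        # boundary t2 inclusive for class 3
        (36, TreeClass.BIG),
    ])
    def test_class_intervals(self, count, expected):
        assert classify_tree(count, self.TH) == expected

    def test_count_outside_parcel_range(self):
        with pytest.raises(ValueError, match="outside"):
            classify_tree(40, self.TH)

    def test_degenerate_thresholds_ordered_rules(self):
        with pytest.warns(UserWarning):
            th = compute_thresholds([10, 10, 10])
        # t1=12 > t2=8; first matching ordered rule wins
        assert classify_tree(10, th) == TreeClass.MISSING_OR_WEAK

    @settings(derandomize=True, max_examples=100)
    @given(counts=st.lists(st.integers(0, 10_000), min_size=2, max_size=60))
    def test_monotone_in_count(self, counts):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            th = compute_thresholds(counts)
        ordered = sorted(set(counts))
        classes = [int(classify_tree(c, th)) for c in ordered]
        assert classes == sorted(classes)

    @settings(derandomize=True, max_examples=60)
    @given(counts=st.lists(st.integers(0, 3_000), min_size=2, max_size=40),
           alpha=st.sampled_from([2, 3, 5, 10]))
    def test_scale_covariance(self, counts, alpha):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            th = compute_thresholds(counts)
            th_s = compute_thresholds([alpha * c for c in counts])
        assert th_s.t1 == pytest.approx(alpha * th.t1)
        assert th_s.t2 == pytest.approx(alpha * th.t2)
        for c in counts:
            assert classify_tree(alpha * c, th_s) == classify_tree(c, th)

    def test_partition_sums_to_tree_count(self, study_truth):
        classes = study_truth.true_classes
        assert sum((classes == k).sum() for k in (1, 2, 3)) == 250


class TestTreeTable:
    def test_columns_and_area(self, small_truth):
        boxes = build_boxes(small_truth.centers, 3.0, small_truth.image)
        count_canopy(small_truth.canopy_truth, boxes)
        classes, _ = classify_boxes(boxes)
        table = tree_table(boxes, classes, small_truth.image)
        assert list(table.columns) == ["tree_id", "row_index", "tree_index",
                                       "px_row", "px_col", "x", "y",
                                       "canopy_pixels", "canopy_m2", "class"]
        np.testing.assert_allclose(table.canopy_m2,
                                   table.canopy_pixels * 0.25)
        assert table["class"].isin([1, 2, 3]).all()
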