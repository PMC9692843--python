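"""Preprocessing contracts: grayscale, thresholding, labelling, augmentation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from testaclust import preprocess as pp
from testaclust import synthetic as syn
from testaclust.errors import EmptyPatchError, InvalidInputError


class TestToGrayscale:
    @pytest.mark.parametrize("pixel,expected", [
        ((1.0, 1.0, 1.0), 1.0),
        ((0.0, 0.0, 0.0), 0.0),
        ((1.0, 0.0, 0.0), 0.299),  # BT.601 red weight
    ])
    def test_luminance_weights(self, pixel, expected):
        raster = np.array(pixel, dtype=float).reshape(1, 1, 3)
        assert pp.to_grayscale(raster)[0, 0] == pytest.approx(expected)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(InvalidInputError):
            pp.to_grayscale(np.zeros((4, 4, 2)))


class TestBinarize:
    def test_boundary_values_at_default_threshold(self):
        gray = np.array([[0.59, 0.60]])
        out = pp.binarize(gray, 0.6)
        assert out[0, 0] == 0 and out[0, 1] == 1

    def test_all_zero_is_background(self):
        assert pp.binarize(np.zeros((3, 3)), 0.6).sum() == 0

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            pp.binarize(np.zeros((2, 2)), 1.5)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_alphabet_is_binary_and_idempotent(self, seed):
        gray = np.random.default_rng(seed).uniform(size=(8, 8))
        out = pp.binarize(gray, 0.6)
        assert set(np.unique(out)) <= {0, 1}
        again = pp.binarize(out.astype(float), 0.5)
        assert np.array_equal(again, out)


class TestLabelComponents:
    def test_corner_touching_merges_under_8_connectivity(self):
        binary = np.zeros((4, 4), dtype=int)
        binary[1, 1] = binary[2, 2] = 1
        _, n8 = pp.label_components(binary, connectivity=8)
        _, n4 = pp.label_components(binary, connectivity=4)
        assert n8 == 1 and n4 == 2

    def test_all_background_gives_zero_components(self):
        labels, count = pp.label_components(np.zeros((5, 5), dtype=int))
        assert count == 0 and labels.sum() == 0

    def test_two_disjoint_blocks(self):
        binary = np.zeros((5, 5), dtype=int)
        binary[0:2, 0:2] = 1
        binary[3:5, 3:5] = 1
        labels, count = pp.label_components(binary, connectivity=8)
        assert count == 2
        areas = sorted(np.bincount(labels.ravel())[1:])
        assert areas == [4, 4]

    def test_non_binary_rejected(self):
        with pytest.raises(InvalidInputError):
            pp.label_components(np.full((2, 2), 3))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_eight_connectivity_never_exceeds_four(self, seed):
        binary = (np.random.default_rng(seed).uniform(size=(12, 12)) > 0.6)
        _, n8 = pp.label_components(binary.astype(int), connectivity=8)
        _, n4 = pp.label_components(binary.astype(int), connectivity=4)
        assert n8 <= n4


class TestMeasureRegions:
    def test_single_block(self):
        binary = np.zeros((5, 5), dtype=int)
        binary[1:3, 1:3] = 1
        labels, _ = pp.label_components(binary)
        table = pp.measure_regions(labels)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["area"] == 4
        assert (row["bbox_r1"] - row["bbox_r0"],
                row["bbox_c1"] - row["bbox_c0"]) == (2, 2)

    def test_empty_label_matrix_gives_empty_table(self):
        table = pp.measure_regions(np.zeros((4, 4), dtype=int))
        assert len(table) == 0
        assert list(table.columns) == pp.REGION_TABLE_COLUMNS

    def test_two_blocks_area_column(self):
        binary = np.zeros((8, 8), dtype=int)
        binary[0:2, 0:2] = 1
        binary[4:7, 4:7] = 1
        labels, _ = pp.label_components(binary)
        areas = sorted(pp.measure_regions(labels)["area"])
        assert areas == [4, 9]

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_region_areas_sum_to_foreground_count(self, seed):
        binary = (np.random.default_rng(seed).uniform(size=(16, 16)) > 0.5)
        labels, _ = pp.label_components(binary.astype(int))
        table = pp.measure_regions(labels)
        assert table["area"].sum() == binary.sum()


class TestColorizeLabels:
    def test_no_components_gives_black(self):
        out = pp.colorize_labels(np.zeros((4, 4), dtype=int))
        assert out.shape == (4, 4, 3) and out.sum() == 0

    def test_distinct_color_per_label(self):
        labels = np.arange(8).reshape(2, 4)  # labels 0..7 -> L = 7
        out = pp.colorize_labels(labels, seed=3)
        colors = {tuple(out[i, j]) for i in range(2) for j in range(4)
                  if labels[i, j] > 0}
        assert len(colors) == 7
        assert tuple(out[0, 0]) == (0.0, 0.0, 0.0)

    def test_deterministic_per_seed(self):
        labels = np.tile(np.arange(4), (3, 1))
        a = pp.colorize_labels(labels, seed=9)
        b = pp.colorize_labels(labels, seed=9)
        assert np.array_equal(a, b)


class TestExtractPatch:
    def test_crops_bright_region_from_frame(self):
        frame = np.zeros((600, 600))
        frame[150:450, 100:400] = 0.9
        patch = pp.extract_patch(frame)
        assert patch.raster.shape == (250, 250)
        assert patch.raster.mean() > 0.8  # filled by the bright region

    def test_full_foreground_is_near_identity(self):
        img = np.full((250, 250), 0.8)
        patch = pp.extract_patch(img)
        assert patch.raster == pytest.approx(img, abs=1e-6)

    def test_blank_image_rejected(self):
        with pytest.raises(EmptyPatchError):
            pp.extract_patch(np.zeros((300, 300)))


class TestAugment:
    def test_draw_bounds_over_1000_draws(self):
        config = pp.AugmentConfig()
        rng = np.random.default_rng(0)
        for _ in range(1000):
            angle, dr, dc = pp.sample_transform(rng, config, side=250)
            assert abs(angle) <= 5.0
            assert abs(dr) <= 2.5 and abs(dc) <= 2.5

    def test_deterministic_and_shape_preserving(self):
        img = syn.generate_image(
            syn.WallClass("U", "granule"),
            syn.default_params(syn.WallClass("U", "granule"), seed=2))
        config = pp.AugmentConfig(seed=77)
        a = pp.augment(img, config)
        b = pp.augment(img, config)
        assert np.array_equal(a.raster, b.raster)
        assert a.raster.shape == img.raster.shape
        assert a.truth == img.truth


class TestShuffleSplit:
    def test_floor_rule_sizes(self):
        items = list(range(100))
        train, test = pp.shuffle_split(items, 0.8, seed=1)
        assert len(train) == 80 and len(test) == 20

    def test_union_preserves_multiset(self):
        items = list("aabbccddee")
        train, test = pp.shuffle_split(items, 0.6, seed=2)
        assert sorted(train + test) == sorted(items)

    def test_same_seed_same_permutation(self):
        items = list(range(30))
        assert pp.shuffle_split(items, 0.5, seed=3) == \
            pp.shuffle_split(items, 0.5, seed=3)

    def test_tiny_input_rejected(self):
        with pytest.raises(InvalidInputError):
            pp.shuffle_split([1], 0.5, seed=0)


class TestVectorize:
    def _rep(self, gray):
        binary = pp.binarize(gray, 0.6)
        labels, _ = pp.label_components(binary)
        return pp.RepresentationSet(
            image_id="t", grayscale=gray, binary=binary, labels=labels,
            colored=pp.colorize_labels(labels),
            region_table=pp.measure_regions(labels))

    def test_grayscale_length_is_downsample_squared(self):
        rep = self._rep(np.random.default_rng(0).uniform(size=(250, 250)))
        assert pp.vectorize(rep, "grayscale").shape == (64 * 64,)

    def test_constant_raster_gives_constant_vector(self):
        rep = self._rep(np.full((250, 250), 0.7))
        vec = pp.vectorize(rep, "grayscale")
        assert np.allclose(vec, 0.7, atol=1e-6)

    def test_colored_empty_gives_zero_vector(self):
        rep = self._rep(np.zeros((50, 50)))
        assert np.array_equal(pp.vectorize(rep, "colored"), np.zeros(10))

    def test_length_depends_only_on_config(self):
        rng = np.random.default_rng(1)
        config = pp.PreprocessConfig(downsample_side=16)
        lengths = set()
        for _ in range(3):
            rep = self._rep(rng.uniform(size=(250, 250)))
            for which in ("grayscale", "threshold"):
                lengths.add(pp.vectorize(rep, which, config).shape)
        assert lengths == {(256,)}

    def test_unknown_representation_rejected(self):
        rep = self._rep(np.zeros((10, 10)))
        with pytest.raises(InvalidInputError):
            pp.vectorize(rep, "rgb")
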