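"""Hysteresis thresholding, size filtering and watershed splitting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp
from skimage.draw import disk

from ciliaquant import (
    HysteresisParams,
    SegmentationConfig,
    hysteresis_segment,
    remove_small_objects,
    resolve_thresholds,
    segment_channel,
    split_touching_objects,
)
from oracles import bfs_hysteresis, filter_small


class TestResolveThresholds:
    def test_absolute_passthrough(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        assert resolve_thresholds(img, HysteresisParams(40, 90, "absolute")) == (40, 90)

    def test_quantiles_of_constant_image(self):
        img = np.full((8, 8), 5.0)
        assert resolve_thresholds(img, HysteresisParams(0.5, 0.99)) == (5.0, 5.0)

    def test_quantiles_match_sorting_oracle(self, rng):
        img = rng.uniform(0, 1000, (64, 64))
        low, high = resolve_thresholds(img, HysteresisParams(0.90, 0.99))
        flat = np.sort(img.ravel())
        # quantile by linear interpolation of the sorted pixels
        for q, got in ((0.90, low), (0.99, high)):
            pos = q * (flat.size - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            expect = flat[lo] + (pos - lo) * (flat[hi] - flat[lo])
            assert got == pytest.approx(expect, rel=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HysteresisParams(1.2, 1.5)
        with pytest.raises(ValueError):
            HysteresisParams(0.9, 0.5)
        with pytest.raises(ValueError):
            resolve_thresholds(np.empty((0, 0)), HysteresisParams(0.1, 0.9))


class TestHysteresis:
    def test_strip_seed_and_attach(self):
        img = np.array([[0, 60, 120, 60, 0]], dtype=float)
        assert hysteresis_segment(img, 50, 100).astype(int).tolist() == [[0, 1, 1, 1, 0]]

    def test_no_seeds_empty_mask(self):
        img = np.full((6, 6), 30.0)
        assert not hysteresis_segment(img, 40, 90).any()

    def test_matches_bfs_oracle(self, rng):
        for _ in range(200):
            img = rng.integers(0, 128, (32, 32)).astype(float)
            assert np.array_equal(
                hysteresis_segment(img, 40, 90), bfs_hysteresis(img, 40, 90)
            )

    def test_equal_thresholds_reduce_to_strict_threshold(self, rng):
        img = rng.integers(0, 100, (24, 24)).astype(float)
        assert np.array_equal(hysteresis_segment(img, 50, 50), img > 50)

    def test_low_above_high_rejected(self):
        with pytest.raises(ValueError):
            hysteresis_segment(np.zeros((4, 4)), 90, 40)

    @given(hnp.arrays(np.int64, (20, 20), elements=st.integers(0, 120)))
    def test_nesting_and_monotonicity(self, img):
        img = img.astype(float)
        hyst = hysteresis_segment(img, 40, 90)
        assert not (np.asarray(img > 90) & ~hyst).any()  # strict(high) subset
        assert not (hyst & ~(img > 40)).any()  # subset of strict(low)
        wider = hysteresis_segment(img, 20, 90)
        assert not (hyst & ~wider).any()  # lowering low only grows
        stricter = hysteresis_segment(img, 40, 110)
        assert not (stricter & ~hyst).any()  # raising high only shrinks


class TestRemoveSmallObjects:
    def test_size_cutoff(self):
        mask = np.zeros((10, 20), bool)
        mask[1, 1:4] = True  # 3 px
        mask[5, 2:12] = True  # 10 px
        out = remove_small_objects(mask, 5)
        assert not out[1, 1:4].any()
        assert out[5, 2:12].all()

    def test_min_area_one_is_identity(self, rng):
        mask = rng.random((16, 16)) > 0.7
        assert np.array_equal(remove_small_objects(mask, 1), mask)

    def test_boundary_size_kept(self):
        mask = np.zeros((5, 10), bool)
        mask[2, 2:7] = True  # exactly 5 px
        assert remove_small_objects(mask, 5).sum() == 5

    def test_matches_labelling_oracle(self, rng):
        for _ in range(20):
            mask = rng.random((24, 24)) > 0.65
            assert np.array_equal(
                remove_small_objects(mask, 4), filter_small(mask, 4)
            )

    def test_idempotent_and_never_grows(self, rng):
        mask = rng.random((32, 32)) > 0.6
        once = remove_small_objects(mask, 6)
        assert once.sum() <= mask.sum()
        assert np.array_equal(remove_small_objects(once, 6), once)


class TestSplitTouchingObjects:
    def test_single_disc_single_label(self):
        m = np.zeros((30, 30), bool)
        rr, cc = disk((15, 15), 8)
        m[rr, cc] = True
        assert split_touching_objects(m, 5).max() == 1

    def test_two_overlapping_discs_split(self):
        m = np.zeros((40, 60), bool)
        rr, cc = disk((20, 24), 8)
        m[rr, cc] = True
        rr, cc = disk((20, 36), 8)
        m[rr, cc] = True
        lab = split_touching_objects(m, 5)
        assert lab.max() == 2
        assert lab[20, 24] != lab[20, 36]

    def test_empty_mask(self):
        assert split_touching_objects(np.zeros((8, 8), bool), 3).max() == 0

    def test_partition_preserves_foreground(self, rng):
        mask = rng.random((48, 48)) > 0.6
        lab = split_touching_objects(mask, 4)
        assert ((lab > 0) == mask).all()

    def test_labels_consecutive(self, rng):
        mask = rng.random((48, 48)) > 0.6
        lab = split_touching_objects(mask, 4)
        present = np.unique(lab[lab > 0])
        assert present.tolist() == list(range(1, lab.max() + 1))

    def test_at_least_one_label_per_component(self, rng):
        from scipy import ndimage as ndi

        mask = rng.random((48, 48)) > 0.7
        _, n_comp = ndi.label(mask, np.ones((3, 3)))
        assert split_touching_objects(mask, 4).max() >= n_comp


class TestSegmentChannel:
    def test_uniform_background_zero_labels(self):
        img = np.full((32, 32), 10.0)
        cfg = SegmentationConfig(hysteresis=HysteresisParams(20, 50, "absolute"))
        assert segment_channel(img, cfg).max() == 0

    def test_deterministic(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        cfg = SegmentationConfig(hysteresis=HysteresisParams(0.95, 0.99))
        assert np.array_equal(segment_channel(img, cfg), segment_channel(img, cfg))

    def test_well_separated_cilia_counted(self, noise_free_config, absolute_segmentation, rng):
        from ciliaquant import max_intensity_projection, render_field

        cilia_cfg, _ = absolute_segmentation
        stack, truth = render_field(noise_free_config, rng)
        img = max_intensity_projection(stack, "ARL13B")
        assert segment_channel(img, cilia_cfg).max() == truth.n_cilia
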