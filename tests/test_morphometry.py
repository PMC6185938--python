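"""Skeleton lengths, region measurements, incidence and field summaries."""

import math

import numpy as np
import pytest

from ciliaquant import (
    compute_incidence,
    measure_objects,
    skeleton_length,
    summarize_field,
)
from ciliaquant.morphometry import FLAG_INCIDENCE_GT_100, FLAG_NO_NUCLEI


def straight_segment(n_px, angle):
    """Mask holding an n-pixel straight segment at 0, 45 or 90 degrees."""
    size = n_px + 4
    mask = np.zeros((size, size), bool)
    for i in range(n_px):
        if angle == 0:
            mask[2, 2 + i] = True
        elif angle == 90:
            mask[2 + i, 2] = True
        elif angle == 45:
            mask[2 + i, 2 + i] = True
    return mask


class TestSkeletonLength:
    @pytest.mark.parametrize(
        "angle,expected",
        [(0, 1.0), (90, 1.0), (45, 10 * math.sqrt(2) * 0.1)],
    )
    def test_straight_segments_exact(self, angle, expected):
        mask = straight_segment(11, angle)
        assert skeleton_length(mask, 0.1) == pytest.approx(expected, rel=1e-12)

    def test_single_pixel_zero_length(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert skeleton_length(mask, 0.1) == 0.0

    def test_l_shaped_path(self):
        # 6 right + 5 down: ~10 unit steps; thinning may cut the corner by
        # one diagonal, so agreement is required within one diagonal step
        mask = np.zeros((10, 10), bool)
        mask[2, 2:8] = True
        mask[2:8, 7] = True
        assert skeleton_length(mask, 1.0) == pytest.approx(10.0, abs=math.sqrt(2))

    def test_scale_equivariance(self, rng):
        mask = straight_segment(9, 45)
        l1 = skeleton_length(mask, 0.1)
        l2 = skeleton_length(mask, 0.3)
        assert l2 == pytest.approx(3 * l1)

    def test_errors(self):
        with pytest.raises(ValueError):
            skeleton_length(np.zeros((4, 4), bool), 0.1)
        two = np.zeros((5, 5), bool)
        two[0, 0] = two[4, 4] = True
        with pytest.raises(ValueError):
            skeleton_length(two, 0.1)

    def test_rendered_cilium_within_tolerance(self, rng):
        """A blurred rendered cilium of known arc length measures within 10%."""
        from ciliaquant import (
            HysteresisParams,
            SegmentationConfig,
            SimulationConfig,
            apply_optics_and_noise,
            rasterize_paths,
            sample_cilium_path,
            segment_channel,
        )

        cfg = SimulationConfig(read_noise_sd=0.0, shot_noise=False)
        path = sample_cilium_path(4.0, cfg.curvature_max, cfg.step_um, rng)
        path = path - path.mean(axis=0) + 4.8
        struct = rasterize_paths((96, 96), [path], 0.1)
        img = apply_optics_and_noise(struct, 400.0, cfg, rng)
        seg = SegmentationConfig(hysteresis=HysteresisParams(150, 250, "absolute"))
        labels = segment_channel(img, seg)
        assert labels.max() == 1
        measured = skeleton_length(labels == 1, 0.1)
        true = float(np.hypot(*np.diff(path, axis=0).T).sum())
        assert measured == pytest.approx(true, rel=0.10)


class TestMeasureObjects:
    def test_constant_segment(self):
        labels = np.zeros((5, 15), int)
        labels[2, 2:13] = 1
        intensity = np.where(labels > 0, 200.0, 7.0)
        (m,) = measure_objects(labels, intensity, 0.1)
        assert m.area_px == 11
        assert m.area_um2 == pytest.approx(11 * 0.01)
        assert m.mean_intensity == 200.0
        assert m.length_um == pytest.approx(1.0)
        assert m.centroid == pytest.approx((2.0, 7.0))

    def test_empty_label_map(self):
        assert measure_objects(np.zeros((4, 4), int), np.zeros((4, 4)), 0.1) == []

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            measure_objects(np.zeros((4, 4), int), np.zeros((5, 5)), 0.1)

    def test_area_and_intensity_match_accumulation_oracle(self, rng):
        from scipy import ndimage as ndi

        mask = rng.random((40, 40)) > 0.8
        labels, n = ndi.label(mask, np.ones((3, 3)))
        intensity = rng.uniform(0, 100, (40, 40))
        results = {m.label: m for m in measure_objects(labels, intensity, 0.1)}
        for lab in range(1, n + 1):
            area = total = 0
            for y in range(40):
                for x in range(40):
                    if labels[y, x] == lab:
                        area += 1
                        total += intensity[y, x]
            assert results[lab].area_px == area
            assert results[lab].mean_intensity == pytest.approx(total / area)

    def test_mean_intensity_within_image_range(self, rng):
        mask = rng.random((32, 32)) > 0.7
        from scipy import ndimage as ndi

        labels, _ = ndi.label(mask, np.ones((3, 3)))
        intensity = rng.uniform(5, 50, (32, 32))
        for m in measure_objects(labels, intensity, 0.1):
            assert intensity.min() <= m.mean_intensity <= intensity.max()

    def test_length_bounded_by_diagonal_traversal(self, rng):
        from scipy import ndimage as ndi

        mask = rng.random((32, 32)) > 0.75
        labels, _ = ndi.label(mask, np.ones((3, 3)))
        for m in measure_objects(labels, np.ones((32, 32)), 0.1):
            assert m.length_um <= m.area_px * 0.1 * math.sqrt(2) + 1e-9


class TestIncidence:
    def test_formula(self):
        assert compute_incidence(30, 100) == pytest.approx(30.0)
        assert compute_incidence(0, 250) == 0.0

    def test_random_ratio_oracle(self, rng):
        for _ in range(50):
            c = int(rng.integers(0, 400))
            n = int(rng.integers(1, 400))
            assert compute_incidence(c, n) == c / n * 100.0

    def test_zero_nuclei_missing(self):
        assert math.isnan(compute_incidence(5, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_incidence(-1, 10)


class TestSummarizeField:
    def _measurement(self, length):
        from ciliaquant import CiliumMeasurement

        return CiliumMeasurement(1, 10, 0.1, length, length, 100.0, (0.0, 0.0))

    def test_mean_and_incidence(self):
        ms = [self._measurement(2.0), self._measurement(4.0)]
        s = summarize_field(ms, 10, "f0")
        assert s.n_cilia == 2
        assert s.mean_length_um == pytest.approx(3.0)
        assert s.incidence_pct == pytest.approx(20.0)
        assert s.qc_flags == ()

    def test_empty_field(self):
        s = summarize_field([], 10, "f0")
        assert s.n_cilia == 0
        assert math.isnan(s.mean_length_um)
        assert s.incidence_pct == 0.0

    def test_no_nuclei_flagged(self):
        s = summarize_field([self._measurement(2.0)], 0, "f0")
        assert math.isnan(s.incidence_pct)
        assert FLAG_NO_NUCLEI in s.qc_flags

    def test_incidence_over_100_flagged_not_clamped(self):
        ms = [self._measurement(2.0) for _ in range(15)]
        s = summarize_field(ms, 10, "f0")
        assert s.incidence_pct == pytest.approx(150.0)
        assert FLAG_INCIDENCE_GT_100 in s.qc_flags
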