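"""Chromosome segmentation, focus enhancement, peak counting, LSD tests."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from tetraco.foci import (
    ROIMask,
    compare_groups_lsd,
    count_foci,
    enhance_foci,
    segment_chromosomes,
)


def gaussian_spot(shape, row, col, amplitude, sigma):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return amplitude * np.exp(-((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma**2))


class TestSegmentChromosomes:
    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="no foreground"):
            segment_chromosomes(np.zeros((64, 64)))
        with pytest.raises(ValueError, match="no foreground"):
            segment_chromosomes(np.full((64, 64), 7.0))

    def test_closing_bridges_one_pixel_gaps(self):
        """Two dashed bright curves come out as two solid components."""
        from skimage.measure import label

        img = np.zeros((80, 80))
        for col in range(10, 70):
            if col % 5 != 0:  # 1-px gaps along each curve
                img[20:23, col] = 1000.0
                img[50:53, col] = 1000.0
        roi = segment_chromosomes(img, closing_radius=2)
        assert label(roi.mask).max() == 2
        assert roi.mask[21, 15] and roi.mask[51, 15]  # gap columns filled

    def test_bright_frame_with_one_dark_pixel_covers_frame(self):
        img = np.full((64, 64), 4000.0)
        img[10, 10] = 0.0
        roi = segment_chromosomes(img)
        assert roi.area >= img.size - 1


class TestEnhanceFoci:
    def test_constant_background_maps_to_zero(self):
        out = enhance_foci(np.full((32, 32), 500.0))
        assert np.allclose(out, 0.0)

    def test_small_radius_rejected(self):
        with pytest.raises(ValueError):
            enhance_foci(np.zeros((8, 8)), tophat_radius=0)

    def test_narrow_spot_amplitude_mostly_preserved(self):
        img = 100.0 + gaussian_spot((64, 64), 30, 30, amplitude=1000.0, sigma=1.5)
        out = enhance_foci(img, tophat_radius=3)
        peak = np.unravel_index(np.argmax(out), out.shape)
        assert peak == (30, 30)
        assert out[30, 30] >= 0.8 * 1000.0

    def test_broad_gradient_flattened(self):
        rr = np.mgrid[0:128, 0:128][0].astype(float)
        out = enhance_foci(rr * 4.0, tophat_radius=3)  # 0..508 ramp
        assert out.max() < 0.05 * 508.0


class TestCountFoci:
    def test_blank_image_counts_zero(self):
        roi = ROIMask(np.ones((32, 32), dtype=bool))
        res = count_foci(np.zeros((32, 32)), roi, peak_threshold=1.0)
        assert res.count == 0 and res.peak_coordinates == ()

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="ROI"):
            count_foci(np.zeros((16, 16)), ROIMask(np.zeros((16, 16), bool)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_foci(np.zeros((16, 16)), ROIMask(np.ones((8, 8), bool)))

    def test_peaks_closer_than_min_separation_merge(self):
        img = np.zeros((32, 32))
        img[10, 10] = 100.0
        img[10, 12] = 90.0
        roi = ROIMask(np.ones((32, 32), bool))
        assert count_foci(img, roi, peak_threshold=50.0, min_separation=3).count == 1
        assert count_foci(img, roi, peak_threshold=50.0, min_separation=1).count == 2

    def test_out_of_roi_peaks_excluded(self):
        img = np.zeros((32, 32))
        img[5, 5] = 100.0
        img[20, 20] = 100.0
        mask = np.zeros((32, 32), bool)
        mask[15:30, 15:30] = True
        res = count_foci(img, ROIMask(mask), peak_threshold=50.0)
        assert res.count == 1
        assert res.peak_coordinates == ((20, 20),)

    def test_raising_threshold_never_increases_count(self):
        rng = np.random.default_rng(4)
        img = rng.normal(100.0, 10.0, size=(64, 64)).clip(min=0)
        roi = ROIMask(np.ones((64, 64), bool))
        counts = [
            count_foci(img, roi, peak_threshold=thr).count
            for thr in np.linspace(90, 150, 13)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_intensity_scale_invariance(self):
        rng = np.random.default_rng(11)
        img = rng.normal(100.0, 10.0, size=(64, 64)).clip(min=0)
        img[20, 20] = 400.0
        roi = ROIMask(np.ones((64, 64), bool))
        a = count_foci(img, roi, peak_threshold=200.0)
        b = count_foci(img * 7.0, roi, peak_threshold=1400.0)
        assert a.count == b.count
        assert a.peak_coordinates == b.peak_coordinates


class TestFisherLSD:
    def test_identical_groups_give_p_one(self):
        out = compare_groups_lsd({"a": [1, 2, 3], "b": [1, 2, 3]})
        row = out.iloc[0]
        assert row["t"] == 0.0 and row["p"] == 1.0

    def test_matches_pooled_mse_oracle(self):
        groups = {"g1": [1, 2, 3], "g2": [4, 5, 6], "g3": [1, 2, 3]}
        out = compare_groups_lsd(groups).set_index(["group1", "group2"])
        # independent evaluation: SSE = 2 per group, MSE = 6/6 = 1, df = 6
        mse, df = 1.0, 6
        t_oracle = (2.0 - 5.0) / math.sqrt(mse * (1 / 3 + 1 / 3))
        p_oracle = 2 * sps.t.sf(abs(t_oracle), df)
        row = out.loc[("g1", "g2")]
        assert row["t"] == pytest.approx(t_oracle)
        assert row["p"] == pytest.approx(p_oracle)
        assert row["df"] == df
        assert out.loc[("g1", "g3")]["p"] == pytest.approx(1.0)

    def test_rejects_underpowered_input(self):
        with pytest.raises(ValueError):
            compare_groups_lsd({"only": [1, 2, 3]})
        with pytest.raises(ValueError):
            compare_groups_lsd({"a": [1, 2], "b": [5]})
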