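"""Fluorescence quantification: exposure, thresholding, rolling ball,
cell masking and puncta segmentation against seeded synthetic images."""

import numpy as np
import pytest

from macnuc import (
    FluorescenceImage,
    PunctaImageParams,
    cell_mask_from_stentorin,
    mean_intensity_in_mask,
    moments_threshold,
    normalize_exposure,
    render_puncta_image,
    rolling_ball_subtract,
    segment_puncta,
)


def _image(seed=0, params=None, **kwargs):
    if params is None:
        params = PunctaImageParams()
    arr, gt = render_puncta_image(params, seed=seed, **kwargs)
    img = FluorescenceImage(
        signal=arr[0], autofluorescence=arr[1],
        pixel_size_um=params.pixel_size_um, exposure_s=params.exposure_s,
    )
    return img, gt


class TestFluorescenceImage:
    def test_mismatched_channels_rejected(self):
        with pytest.raises(ValueError):
            FluorescenceImage(np.zeros((4, 4)), np.zeros((4, 5)), 0.25)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            FluorescenceImage(-np.ones((4, 4)), np.ones((4, 4)), 0.25)

    def test_missing_exposure_rejected(self):
        with pytest.raises(ValueError):
            FluorescenceImage(np.ones((4, 4)), np.ones((4, 4)), 0.25,
                              exposure_s=0.0)


class TestNormalizeExposure:
    def test_scales_both_channels_to_one_second(self):
        img = FluorescenceImage(
            np.full((4, 4), 100.0), np.full((4, 4), 50.0), 0.25, exposure_s=2.0
        )
        out = normalize_exposure(img)
        assert out.exposure_s == 1.0
        np.testing.assert_allclose(out.signal, 50.0)
        np.testing.assert_allclose(out.autofluorescence, 25.0)

    def test_idempotent(self):
        img = FluorescenceImage(
            np.full((4, 4), 100.0), np.full((4, 4), 50.0), 0.25, exposure_s=0.5
        )
        once = normalize_exposure(img)
        twice = normalize_exposure(once)
        np.testing.assert_array_equal(once.signal, twice.signal)


class TestMomentsThreshold:
    def test_two_level_image_threshold_strictly_between(self):
        img = np.full((20, 20), 100.0)
        img[:5, :] = 200.0
        thr = moments_threshold(img)
        assert 100.0 < thr < 200.0

    def test_separates_two_gaussian_modes(self):
        rng = np.random.default_rng(0)
        lo = rng.normal(100, 5, 4000)
        hi = rng.normal(220, 8, 1000)
        img = np.concatenate([lo, hi]).reshape(50, 100)
        thr = moments_threshold(img)
        assert 100 < thr < 220
        accuracy = ((lo < thr).sum() + (hi >= thr).sum()) / 5000
        assert accuracy > 0.95

    def test_insensitive_to_bin_count(self):
        rng = np.random.default_rng(1)
        img = np.concatenate(
            [rng.normal(100, 5, 4000), rng.normal(220, 8, 1000)]
        ).reshape(50, 100)
        t256 = moments_threshold(img, n_bins=256)
        t512 = moments_threshold(img, n_bins=512)
        assert t512 == pytest.approx(t256, abs=(img.max() - img.min()) / 64)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(2)
        img = np.concatenate(
            [rng.normal(100, 5, 2000), rng.normal(220, 8, 500)]
        ).reshape(50, 50)
        t0 = moments_threshold(img)
        t1 = moments_threshold(img + 1000.0)
        assert t1 == pytest.approx(t0 + 1000.0, abs=1e-6)

    def test_matches_exhaustive_moment_preserving_search(self):
        """Brute-force oracle over all 256 candidate thresholds.

        For each candidate split fraction p0, the two output levels that
        match the first two histogram moments are determined; the
        moment-preserving threshold is the candidate that best preserves
        the third moment. The closed-form implementation must agree."""
        rng = np.random.default_rng(3)
        data = np.concatenate(
            [rng.normal(100, 4, 6000), rng.normal(240, 6, 2000)]
        )
        img = data.reshape(80, 100)
        thr = moments_threshold(img, n_bins=256)

        hist, edges = np.histogram(data, bins=256, range=(data.min(), data.max()))
        centers = (edges[:-1] + edges[1:]) / 2.0
        p = hist / hist.sum()
        m1, m2, m3 = (float(np.sum(p * centers**k)) for k in (1, 2, 3))
        var = m2 - m1 * m1
        cum = np.cumsum(p)
        best, best_err = None, np.inf
        for i in range(256):
            p0 = cum[i]
            if not (0 < p0 < 1):
                continue
            d = np.sqrt(var * (1 - p0) / p0)
            z0, z1 = m1 - d, m1 + var / d
            err = abs(p0 * z0**3 + (1 - p0) * z1**3 - m3)
            if err < best_err:
                best_err, best = err, centers[i]
        bin_w = centers[1] - centers[0]
        assert thr == pytest.approx(best, abs=1.5 * bin_w)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            moments_threshold(np.full((5, 5), 7.0))


class TestRollingBall:
    def test_constant_image_maps_to_zero(self):
        out = rolling_ball_subtract(np.full((30, 30), 123.0), 5.0, 1.0)
        np.testing.assert_allclose(out, 0.0)

    def test_output_nonnegative_and_bounded_by_input(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, (40, 40))
        out = rolling_ball_subtract(img, 5.0, 1.0)
        assert (out >= 0).all()
        assert (out <= img + 1e-9).all()

    def test_narrow_spike_preserved(self):
        img = np.full((41, 41), 50.0)
        img[20, 20] = 550.0
        out = rolling_ball_subtract(img, 10.0, 1.0)
        assert out[20, 20] == pytest.approx(500.0, rel=0.05)

    def test_smooth_gradient_mostly_removed(self):
        yy, xx = np.mgrid[0:60, 0:60]
        img = 100.0 + 2.0 * xx  # 2 units/px ramp
        out = rolling_ball_subtract(img, 10.0, 1.0)
        # residual bounded by what a radius-10 ball can miss on this slope
        assert out.max() < 25.0
        assert out.mean() < 10.0

    def test_constant_offset_cancels_exactly(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 100, (30, 30))
        a = rolling_ball_subtract(img, 5.0, 1.0)
        b = rolling_ball_subtract(img + 500.0, 5.0, 1.0)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_subpixel_radius_rejected(self):
        with pytest.raises(ValueError):
            rolling_ball_subtract(np.ones((10, 10)), 0.1, 0.25)
        with pytest.raises(ValueError):
            rolling_ball_subtract(np.ones((10, 10)), -1.0, 0.25)


class TestCellMask:
    def test_recovers_ground_truth_ellipse(self):
        img, gt = _image(seed=4)
        mask = cell_mask_from_stentorin(img.autofluorescence)
        inter = np.logical_and(mask, gt.cell_mask).sum()
        union = np.logical_or(mask, gt.cell_mask).sum()
        assert inter / union > 0.98

    def test_single_component_no_holes(self):
        img, _ = _image(seed=5)
        mask = cell_mask_from_stentorin(img.autofluorescence)
        from scipy import ndimage

        assert ndimage.label(mask)[1] == 1
        filled = ndimage.binary_fill_holes(mask)
        np.testing.assert_array_equal(mask, filled)

    def test_otsu_agrees_on_bimodal_image(self):
        img, gt = _image(seed=6)
        a = cell_mask_from_stentorin(img.autofluorescence, method="moments")
        b = cell_mask_from_stentorin(img.autofluorescence, method="otsu")
        agree = (a == b).mean()
        assert agree > 0.99

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown threshold method"):
            cell_mask_from_stentorin(np.ones((5, 5)), method="mystery")

    def test_constant_channel_rejected(self):
        with pytest.raises(ValueError):
            cell_mask_from_stentorin(np.full((5, 5), 9.0))


class TestMeanIntensity:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        sig = rng.uniform(0, 100, (20, 20))
        mask = rng.random((20, 20)) > 0.5
        expected = sig[mask].sum() / mask.sum()
        assert mean_intensity_in_mask(sig, mask) == pytest.approx(expected)

    def test_shape_mismatch_and_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mean_intensity_in_mask(np.ones((4, 4)), np.ones((4, 5), bool))
        with pytest.raises(ValueError):
            mean_intensity_in_mask(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestSegmentPuncta:
    def test_well_separated_in_range_spots_recovered_exactly(self):
        """Explicit fixture of comfortably in-range spots: exactly n
        detections, each matching a ground-truth centre within 2 px."""
        import pandas as pd

        rng = np.random.default_rng(10)
        ys = [90.0, 90.0, 90.0, 160.0, 160.0, 160.0]
        xs = [110.0, 190.0, 270.0, 110.0, 190.0, 270.0]
        table = pd.DataFrame(
            {"y_px": ys, "x_px": xs,
             "fwhm_um": rng.uniform(1.5, 3.5, 6),
             "amplitude": rng.uniform(5000, 9000, 6)}
        )
        img, gt = _image(seed=0, spot_table=table)
        spots = segment_puncta(img)
        assert len(spots) == len(gt.spots)
        for _, sp in gt.spots.iterrows():
            d = min(
                np.hypot(p.centroid_xy_px[0] - sp.x_px,
                         p.centroid_xy_px[1] - sp.y_px)
                for p in spots
            )
            assert d < 2.0

    def test_default_fixture_recall_and_precision(self):
        """Pooled over seeded default fixtures (separation 6 um > 3 sigma,
        SNR >> 5), recall and precision are both >= 95%."""
        tp = n_gt = n_det = 0
        for seed in range(6):
            img, gt = _image(seed=seed)
            spots = segment_puncta(img)
            n_gt += len(gt.spots)
            n_det += len(spots)
            for _, sp in gt.spots.iterrows():
                d = min(
                    np.hypot(p.centroid_xy_px[0] - sp.x_px,
                             p.centroid_xy_px[1] - sp.y_px)
                    for p in spots
                )
                if d < 3.0:
                    tp += 1
        assert tp / n_gt >= 0.95
        assert tp / n_det >= 0.95

    def test_spec_size_gate_example_04_vs_2um(self):
        """One 0.4 um spot and one 2 um spot: only the 2 um spot is an
        in-gate punctum."""
        import pandas as pd

        table = pd.DataFrame(
            {"y_px": [100.0, 120.0], "x_px": [100.0, 260.0],
             "fwhm_um": [0.4, 2.0], "amplitude": [6000.0, 6000.0]}
        )
        img, _ = _image(seed=1, spot_table=table)
        spots = segment_puncta(img)
        assert len(spots) == 1
        x, y = spots[0].centroid_xy_px
        assert np.hypot(x - 260.0, y - 120.0) < 2.0

    def test_size_gate_excludes_larger_spot(self):
        """Measure the two spots once, then place the gate between their
        equivalent diameters: only the smaller one survives."""
        import pandas as pd

        table = pd.DataFrame(
            {"y_px": [100.0, 120.0], "x_px": [100.0, 260.0],
             "fwhm_um": [1.2, 3.5], "amplitude": [6000.0, 6000.0]}
        )
        img, _ = _image(seed=1, spot_table=table)
        free = sorted(segment_puncta(img),
                      key=lambda p: p.equivalent_diameter_um)
        assert len(free) == 2
        cut = float(np.mean([p.equivalent_diameter_um for p in free]))
        gated = segment_puncta(img, max_d_um=cut)
        assert len(gated) == 1
        assert gated[0].equivalent_diameter_um == pytest.approx(
            free[0].equivalent_diameter_um
        )

    def test_intensity_floor_excludes_dim_spot(self):
        import pandas as pd

        table = pd.DataFrame(
            {"y_px": [100.0, 120.0], "x_px": [100.0, 260.0],
             "fwhm_um": [2.5, 2.5], "amplitude": [1800.0, 4000.0]}
        )
        img, _ = _image(seed=2, spot_table=table)
        free = segment_puncta(img)
        assert len(free) == 2
        bright = max(p.mean_intensity for p in free)
        dim = min(p.mean_intensity for p in free)
        assert dim < 2000.0 < bright
        floored = segment_puncta(img, intensity_floor=2000.0)
        assert len(floored) == 1
        assert floored[0].mean_intensity == pytest.approx(bright)

    def test_constant_background_offset_invariance(self):
        img, _ = _image(seed=3)
        shifted = FluorescenceImage(
            img.signal + 700.0, img.autofluorescence, img.pixel_size_um
        )
        a = segment_puncta(img)
        b = segment_puncta(shifted)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            assert pa.area_um2 == pytest.approx(pb.area_um2)
            assert pa.mean_intensity == pytest.approx(pb.mean_intensity, rel=1e-9)

    def test_blank_image_yields_no_spots(self):
        img = FluorescenceImage(
            np.full((64, 64), 100.0), np.full((64, 64), 100.0), 0.25
        )
        assert segment_puncta(img) == []

    def test_touching_spots_split_by_watershed(self):
        import pandas as pd

        table = pd.DataFrame(
            {"y_px": [128.0, 128.0], "x_px": [170.0, 186.0],
             "fwhm_um": [2.0, 2.0], "amplitude": [7000.0, 7000.0]}
        )
        img, _ = _image(seed=8, spot_table=table)
        spots = segment_puncta(img)
        assert len(spots) == 2
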