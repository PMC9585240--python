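import math

import numpy as np
import pandas as pd
import pytest

from microvns.fiber_morphometry import (
    SegmentationParams,
    classify_size,
    diameter_distance_regression,
    measure_fibers,
    segment_fibers,
    summarize,
)


def _square_boundary(side=100.0):
    return np.array([[0, 0], [side, 0], [side, side], [0, side]], float)


class TestSegmentFibers:
    def test_blank_image_zero_fibers_with_warning(self):
        img = np.full((64, 64), 128, np.uint8)
        with pytest.warns(UserWarning, match="blank"):
            labels = segment_fibers(img)
        assert labels.max() == 0

    def test_multichannel_rejected(self):
        with pytest.raises(ValueError, match="single-channel"):
            segment_fibers(np.zeros((8, 8, 3), np.uint8))

    def test_two_annuli_with_bright_gap_stay_separate(self):
        img = np.full((60, 100), 170, np.uint8)
        yy, xx = np.mgrid[:60, :100]
        for cx in (30, 63):  # 2-px bright gap between rims at x=45..47
            r2 = (xx - cx) ** 2 + (yy - 30) ** 2
            img[r2 <= 15**2] = 40
            img[r2 <= 9**2] = 210
        labels = segment_fibers(
            img, SegmentationParams(min_area_px=10, max_area_px=3000)
        )
        assert labels.max() == 2

    def test_detection_recall_and_precision_on_synthetic(self, small_synthetic):
        from scipy.spatial import cKDTree

        spec, recs, img, boundary, origin = small_synthetic
        labels = segment_fibers(img)
        meas = measure_fibers(labels, spec.pixel_size, boundary, origin)
        t = cKDTree(recs[["x_um", "y_um"]].to_numpy())
        dd, ii = t.query(meas[["x_um", "y_um"]].to_numpy())
        matched = dd < recs["diameter_um"].to_numpy()[ii]
        precision = matched.mean()
        recall = len(set(ii[matched])) / len(recs)
        assert precision >= 0.95
        assert recall >= 0.95

    def test_intensity_rescaling_invariance(self, small_synthetic):
        spec, recs, img, boundary, origin = small_synthetic
        rescaled = (img.astype(float) * 0.6 + 40).astype(np.uint8)
        l1 = segment_fibers(img)
        l2 = segment_fibers(rescaled)
        m1 = measure_fibers(l1, spec.pixel_size, boundary, origin)
        m2 = measure_fibers(l2, spec.pixel_size, boundary, origin)
        assert abs(len(m1) - len(m2)) <= 0.02 * len(m1)
        assert m1["diameter_um"].median() == pytest.approx(
            m2["diameter_um"].median(), abs=spec.pixel_size
        )


class TestMeasureFibers:
    def test_rendered_disk_diameter_within_one_pixel(self):
        img = np.full((101, 101), 170, np.uint8)
        yy, xx = np.mgrid[:101, :101]
        r = 20  # px
        img[(xx - 50) ** 2 + (yy - 50) ** 2 <= r**2] = 40
        labels = segment_fibers(img, SegmentationParams(max_area_px=8000))
        px = 0.5
        meas = measure_fibers(labels, px, _square_boundary(50.5))
        assert len(meas) == 1
        assert meas["diameter_um"].iloc[0] == pytest.approx(2 * r * px, abs=px)

    def test_centered_fiber_distance_equals_radius(self):
        # circular boundary of radius R, one fiber at the center
        th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        R = 40.0
        boundary = np.c_[R * np.cos(th), R * np.sin(th)]
        labels = np.zeros((81, 81), np.int32)
        labels[38:43, 38:43] = 1  # small blob centered at pixel (40, 40)
        meas = measure_fibers(labels, 1.0, boundary, origin=(-40.5, -40.5))
        assert meas["distance_to_epineurium_um"].iloc[0] == pytest.approx(
            R, abs=0.1
        )

    def test_missing_boundary_rejected(self):
        with pytest.raises(ValueError, match="boundary"):
            measure_fibers(np.zeros((4, 4), np.int32), 1.0, None)

    def test_distances_bounded_by_semi_major_axis(self, small_synthetic):
        spec, recs, img, boundary, origin = small_synthetic
        labels = segment_fibers(img)
        meas = measure_fibers(labels, spec.pixel_size, boundary, origin)
        assert (
            meas["distance_to_epineurium_um"] <= max(spec.nerve_semi_axes) + 1e-9
        ).all()


class TestClassifySize:
    def test_all_equal_diameters_all_small_under_median_rule(self):
        rec = pd.DataFrame({"diameter_um": [2.0] * 5})
        out = classify_size(rec, "median")
        assert (out["size_class"] == "small").all()

    def test_strict_inequality_on_integers(self):
        rec = pd.DataFrame({"diameter_um": [1.0, 2.0, 3.0, 4.0, 5.0]})
        out = classify_size(rec, "median")
        assert list(out["size_class"]) == ["small"] * 3 + ["large"] * 2

    def test_numeric_threshold_matches_truth_fraction(self, small_synthetic):
        spec, recs, img, boundary, origin = small_synthetic
        labels = segment_fibers(img)
        meas = measure_fibers(labels, spec.pixel_size, boundary, origin)
        f_meas = (classify_size(meas, 2.98)["size_class"] == "large").mean()
        f_truth = (recs["diameter_um"] > 2.98).mean()
        assert f_meas == pytest.approx(f_truth, abs=0.02)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_size(pd.DataFrame({"diameter_um": []}))


class TestSummarize:
    def test_unit_square_single_fiber_density(self):
        rec = pd.DataFrame(
            {"diameter_um": [0.5], "size_class": ["small"]}
        )
        s = summarize(rec, _square_boundary(1000.0), 1.0)  # 1 mm^2
        assert s.density_per_mm2 == pytest.approx(1.0)
        assert s.nerve_area_um2 == pytest.approx(1e6)

    def test_density_count_consistency(self, small_synthetic):
        spec, recs, img, boundary, origin = small_synthetic
        s = summarize(classify_size(recs), boundary, spec.pixel_size)
        assert s.density_per_mm2 == pytest.approx(
            s.myelinated_count / (s.nerve_area_um2 * 1e-6)
        )
        assert s.nerve_diameter_um == pytest.approx(
            2 * math.sqrt(s.nerve_area_um2 / math.pi)
        )

    def test_perfect_pipeline_preserves_count(self, small_synthetic):
        spec, recs, img, boundary, origin = small_synthetic
        s = summarize(classify_size(recs), boundary, spec.pixel_size)
        assert s.myelinated_count == len(recs)

    def test_degenerate_polygon_rejected(self):
        rec = pd.DataFrame({"diameter_um": [1.0], "size_class": ["small"]})
        bad = np.array([[0, 0], [1, 1], [2, 2]], float)
        with pytest.raises(Exception):
            summarize(rec, bad, 1.0)


class TestRegression:
    def test_collinear_points_exact_slope_zero_ci_width(self):
        x = np.linspace(0, 100, 50)
        rec = pd.DataFrame(
            {"diameter_um": 5.0 - 0.01 * x, "distance_to_epineurium_um": x}
        )
        out = diameter_distance_regression(rec)
        assert out["slope"] == pytest.approx(-0.01, abs=1e-12)
        lo, hi = out["slope_ci95"]
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_zero_distance_variance_rejected(self):
        rec = pd.DataFrame(
            {"diameter_um": [1, 2, 3.0], "distance_to_epineurium_um": [5, 5, 5.0]}
        )
        with pytest.raises(ValueError, match="variance"):
            diameter_distance_regression(rec)

    def test_shuffled_distances_ci_covers_zero(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 150, 800)
        d = np.clip(3.0 - 0.009 * x + rng.normal(0, 1.0, 800), 0.3, None)
        covered = 0
        n_perm = 50
        for _ in range(n_perm):
            rec = pd.DataFrame(
                {"diameter_um": d, "distance_to_epineurium_um": rng.permutation(x)}
            )
            lo, hi = diameter_distance_regression(rec)["slope_ci95"]
            covered += lo <= 0.0 <= hi
        assert covered >= 0.9 * n_perm

    def test_parameter_recovery_through_generator(self):
        from microvns.synthetic_tem import SyntheticNerveSpec, sample_population

        slopes, ses = [], []
        for seed in range(1, 6):
            recs = sample_population(
                SyntheticNerveSpec(seed=seed, target_fiber_count=1000)
            )
            out = diameter_distance_regression(recs)
            slopes.append(out["slope"])
            ses.append(out["stderr"])
        # mean recovered slope within one pooled CI of the requested value
        ci = 2 * np.mean(ses) / math.sqrt(len(slopes))
        assert abs(np.mean(slopes) - (-0.009)) < max(ci, 2 * np.std(slopes))
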