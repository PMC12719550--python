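import numpy as np
import pytest

from spectmcvar import metrics
from spectmcvar.metrics import (CountSeries, calibration_factor,
                                compare_variability, decay_weight,
                                equivalent_scan_time, fit_rc_curve, rc_model,
                                recovery_coefficient, roi_counts, variability)

NEMA_RADII_CM = np.array([1.85, 1.4, 1.1, 0.85, 0.65, 0.5])


class TestROICounts:
    def test_uniform_image(self):
        img = np.full((10, 10, 10), 2.0)
        mask = np.zeros_like(img, dtype=bool)
        mask.ravel()[:100] = True
        assert roi_counts(img, mask) == pytest.approx(200.0)

    def test_linear_in_decay_weight(self, rng):
        img = rng.random((6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.5
        assert roi_counts(img, mask, 2.0) == pytest.approx(
            2.0 * roi_counts(img, mask, 1.0))

    def test_equals_per_voxel_loop(self, rng):
        img = rng.random((5, 5, 5))
        mask = rng.random((5, 5, 5)) > 0.4
        total = 0.0
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    if mask[i, j, k]:
                        total += img[i, j, k]
        assert roi_counts(img, mask) == pytest.approx(total)

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            roi_counts(np.ones((3, 3, 3)), np.zeros((3, 3, 3), dtype=bool))


class TestCalibrationAndRC:
    def test_calibration_arithmetic(self):
        assert calibration_factor(1000.0, 10.0) == pytest.approx(0.01)

    def test_inverse_identity(self):
        cf = calibration_factor(1234.5, 7.7)
        assert cf * 1234.5 == pytest.approx(7.7)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            calibration_factor(0.0, 10.0)

    def test_perfect_reconstruction_gives_100(self):
        assert recovery_coefficient(900.0, 1000.0, 9.0, 10.0) == pytest.approx(100.0)

    def test_global_rescale_invariance(self, rng):
        c_roi, c_bkg = 731.0, 1894.0
        rc1 = recovery_coefficient(c_roi, c_bkg, 9.0, 10.0)
        rc2 = recovery_coefficient(5.5 * c_roi, 5.5 * c_bkg, 9.0, 10.0)
        assert rc1 == pytest.approx(rc2)

    def test_decay_weight_of_one_half_life(self):
        assert decay_weight(metrics.LU177_HALF_LIFE_DAYS) == pytest.approx(2.0)


class TestVariability:
    def test_identical_values_zero(self):
        s = CountSeries("roi", [5.0, 5.0, 5.0])
        assert variability(s) == 0.0

    def test_reference_series(self):
        assert variability(CountSeries("roi", [90.0, 100.0, 110.0])) == \
            pytest.approx(10.0)

    def test_poisson_series_matches_cv_oracle(self, rng):
        lam, n = 1e4, 500
        s = CountSeries("roi", rng.poisson(lam, n).astype(float))
        # CV of Poisson = 1/sqrt(lam) = 1%; SE of the sample CV ~ cv/sqrt(2(n-1))
        se = 100 / np.sqrt(lam) / np.sqrt(2 * (n - 1))
        assert variability(s) == pytest.approx(1.0, abs=3 * se)

    def test_single_measurement_rejected(self):
        with pytest.raises(ValueError):
            variability(CountSeries("roi", [1.0]))


class TestCompareVariability:
    def test_identical_series_limit(self):
        vals = [90.0, 100.0, 110.0, 95.0, 105.0]
        res = compare_variability(CountSeries("r", vals), CountSeries("r", vals))
        assert res.delta == pytest.approx(0.0)
        assert res.speedup == pytest.approx(1.0)
        assert res.u_delta == pytest.approx(0.0, abs=1e-6)
        assert res.u_speedup == pytest.approx(0.0, abs=1e-6)
        assert res.correlation == pytest.approx(1.0)

    def test_delta_is_difference_of_sigmas(self):
        conv = CountSeries("bkg", [77.0, 100.0, 123.0])     # 23.0 percent SD
        mc = CountSeries("bkg", [80.75, 100.0, 119.25])     # 19.25 percent SD
        res = compare_variability(conv, mc)
        assert res.sigma_conv == pytest.approx(23.0)
        assert res.sigma_mc == pytest.approx(19.25)
        assert res.delta == pytest.approx(3.75)

    def test_sf_consistent_with_sigma_ordering(self, rng):
        a = CountSeries("r", rng.normal(100, 20, 40))
        b = CountSeries("r", rng.normal(100, 10, 40))
        res = compare_variability(a, b)
        assert (res.speedup >= 1.0) == (res.sigma_conv >= res.sigma_mc)

    def test_zero_covariance_reduces_to_textbook_forms(self, rng):
        """With independent series the estimators collapse to the
        uncorrelated delta-method expressions."""
        n = 2000
        a = CountSeries("r", rng.normal(100, 20, n))
        b = CountSeries("r", rng.normal(100, 10, n))
        res = compare_variability(a, b)
        s1, s2 = res.sigma_conv / 100, res.sigma_mc / 100
        rho = res.correlation
        u_text = 100 * np.sqrt(
            (s1 ** 2 + s2 ** 2 - 2 * rho ** 2 * s1 * s2) / (2 * (n - 1)))
        assert res.u_delta == pytest.approx(u_text, rel=1e-9)
        assert abs(rho) < 0.1

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_variability(CountSeries("r", [1, 2, 3.0]),
                                CountSeries("r", [1, 2, 3, 4.0]))


class TestEquivalentScanTime:
    def test_speedup_factor_three(self):
        # 15 s/projection at SF = 3 -> 45 s/projection
        sf = 3.0
        assert equivalent_scan_time(15.0, np.sqrt(sf), 1.0) == pytest.approx(45.0)

    def test_equal_variability_same_time(self):
        assert equivalent_scan_time(20.0, 5.0, 5.0) == pytest.approx(20.0)

    def test_inverse_square_law(self):
        assert equivalent_scan_time(10.0, 8.0, 4.0) == pytest.approx(40.0)


class TestRCModel:
    def test_no_blur_limit_is_unity(self):
        # leading correction is ~ 3 w / (sqrt(2 pi) R)
        assert rc_model(1.0, 1.0, 1e-6) == pytest.approx(1.0, abs=1e-5)

    def test_vanishes_for_tiny_spheres(self):
        assert rc_model(1e-3, 1.0, 0.5) < 1e-4

    def test_monotone_nondecreasing_in_radius(self):
        r = np.linspace(0.05, 5.0, 200)
        rc = rc_model(r, 1.26, 0.57)
        assert np.all(np.diff(rc) >= -1e-12)

    def test_asymptote_is_scale_factor(self):
        # approach is linear in w/R, so go far out on the radius axis
        assert rc_model(5e3, 1.26, 0.57) == pytest.approx(1.26, rel=1e-3)
        assert rc_model(5e4, 1.26, 0.57) == pytest.approx(1.26, rel=1e-4)

    def test_matches_numerical_sphere_overlap_integral(self):
        """Independent oracle: numerically average the two-sphere overlap
        volume over a Maxwell-distributed displacement."""
        from scipy.integrate import quad
        R, w = 1.1, 0.57

        def overlap(d):
            return np.pi * (4 * R + d) * (2 * R - d) ** 2 / 12.0

        def maxwell(d):
            return np.sqrt(2 / np.pi) * d ** 2 / w ** 3 * np.exp(-d ** 2 / (2 * w ** 2))

        v_sphere = 4 / 3 * np.pi * R ** 3
        num, _ = quad(lambda d: maxwell(d) * overlap(d), 0, 2 * R)
        assert rc_model(R, 1.0, w) == pytest.approx(num / v_sphere, rel=1e-9)


class TestRCCurveFit:
    def test_recovers_generating_parameters(self):
        s_true, w_true = 1.26, 0.57
        rc = rc_model(NEMA_RADII_CM, s_true, w_true)
        fit = fit_rc_curve(NEMA_RADII_CM, rc)
        assert fit.converged
        assert abs(fit.s - s_true) < 1e-6
        assert abs(fit.w - w_true) < 1e-6
        assert np.max(np.abs(fit.residuals)) < 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_rc_curve([1.0, 2.0], [0.5, 0.6])

    def test_noisy_fit_reports_uncertainties(self, rng):
        rc = rc_model(NEMA_RADII_CM, 1.1, 0.5) + rng.normal(0, 0.01, 6)
        fit = fit_rc_curve(NEMA_RADII_CM, rc)
        assert fit.converged
        assert fit.s_stderr > 0 and fit.w_stderr > 0
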