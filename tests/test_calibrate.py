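"""Calibration: source detection, optical centre, Seidel fitting."""

import numpy as np
import pytest

from ringdecon.calibrate import (build_calibration_image, detect_point_sources,
                                 estimate_optical_center, fit_seidel,
                                 _SeidelFitProblem)
from ringdecon.deblur import SolverConfig
from ringdecon.metrics import rel_l2
from ringdecon.seidel import OpticalGrid, SeidelCoefficients
from ringdecon.synth import NoiseSpec, make_calibration_image

from test_polar import rotate_about_center


class TestDetection:
    def test_all_sources_found_within_one_pixel(self, grid64):
        coeffs = SeidelCoefficients(0.5, 0.5, 0.3, 0.2, 0.0)
        cal, truth = make_calibration_image(coeffs, 15, grid64, seed=2,
                                            min_separation=10, sources="none")
        found = detect_point_sources(cal.image, min_separation=6)
        assert len(found) == 15
        for t in truth:
            d = min(np.hypot(s.row - t.apparent_position[0],
                             s.col - t.apparent_position[1]) for s in found)
            assert d <= 1.0

    def test_empty_image_gives_empty_list(self):
        assert detect_point_sources(np.zeros((64, 64))) == []

    def test_close_pair_keeps_brighter(self):
        img = np.zeros((64, 64))
        img[30, 30] = 1.0
        img[30, 36] = 0.4
        with pytest.warns(UserWarning, match="separation"):
            found = detect_point_sources(img, min_separation=10, smooth_sigma=1.0)
        assert len(found) == 1
        assert abs(found[0].col - 30) < 1.5


class TestOpticalCenter:
    def test_recovers_geometric_center(self, grid64):
        cal, _ = make_calibration_image(SeidelCoefficients(0.3, 0.4, 0.2, 0.1, 0.0),
                                        12, grid64, seed=5, sources="none")
        # the bead pattern itself is not symmetric, so symmetrise it the way a
        # rotationally symmetric system would: add the 180-degree copy
        img = cal.image + rotate_about_center(cal.image, np.pi)
        row, col = estimate_optical_center(img)
        assert abs(row - 31.5) <= 2 and abs(col - 31.5) <= 2

    def test_recovers_shifted_center(self):
        rng = np.random.default_rng(3)
        img = np.zeros((64, 64))
        cy, cx = 36.5, 28.5  # (+5, -3) from the geometric centre
        for _ in range(40):
            dy, dx = rng.uniform(-20, 20, 2)
            r, c = int(round(cy + dy)), int(round(cx + dx))
            r2, c2 = int(round(cy - dy)), int(round(cx - dx))
            if 0 <= r < 64 and 0 <= c < 64 and 0 <= r2 < 64 and 0 <= c2 < 64:
                a = rng.uniform(0.5, 1)
                img[r, c] += a
                img[r2, c2] += a
        row, col = estimate_optical_center(img)
        assert abs(row - cy) <= 2 and abs(col - cx) <= 2

    def test_flat_image_raises(self):
        with pytest.raises(ValueError):
            estimate_optical_center(np.ones((32, 32)))


class TestSeidelFit:
    def test_gradient_matches_finite_differences(self, grid64):
        cal, _ = make_calibration_image(SeidelCoefficients(1.0, 0.5, 0.8, 0.3, 1.2),
                                        6, grid64, seed=11)
        prob = _SeidelFitProblem(cal, grid64, 31, False)
        x = np.array([0.7, 0.4, 0.9, 0.2, 0.8])
        _, grad, _ = prob.loss_grad(x)
        fd = np.zeros(5)
        h = 1e-5
        for k in range(5):
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            fd[k] = (prob.loss_grad(xp)[0] - prob.loss_grad(xm)[0]) / (2 * h)
        assert np.allclose(grad, fd, rtol=1e-5, atol=1e-10)

    def test_zero_aberration_recovery(self, grid64):
        cal, _ = make_calibration_image(SeidelCoefficients(), 10, grid64, seed=7)
        res = fit_seidel(cal, grid64, SolverConfig(seed=0), num_starts=1,
                         max_iters=100)
        assert np.all(np.abs(res.coefficients.as_array()) <= 0.05)

    def test_noiseless_recovery_three_seeds(self, grid64):
        rng = np.random.default_rng(0)
        for trial in range(3):
            arr = rng.uniform(0, 3, 5)
            cal, _ = make_calibration_image(SeidelCoefficients.from_array(arr),
                                            10, grid64, seed=40 + trial)
            res = fit_seidel(cal, grid64, SolverConfig(seed=trial),
                             num_starts=2, max_iters=150)
            assert np.abs(res.coefficients.as_array() - arr).max() <= 0.1

    def test_loss_exact_zero_at_truth(self, grid64):
        arr = np.array([1.9, 0.8, 0.1, 0.05, 2.4])
        cal, _ = make_calibration_image(SeidelCoefficients.from_array(arr), 10,
                                        grid64, seed=100)
        prob = _SeidelFitProblem(cal, grid64, 31, False)
        ref = float(np.sum(cal.image**2))
        assert prob.loss_grad(arr)[0] <= 1e-12 * ref

    def test_rotation_equivariance(self, grid64):
        arr = np.array([0.8, 1.2, 0.6, 0.4, 0.9])
        cal, truth = make_calibration_image(SeidelCoefficients.from_array(arr),
                                            8, grid64, seed=21)
        res0 = fit_seidel(cal, grid64, SolverConfig(seed=0), num_starts=2,
                          max_iters=120)
        # rotate sources and image about the centre by 90 degrees (exact on
        # the pixel grid) and refit
        rot_img = np.rot90(cal.image).copy()
        from ringdecon.calibrate import CalibrationImage, DetectedSource
        rot_sources = [DetectedSource(row=63 - s.col, col=s.row, radius=s.radius,
                                      angle=np.arctan2(-( s.col - 31.5), s.row - 31.5),
                                      amplitude=s.amplitude)
                       for s in cal.sources]
        cal_rot = CalibrationImage(image=rot_img, center=cal.center,
                                   sources=rot_sources)
        res90 = fit_seidel(cal_rot, grid64, SolverConfig(seed=0), num_starts=2,
                           max_iters=120)
        assert np.abs(res90.coefficients.as_array()
                      - res0.coefficients.as_array()).max() <= 0.05

    def test_denoising_property(self, grid64):
        # PSFs regenerated from a fit on noisy data are closer to the clean
        # truth than the raw noisy image is
        arr = np.array([1.2, 0.9, 0.6, 0.5, 0.3])
        noise = NoiseSpec(kind="gaussian", snr_db=-10, seed=3)
        cal_n, _ = make_calibration_image(SeidelCoefficients.from_array(arr), 10,
                                          grid64, noise=noise, seed=33)
        cal_c, _ = make_calibration_image(SeidelCoefficients.from_array(arr), 10,
                                          grid64, seed=33)
        res = fit_seidel(cal_n, grid64, SolverConfig(seed=0), num_starts=2,
                         max_iters=120)
        prob = _SeidelFitProblem(cal_c, grid64, 31, False)
        p_true = prob.model_sensor_psfs(arr)
        p_fit = prob.model_sensor_psfs(res.coefficients.as_array())
        fit_err = rel_l2(p_fit, p_true)
        raw_err = rel_l2(cal_n.image, cal_c.image)
        assert fit_err < raw_err

    def test_no_sources_raises(self, grid64):
        from ringdecon.calibrate import CalibrationImage
        cal = CalibrationImage(image=np.zeros((64, 64)), center=(31.5, 31.5),
                               sources=[])
        with pytest.raises(ValueError):
            fit_seidel(cal, grid64)

    def test_on_axis_only_warns(self, grid64):
        from ringdecon.calibrate import CalibrationImage, DetectedSource
        from ringdecon.seidel import render_psf
        img = render_psf(SeidelCoefficients(sphere=0.5), 0.0, 0.0, grid64)
        cal = CalibrationImage(image=img, center=(31.5, 31.5),
                               sources=[DetectedSource(31.5, 31.5, 0.0, 0.0, 1.0)])
        with pytest.warns(UserWarning, match="on-axis"):
            fit_seidel(cal, grid64, num_starts=1, max_iters=10)
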