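"""Inverse solvers: ring deconvolution, LSI baselines, blind search."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from ringdecon.deblur import (SolverConfig, blind_deconvolve_spherical,
                              iterative_least_squares, ring_deconvolve,
                              standard_deconvolve)
from ringdecon.fourier import lsi_convolve
from ringdecon.lri import RingOperator, ideal_impulse_stack
from ringdecon.metrics import psnr, rel_l2, total_gradient
from ringdecon.seidel import (OpticalGrid, SeidelCoefficients, render_psf,
                              render_radial_psf_stack)


@pytest.fixture(scope="module")
def ring_problem(grid64, smooth64):
    coeffs = SeidelCoefficients(0.0, 1.0, 0.5, 0.5, 0.0)
    op = RingOperator(render_radial_psf_stack(coeffs, grid64, 47))
    g = smooth64 / smooth64.max()
    return g, op.apply(g), op


class TestSolverConfig:
    def test_rejects_bad_settings(self):
        with pytest.raises(ValueError):
            SolverConfig(max_iters=0)
        with pytest.raises(ValueError):
            SolverConfig(tol=0.0)


class TestRingDeconvolve:
    def test_noiseless_self_consistency_gains_3db(self, ring_problem):
        g, f, op = ring_problem
        res = ring_deconvolve(f, op)
        assert psnr(res.estimate, g) >= psnr(f, g) + 3.0

    def test_loss_tail_is_monotone(self, ring_problem):
        g, f, op = ring_problem
        res = ring_deconvolve(f, op)
        tail = res.loss_trace[int(0.9 * len(res.loss_trace)):]
        assert np.all(np.diff(tail) <= 1e-6 * np.abs(tail[:-1]))

    def test_identity_operator_returns_input(self, grid32, smooth32):
        ids = ideal_impulse_stack(grid32, 24)
        op = RingOperator(ids)
        res = ring_deconvolve(op.apply(smooth32), op,
                              SolverConfig(max_iters=150))
        assert rel_l2(res.estimate, smooth32) <= 0.03

    def test_nonnegativity_enforced(self, ring_problem):
        g, f, op = ring_problem
        res = ring_deconvolve(f, op, SolverConfig(max_iters=50))
        assert res.estimate.min() >= 0

    def test_divergent_loss_raises(self):
        f = np.full((8, 8), np.inf)
        with pytest.raises(FloatingPointError):
            iterative_least_squares(f, lambda x: x, lambda x: x,
                                    SolverConfig(max_iters=5))

    def test_two_random_inits_reach_same_loss(self, ring_problem):
        g, f, op = ring_problem
        rng = np.random.default_rng(4)
        cfg = SolverConfig(max_iters=600)
        r1 = ring_deconvolve(f, op, cfg, x0=rng.random(f.shape))
        r2 = ring_deconvolve(f, op, cfg, x0=rng.random(f.shape))
        assert abs(r1.loss_trace[-1] - r2.loss_trace[-1]) <= 0.01 * r1.loss_trace[-1]


class TestStandardDeconvolve:
    @pytest.fixture(scope="class")
    def odd_psf(self):
        psf = np.zeros((63, 63))
        psf[31, 31] = 1.0
        psf = gaussian_filter(psf, 2.0)
        return psf / psf.sum()

    @pytest.fixture(scope="class")
    def band_limited63(self):
        rng = np.random.default_rng(9)
        return gaussian_filter(rng.random((63, 63)), 3.0)

    @pytest.mark.parametrize("method", ["wiener", "richardson_lucy", "iterative_ls"])
    def test_delta_psf_returns_input(self, method, band_limited63):
        delta = np.zeros((63, 63))
        delta[31, 31] = 1.0
        res = standard_deconvolve(band_limited63, delta, method,
                                  SolverConfig(max_iters=30), nsr=1e-12)
        tol = 1e-8 if method == "wiener" else 0.05
        assert rel_l2(res.estimate, band_limited63) <= tol

    def test_wiener_inverts_noiseless_blur(self, odd_psf, band_limited63):
        f = lsi_convolve(band_limited63, odd_psf)
        res = standard_deconvolve(f, odd_psf, "wiener", nsr=1e-12)
        assert rel_l2(res.estimate, band_limited63) <= 1e-3

    def test_richardson_lucy_conserves_flux_every_iteration(
            self, odd_psf, band_limited63):
        f = np.abs(lsi_convolve(band_limited63, odd_psf))
        x = f.copy()
        for _ in range(10):
            res = standard_deconvolve(x, odd_psf, "richardson_lucy",
                                      SolverConfig(max_iters=1))
            assert abs(res.estimate.sum() / f.sum() - 1.0) <= 1e-3
            x = res.estimate

    def test_richardson_lucy_matches_skimage(self, odd_psf, band_limited63):
        # independent cross-check of the multiplicative updates
        from skimage.restoration import richardson_lucy as sk_rl
        f = np.abs(lsi_convolve(band_limited63, odd_psf))
        ours = standard_deconvolve(f, odd_psf, "richardson_lucy",
                                   SolverConfig(max_iters=10)).estimate
        theirs = sk_rl(f, odd_psf, num_iter=10, clip=False)
        # boundary conventions differ (circular vs same-mode); compare interior
        assert rel_l2(ours[10:-10, 10:-10], theirs[10:-10, 10:-10]) <= 0.02

    def test_iterative_ls_agrees_with_wiener_in_noiseless_limit(self):
        # strictly band-limited object and a kernel whose OTF stays well away
        # from zero inside that band
        rng = np.random.default_rng(9)
        obj = gaussian_filter(rng.random((63, 63)), 3.0)
        spec = np.fft.fft2(obj)
        fy = np.fft.fftfreq(63)[:, None]
        fx = np.fft.fftfreq(63)[None, :]
        spec[np.hypot(fy, fx) > 0.12] = 0
        obj = np.fft.ifft2(spec).real
        obj -= obj.min()
        psf = np.zeros((63, 63))
        psf[31, 31] = 1.0
        psf = gaussian_filter(psf, 1.5)
        psf /= psf.sum()
        f = lsi_convolve(obj, psf)
        wiener = standard_deconvolve(f, psf, "wiener", nsr=1e-6).estimate
        ls = standard_deconvolve(
            f, psf, "iterative_ls",
            SolverConfig(max_iters=800, tv_weight=0.0, nonneg=False,
                         tol=1e-14)).estimate
        assert rel_l2(ls, wiener) <= 0.01

    def test_zero_psf_rejected(self, band_limited63):
        with pytest.raises(ValueError):
            standard_deconvolve(band_limited63, np.zeros((63, 63)), "wiener")

    def test_rl_rejects_negative_input(self, odd_psf):
        with pytest.raises(ValueError):
            standard_deconvolve(np.full((63, 63), -1.0), odd_psf,
                                "richardson_lucy")


class TestBlindDeconvolve:
    def test_degenerate_noise_input_stays_finite(self, grid64):
        rng = np.random.default_rng(5)
        f = rng.random((64, 64))
        c, res = blind_deconvolve_spherical(f, grid64, outer_iters=5,
                                            inner_iters=5)
        assert 0.0 <= c <= 3.0
        assert np.all(np.isfinite(res.estimate))

    def test_output_sharper_than_input(self, grid64, phantom64):
        psf = render_psf(SeidelCoefficients(sphere=1.0), 0.0, 0.0, grid64)
        f = np.clip(lsi_convolve(phantom64, psf), 0, None)
        c, res = blind_deconvolve_spherical(f, grid64, outer_iters=15)
        assert total_gradient(res.estimate) > total_gradient(f / f.max())

    def test_sharpness_landscape_prefers_truth_over_underestimate(
            self, grid64, phantom64):
        # the surrogate is monotone through truth from below: deconvolving
        # with the true kernel is sharper than with a 1-wave underestimate
        true_c = 1.5
        psf = render_psf(SeidelCoefficients(sphere=true_c), 0.0, 0.0, grid64)
        f = np.clip(lsi_convolve(phantom64, psf), 0, None)
        fn = f / f.max()

        def sharp(c):
            p = render_psf(SeidelCoefficients(sphere=c), 0.0, 0.0, grid64)
            r = standard_deconvolve(fn, p, "richardson_lucy",
                                    SolverConfig(max_iters=20))
            return total_gradient(r.estimate)

        assert sharp(true_c) > sharp(true_c - 1.0)
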