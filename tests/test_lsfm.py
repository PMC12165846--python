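"""Light-sheet sheet convolution/deconvolution and the (alpha, beta) model."""

import numpy as np
import pytest

from ringdecon.deblur import SolverConfig
from ringdecon.lsfm import (AxialPSFSet, LSFMPSFModel, SheetOperator,
                            fit_lsfm_model, interpolate_psf, lsfm_psf,
                            measure_fwhm, sheet_blur_direct, sheet_convolve,
                            sheet_correlate, sheet_deconvolve, sigma_profile)
from ringdecon.metrics import psnr, rel_l2
from ringdecon.synth import NoiseSpec, make_bead_volume


@pytest.fixture(scope="module")
def model():
    return LSFMPSFModel(alpha=1.5, beta=0.08, kernel_shape=(9, 11, 11))


@pytest.fixture(scope="module")
def sparse_volume(model):
    rng = np.random.default_rng(5)
    g = np.zeros((32, 32, 16))
    idx = rng.integers(0, [32, 32, 16], size=(30, 3))
    g[idx[:, 0], idx[:, 1], idx[:, 2]] = rng.random(30)
    return g


class TestSigmaProfile:
    def test_waist_value(self, model):
        assert sigma_profile(model, 0.0) == pytest.approx(model.alpha)

    def test_sqrt_two_at_inverse_beta(self, model):
        assert sigma_profile(model, 1 / model.beta) == pytest.approx(
            model.alpha * np.sqrt(2))

    def test_beta_zero_is_u_invariant(self):
        m = LSFMPSFModel(alpha=2.0, beta=0.0)
        assert sigma_profile(m, 25.0) == pytest.approx(2.0)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            LSFMPSFModel(alpha=0.0, beta=0.1)
        with pytest.raises(ValueError):
            LSFMPSFModel(alpha=1.0, beta=-0.1)


class TestLsfmPsf:
    def test_beta_zero_gives_identical_kernels(self):
        m = LSFMPSFModel(alpha=1.5, beta=0.0, kernel_shape=(9, 9, 9))
        assert np.allclose(lsfm_psf(m, 0.0), lsfm_psf(m, 20.0))

    def test_axial_second_moment_grows_with_u(self, model):
        kz = model.kernel_shape[2]
        dz = np.arange(kz) - (kz - 1) / 2
        moments = []
        for u in (0.0, 10.0, 20.0, 30.0):
            k = lsfm_psf(model, u)
            prof = k.sum(axis=(0, 1))
            moments.append((prof * dz**2).sum() / prof.sum())
        assert all(b >= a for a, b in zip(moments, moments[1:]))

    def test_flux_non_increasing_with_u(self, model):
        fluxes = [lsfm_psf(model, u).sum() for u in (0.0, 10.0, 20.0, 30.0)]
        assert all(b <= a + 1e-12 for a, b in zip(fluxes, fluxes[1:]))


class TestInterpolatePsf:
    @pytest.fixture(scope="class")
    def psf_set(self, model):
        us = np.array([-10.0, 0.0, 10.0])
        return AxialPSFSet(psfs=[lsfm_psf(model, u) for u in us], u_positions=us)

    def test_exact_at_measured_positions(self, psf_set, model):
        assert np.allclose(interpolate_psf(0.0, psf_set), lsfm_psf(model, 0.0))

    def test_midpoint_is_average(self, psf_set):
        mid = interpolate_psf(5.0, psf_set)
        expected = 0.5 * psf_set.psfs[1] + 0.5 * psf_set.psfs[2]
        assert np.allclose(mid, expected)

    def test_clamps_outside_range(self, psf_set):
        assert np.allclose(interpolate_psf(99.0, psf_set), psf_set.psfs[-1])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            AxialPSFSet(psfs=[], u_positions=np.array([]))


class TestSheetConvolve:
    def test_matches_brute_force_superposition(self, sparse_volume, model):
        f1 = sheet_convolve(sparse_volume, model)
        f2 = sheet_blur_direct(sparse_volume, model)
        assert rel_l2(f1, f2) <= 1e-6

    def test_impulse_places_the_local_kernel(self, model):
        g = np.zeros((32, 32, 16))
        g[20, 16, 8] = 1.0
        out = sheet_convolve(g, model)
        expected = sheet_blur_direct(g, model)
        assert rel_l2(out, expected) <= 1e-10

    def test_beta_zero_equals_3d_fft_convolution(self, sparse_volume):
        m0 = LSFMPSFModel(alpha=1.5, beta=0.0, kernel_shape=(9, 11, 11))
        f = sheet_convolve(sparse_volume, m0)
        ker = lsfm_psf(m0, 0.0)
        emb = np.zeros_like(sparse_volume)
        emb[:9, :11, :11] = ker
        emb = np.roll(emb, (-4, -5, -5), axis=(0, 1, 2))
        ref = np.fft.ifftn(np.fft.fftn(sparse_volume) * np.fft.fftn(emb)).real
        assert rel_l2(f, ref) <= 1e-6

    def test_adjoint_identity(self, model):
        rng = np.random.default_rng(1)
        op = SheetOperator((32, 32, 16), model)
        x = rng.random((32, 32, 16))
        y = rng.random((32, 32, 16))
        lhs = np.vdot(op.apply(x), y)
        rhs = np.vdot(x, op.adjoint(y))
        assert abs(lhs - rhs) <= 1e-10 * abs(lhs)

    def test_kernel_larger_than_volume_rejected(self, model):
        with pytest.raises(ValueError):
            sheet_convolve(np.zeros((16, 8, 8)), model)


class TestSheetDeconvolve:
    def test_noiseless_self_consistency_gains_3db(self, model):
        vol, _ = make_bead_volume(model, 6, (32, 24, 16), seed=4)
        g = vol / vol.max()
        op = SheetOperator(g.shape, model)
        f = op.apply(g)
        res = sheet_deconvolve(f, op, SolverConfig(max_iters=150))
        assert psnr(res.estimate, g) >= psnr(f, g) + 3.0

    def test_beta_zero_matches_standard_3d_deconvolution(self):
        m0 = LSFMPSFModel(alpha=1.5, beta=0.0, kernel_shape=(9, 11, 11))
        vol, _ = make_bead_volume(m0, 5, (24, 24, 16), seed=8, min_separation=6)
        g = vol / vol.max()
        op = SheetOperator(g.shape, m0)
        f = op.apply(g)
        r_sheet = sheet_deconvolve(f, op, SolverConfig(max_iters=120))
        # standard 3D deconvolution: same solver, space-invariant waist kernel
        ker = lsfm_psf(m0, 0.0)
        emb = np.zeros_like(g)
        emb[:9, :11, :11] = ker
        emb = np.roll(emb, (-4, -5, -5), axis=(0, 1, 2))
        khat = np.fft.fftn(emb)
        from ringdecon.deblur import iterative_least_squares
        r_std = iterative_least_squares(
            f,
            lambda x: np.fft.ifftn(np.fft.fftn(x) * khat).real,
            lambda x: np.fft.ifftn(np.fft.fftn(x) * np.conj(khat)).real,
            SolverConfig(max_iters=120))
        assert rel_l2(r_sheet.estimate, r_std.estimate) <= 0.01


class TestModelFit:
    def test_alpha_beta_recovery(self):
        true = LSFMPSFModel(alpha=2.0, beta=0.05, kernel_shape=(11, 11, 13))
        vol, _ = make_bead_volume(true, 8, (48, 32, 24), seed=9)
        fit = fit_lsfm_model(vol, LSFMPSFModel(alpha=1.0, beta=0.2,
                                               kernel_shape=(11, 11, 13)))
        assert abs(fit.alpha - 2.0) / 2.0 <= 0.10
        assert abs(fit.beta - 0.05) / 0.05 <= 0.20

    def test_beta_zero_case(self):
        true = LSFMPSFModel(alpha=1.8, beta=0.0, kernel_shape=(11, 11, 13))
        vol, _ = make_bead_volume(true, 6, (40, 28, 20), seed=10)
        fit = fit_lsfm_model(vol, LSFMPSFModel(alpha=1.0, beta=0.1,
                                               kernel_shape=(11, 11, 13)))
        assert fit.beta <= 0.01

    def test_noisy_recovery_within_twice_tolerance(self):
        true = LSFMPSFModel(alpha=2.0, beta=0.05, kernel_shape=(11, 11, 13))
        vol, _ = make_bead_volume(true, 8, (48, 32, 24),
                                  noise=NoiseSpec(kind="gaussian", snr_db=20,
                                                  seed=2), seed=9)
        fit = fit_lsfm_model(vol, LSFMPSFModel(alpha=1.0, beta=0.2,
                                               kernel_shape=(11, 11, 13)))
        assert abs(fit.alpha - 2.0) / 2.0 <= 0.20
        assert abs(fit.beta - 0.05) / 0.05 <= 0.40

    def test_empty_stack_raises(self):
        with pytest.raises(ValueError):
            fit_lsfm_model(np.zeros((16, 16, 16)))


class TestFwhm:
    def test_gaussian_closed_form(self):
        sigma = 2.0
        zz = np.arange(33) - 16
        vol = np.exp(-0.5 * (zz[None, None, :] / sigma) ** 2) \
            * np.exp(-0.5 * ((zz[:, None, None] / sigma) ** 2
                             + (zz[None, :, None] / sigma) ** 2))
        fwhm = measure_fwhm(vol, (16, 16, 16), axis=2)
        assert fwhm == pytest.approx(2 * sigma * np.sqrt(2 * np.log(2)), rel=0.05)

    def test_invariant_to_intensity_scale(self):
        rng = np.random.default_rng(6)
        zz = np.arange(25) - 12
        vol = np.exp(-0.5 * (zz[None, None, :] / 1.7) ** 2) * np.ones((25, 25, 1))
        a = measure_fwhm(vol, (12, 12, 12), axis=2)
        b = measure_fwhm(vol * 7.3, (12, 12, 12), axis=2)
        assert a == pytest.approx(b)

    def test_raw_axial_fwhm_grows_with_distance_from_waist(self, model):
        vol, pos = make_bead_volume(model, 8, (48, 32, 24), seed=9)
        pairs = []
        for p in pos:
            try:
                pairs.append((abs(p[0] - 23.5), measure_fwhm(vol, p, axis=2)))
            except ValueError:
                continue
        pairs.sort()
        us = np.array([p[0] for p in pairs])
        fw = np.array([p[1] for p in pairs])
        from scipy.stats import spearmanr
        assert spearmanr(us, fw).statistic > 0.8

    def test_edge_peak_raises(self):
        vol = np.ones((8, 8, 8))
        with pytest.raises(ValueError):
            measure_fwhm(vol, (4, 4, 7), axis=2)
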