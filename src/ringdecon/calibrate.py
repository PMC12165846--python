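"""Single-image Seidel calibration from randomly scattered point sources.

Given one image of sparse point emitters (e.g. sub-resolution fluorescent
beads), this module estimates the five primary Seidel coefficients by matching
synthetic pupil-model PSFs to crops around each detected source:

    w_hat = argmin_w  sum_j || crop_j - a_j * PSF(w; H_j, theta_j) - b_j ||^2

with per-source amplitudes ``a_j`` and a shared background solved jointly in
closed form each iteration (nuisance parameters; solving them jointly also
models overlapping flare tails between nearby sources).  The problem is
nonconvex; a small multi-start Adam search with analytic gradients through
the pupil FFT, plus a coarse sweep of the wrap-prone spherical/coma axes,
gives reliable fits.

Geometry note: the fit places each model PSF's *unaberrated* image point at
the position carried by the source record.  When those records are the true
generated positions (the simulation protocol), distortion appears as a tilt
shift of the pattern relative to the record and is fully identifiable.  When
they come from peak detection on a real image, the distortion shift is
already absorbed into the detected positions and cannot be separated from
them — freeze distortion at zero in that case (``freeze_distortion``), which
mirrors how such systems are calibrated in practice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve
from skimage.feature import peak_local_max

from .deblur import SolverConfig
from .seidel import OpticalGrid, SeidelCoefficients, _PupilBasis

__all__ = [
    "DetectedSource",
    "CalibrationImage",
    "SeidelFitResult",
    "detect_point_sources",
    "estimate_optical_center",
    "build_calibration_image",
    "fit_seidel",
    "calibrate",
]


@dataclass(frozen=True)
class DetectedSource:
    """A localized point source in the calibration image."""

    row: float
    col: float
    radius: float
    angle: float
    amplitude: float


@dataclass
class CalibrationImage:
    """A bead image with its optical center and detected sources."""

    image: np.ndarray
    center: tuple[float, float]
    sources: list[DetectedSource]


@dataclass
class SeidelFitResult:
    """Fitted Seidel coefficients with per-source diagnostics."""

    coefficients: SeidelCoefficients
    per_source_residuals: np.ndarray
    loss_trace: np.ndarray
    extra: dict = field(default_factory=dict)


def detect_point_sources(
    image: np.ndarray,
    threshold_sigmas: float = 5.0,
    min_separation: float = 10.0,
    window: int = 9,
    center: tuple[float, float] | None = None,
    smooth_sigma: float = 1.0,
) -> list[DetectedSource]:
    """Local-maximum detection with sub-pixel centroid refinement.

    Peaks must exceed ``background + threshold_sigmas * sigma`` where the
    background and its spread are robust (median / MAD) statistics of the
    smoothed image.  Of any pair closer than ``min_separation`` only the
    brighter survives.  Returned sources are sorted by radius about
    ``center`` (default: geometric center).
    """
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        image = np.clip(image, 0.0, None)
    n0, n1 = image.shape
    if center is None:
        center = ((n0 - 1) / 2.0, (n1 - 1) / 2.0)
    sm = gaussian_filter(image, smooth_sigma) if smooth_sigma > 0 else image
    bg = float(np.median(sm))
    sigma = 1.4826 * float(np.median(np.abs(sm - bg)))
    thr = bg + threshold_sigmas * max(sigma, 1e-12)
    # find every local maximum; the separation contract (keep the brighter of
    # any close pair, with a warning) is applied on refined positions below
    peaks = peak_local_max(sm, min_distance=2, threshold_abs=thr,
                           exclude_border=False)
    sources = []
    hw = window // 2
    for pr, pc in peaks:
        r0, r1 = max(pr - hw, 0), min(pr + hw + 1, n0)
        c0, c1 = max(pc - hw, 0), min(pc + hw + 1, n1)
        patch = np.clip(sm[r0:r1, c0:c1] - bg, 0.0, None)
        tot = patch.sum()
        if tot <= 0:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        row = float((patch * yy).sum() / tot)
        col = float((patch * xx).sum() / tot)
        dy, dx = row - center[0], col - center[1]
        sources.append(DetectedSource(
            row=row, col=col, radius=float(np.hypot(dy, dx)),
            angle=float(np.arctan2(dy, dx)), amplitude=float(image[pr, pc] - bg)))
    # enforce the separation contract on refined positions
    sources.sort(key=lambda s: -s.amplitude)
    kept: list[DetectedSource] = []
    dropped = 0
    for s in sources:
        if all(np.hypot(s.row - k.row, s.col - k.col) >= min_separation for k in kept):
            kept.append(s)
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"dropped {dropped} source(s) closer than the minimum "
                      "separation; kept the brighter of each pair")
    kept.sort(key=lambda s: s.radius)
    return kept


def estimate_optical_center(image: np.ndarray) -> tuple[float, float]:
    """Optical center via the peak of the image's autoconvolution.

    Correlating the image with its 180-degree rotation is the same as
    convolving it with itself; the peak sits at twice the center of symmetry.
    Raises on flat images, where the landscape carries no information.
    """
    image = np.asarray(image, dtype=float)
    if image.std() < 1e-12 * (abs(float(image.mean())) + 1.0):
        raise ValueError("flat image: optical center is undefined")
    ac = fftconvolve(image, image, mode="full")
    pr, pc = np.unravel_index(int(np.argmax(ac)), ac.shape)

    def _parabolic(v, i):
        if 0 < i < len(v) - 1:
            denom = v[i - 1] - 2 * v[i] + v[i + 1]
            if denom < 0:
                return i + 0.5 * (v[i - 1] - v[i + 1]) / denom
        return float(i)

    row2 = _parabolic(ac[:, pc], pr)
    col2 = _parabolic(ac[pr, :], pc)
    return (row2 / 2.0, col2 / 2.0)


def build_calibration_image(
    image: np.ndarray,
    center: tuple[float, float] | str = "auto",
    threshold_sigmas: float = 5.0,
    min_separation: float = 10.0,
    smooth_sigma: float = 1.0,
) -> CalibrationImage:
    """Package a bead image with an estimated center and detected sources."""
    image = np.asarray(image, dtype=float)
    if isinstance(center, str):
        if center == "auto":
            try:
                center = estimate_optical_center(image)
            except ValueError:
                center = ((image.shape[0] - 1) / 2.0, (image.shape[1] - 1) / 2.0)
        elif center == "geometric":
            center = ((image.shape[0] - 1) / 2.0, (image.shape[1] - 1) / 2.0)
        else:
            raise ValueError(f"unknown center mode {center!r}")
    sources = detect_point_sources(image, threshold_sigmas=threshold_sigmas,
                                   min_separation=min_separation,
                                   smooth_sigma=smooth_sigma, center=center)
    return CalibrationImage(image=image, center=center, sources=sources)


# ---------------------------------------------------------------------------
# Seidel fitting
# ---------------------------------------------------------------------------

class _SeidelFitProblem:
    """Loss + analytic gradient of the joint PSF-matching problem.

    The model image is the sum over sources of pupil-model PSFs, each placed
    with its unaberrated point at the position carried by the source record
    and evaluated at that record's field height/angle (so distortion shows up
    as a tilt shift of the pattern relative to the record).  Per-source
    amplitudes and a global background are solved in closed form each
    iteration, which also accounts for overlapping flare tails between
    sources.  The loss is restricted to the union of windows around the
    sources.  The gradient costs two batched FFTs per iteration via the
    adjoint of the pupil transform; by the envelope theorem the closed-form
    nuisances contribute no extra gradient terms.
    """

    def __init__(self, cal: CalibrationImage, grid: OpticalGrid, window: int,
                 freeze_distortion: bool, smooth_sigma: float = 0.0):
        if not cal.sources:
            raise ValueError("no detected sources to fit")
        self.smooth_sigma = float(smooth_sigma)
        if all(s.radius < 2.0 for s in cal.sources):
            warnings.warn("all sources are (near) on-axis; off-axis Seidel "
                          "terms are unconstrained")
        self.grid = grid
        self.freeze_distortion = freeze_distortion
        self.r_max = grid.r_max
        self.l = grid.pupil_samples
        self.basis = _PupilBasis.get(self.l, grid.pupil_fraction)
        if window % 2 == 0:
            window += 1
        self.window = window
        img = np.asarray(cal.image, dtype=float)
        n = img.shape[0]
        if img.shape != (n, n) or n != grid.n:
            raise ValueError(f"image shape {img.shape} does not match grid n={grid.n}")
        self.n = n
        self.s0 = (self.l - n) // 2
        natural = self.l // 2 - self.s0
        self.image = img
        self.center = cal.center
        self.sources = cal.sources
        nsrc = len(cal.sources)
        b = self.basis
        self.bases = np.zeros((5, nsrc, self.l, self.l))
        self.tilts = np.zeros((nsrc, self.l, self.l))
        self.heights = np.zeros(nsrc)
        hw = window // 2
        union = np.zeros((n, n), dtype=bool)
        yy, xx = np.mgrid[:n, :n]
        for j, s in enumerate(cal.sources):
            h = min(s.radius / self.r_max, 1.0)
            ct, st = math.cos(s.angle), math.sin(s.angle)
            q = b.xhat * ct + b.yhat * st
            self.heights[j] = h
            self.bases[0, j] = b.rho4
            self.bases[1, j] = h * b.rho2 * q
            self.bases[2, j] = h * h * q * q
            self.bases[3, j] = h * h * b.rho2
            self.bases[4, j] = h**3 * q
            ty = s.row - natural
            tx = s.col - natural
            # one wave of rho*cos tilt shifts by -2/fraction px
            self.tilts[j] = -(b.fraction * tx / 2.0) * b.xhat \
                - (b.fraction * ty / 2.0) * b.yhat
            union |= (np.abs(yy - s.row) <= hw) & (np.abs(xx - s.col) <= hw)
        self.union = union
        self.n_union = int(union.sum())
        # matched filter: smoothing data and model identically keeps the fit
        # exact at the true coefficients while suppressing white noise
        self.image_s = (gaussian_filter(img, self.smooth_sigma)
                        if self.smooth_sigma > 0 else img)

    def _model_psfs(self, params: np.ndarray):
        """Batched pupil -> PSF evaluation at the current coefficients."""
        w = np.tensordot(params, self.bases, axes=(0, 0)) + self.tilts
        pupil = np.exp(2j * np.pi * w) * self.basis.mask[None]
        e = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(pupil, axes=(1, 2))),
                            axes=(1, 2))
        psf = (e.real**2 + e.imag**2) / self.basis.energy
        return pupil, e, psf

    def model_sensor_psfs(self, params: np.ndarray) -> np.ndarray:
        """Sensor-frame model PSFs (J, n, n) at the given coefficients."""
        params = np.asarray(params, dtype=float).copy()
        if self.freeze_distortion:
            params[4] = 0.0
        sl = slice(self.s0, self.s0 + self.n)
        return self._model_psfs(params)[2][:, sl, sl]

    def loss_grad(self, params: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        """Total loss, its gradient, and per-source residual norms."""
        params = np.asarray(params, dtype=float).copy()
        if self.freeze_distortion:
            params[4] = 0.0
        pupil, e, psf_full = self._model_psfs(params)
        sl = slice(self.s0, self.s0 + self.n)
        p_raw = psf_full[:, sl, sl]
        if self.smooth_sigma > 0:
            p_raw = gaussian_filter(p_raw, sigma=(0, self.smooth_sigma,
                                                  self.smooth_sigma))
        p = p_raw * self.union[None]
        img = self.image_s * self.union
        nsrc = len(self.sources)
        # joint closed-form amplitudes + one global background
        gram = np.empty((nsrc + 1, nsrc + 1))
        gram[:nsrc, :nsrc] = np.einsum("jxy,kxy->jk", p, p, optimize=True)
        s_p = p.sum(axis=(1, 2))
        gram[:nsrc, nsrc] = s_p
        gram[nsrc, :nsrc] = s_p
        gram[nsrc, nsrc] = self.n_union
        rhs = np.empty(nsrc + 1)
        rhs[:nsrc] = np.einsum("jxy,xy->j", p, img, optimize=True)
        rhs[nsrc] = img.sum()
        try:
            coef = np.linalg.solve(gram, rhs)
        except np.linalg.LinAlgError:
            coef = np.linalg.lstsq(gram, rhs, rcond=None)[0]
        a, bg = coef[:nsrc], coef[nsrc]
        model = np.tensordot(a, p, axes=(0, 0)) + bg * self.union
        resid = (img - model) * self.union
        loss = float(np.sum(resid * resid))
        # per-source diagnostic: residual energy in each source's window
        hw = self.window // 2
        per_source = np.zeros(nsrc)
        for j, s in enumerate(self.sources):
            ci, cj = int(round(s.row)), int(round(s.col))
            r0, r1 = max(ci - hw, 0), min(ci + hw + 1, self.n)
            c0, c1 = max(cj - hw, 0), min(cj + hw + 1, self.n)
            per_source[j] = math.sqrt(float(np.sum(resid[r0:r1, c0:c1] ** 2)))
        # dL/dpsf_k = -2 a_k S^T(resid), pushed back through the pupil
        # transform (S is the symmetric matched-filter smoothing)
        back = resid if self.smooth_sigma <= 0 else \
            gaussian_filter(resid, self.smooth_sigma)
        q_full = np.zeros_like(psf_full)
        q_full[:, sl, sl] = (-2.0 * a[:, None, None]) * back[None]
        z = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(q_full * e, axes=(1, 2)),
                                        axes=(1, 2)), axes=(1, 2)) / self.l**2
        y = np.imag(np.conj(z) * pupil) * (-4.0 * np.pi / self.basis.energy)
        grad = np.tensordot(self.bases, y, axes=([1, 2, 3], [0, 1, 2]))
        if self.freeze_distortion:
            grad[4] = 0.0
        return loss, grad, per_source


def fit_seidel(
    cal: CalibrationImage,
    grid: OpticalGrid,
    cfg: SolverConfig | None = None,
    window: int = 31,
    freeze_distortion: bool = False,
    num_starts: int = 3,
    max_iters: int = 200,
    step_size: float = 0.05,
    bounds: tuple[float, float] = (0.0, 3.0),
    smooth_sigma: float = 0.0,
) -> SeidelFitResult:
    """Fit the five primary Seidel coefficients to a calibration image.

    Multi-start projected Adam on the masked-crop matching loss; the best
    final loss wins.  Coefficients are clamped to ``bounds`` (the 0-3 wave
    range of practical systems; this also removes the sphere sign ambiguity
    of intensity-only pupil fitting).  ``cfg.seed`` seeds the extra random
    starts (the first start is always all-zeros).
    """
    cfg = cfg or SolverConfig()
    problem = _SeidelFitProblem(cal, grid, window, freeze_distortion,
                                smooth_sigma=smooth_sigma)
    rng = np.random.default_rng(cfg.seed)
    lo, hi = bounds
    # scale for "converged to numerical zero" decisions
    ref = float(np.sum((problem.image_s * problem.union) ** 2))
    floor = 1e-10 * ref

    def run(x0: np.ndarray, iters: int):
        """Adam run tracking the incumbent (best-so-far) iterate.

        The landscape is nonconvex and the iterations oscillate, so the
        returned coefficients are the best ones seen, and the returned trace
        is the incumbent loss per iteration (non-increasing by construction;
        this is the convergence curve a multi-start solver reports).
        """
        x = np.clip(np.asarray(x0, dtype=float), lo, hi)
        if freeze_distortion:
            x[4] = 0.0
        m = np.zeros(5)
        v = np.zeros(5)
        b1, b2, eps = 0.9, 0.999, 1e-8
        trace = np.empty(iters)
        best_loss = np.inf
        best_x = x.copy()
        best_resids = None
        it = 0
        for it in range(1, iters + 1):
            loss, grad, resids = problem.loss_grad(x)
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite Seidel fitting loss")
            if loss < best_loss:
                best_loss, best_x, best_resids = loss, x.copy(), resids
            trace[it - 1] = best_loss
            if best_loss < floor:
                break
            # short warmup tames the first normalized steps, then linear decay
            lr = step_size * min(1.0, it / 5.0) \
                * (1.0 - 0.9 * (it - 1) / max(iters - 1, 1))
            m = b1 * m + (1 - b1) * grad
            v = b2 * v + (1 - b2) * grad * grad
            x = x - lr * (m / (1 - b1**it)) / (np.sqrt(v / (1 - b2**it)) + eps)
            x = np.clip(x, lo, hi)
            if freeze_distortion:
                x[4] = 0.0
        return best_loss, best_x, trace[:it], best_resids

    starts = [np.zeros(5)]
    for _ in range(max(num_starts - 1, 0)):
        starts.append(rng.uniform(lo, lo + 0.67 * (hi - lo), size=5))
    best = None
    for x0 in starts:
        cand = run(x0, max_iters)
        if best is None or cand[0] < best[0]:
            best = cand
        if best[0] < 1e-8 * ref:
            break
    # escape the wrap-around local minima of intensity-only pupil fitting:
    # sweep the spherical term on a coarse grid at the current solution, then
    # re-polish from the most promising offsets (sphere, then coma)
    for axis in (0, 1):
        if best[0] < 1e-8 * ref:
            break
        sweep = np.arange(lo, hi + 1e-9, 0.25)
        losses = []
        for val in sweep:
            x = best[1].copy()
            x[axis] = val
            losses.append(problem.loss_grad(x)[0])
        order = np.argsort(losses)
        polished = 0
        for idx in order:
            if abs(sweep[idx] - best[1][axis]) < 0.3:
                continue
            x = best[1].copy()
            x[axis] = sweep[idx]
            cand = run(x, max_iters // 2)
            if cand[0] < best[0]:
                best = cand
            polished += 1
            if polished >= 2 or best[0] < 1e-8 * ref:
                break
    _, x, trace, resids = best
    return SeidelFitResult(
        coefficients=SeidelCoefficients.from_array(x),
        per_source_residuals=resids,
        loss_trace=trace,
    )


def calibrate(
    image: np.ndarray,
    grid: OpticalGrid,
    center: tuple[float, float] | str = "auto",
    freeze_distortion: bool = False,
    **fit_kwargs,
) -> SeidelFitResult:
    """End-to-end calibration: center, detection, then the Seidel fit."""
    cal = build_calibration_image(image, center=center)
    result = fit_seidel(cal, grid, freeze_distortion=freeze_distortion, **fit_kwargs)
    result.extra["calibration"] = cal
    return result
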