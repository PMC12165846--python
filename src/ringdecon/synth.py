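"""Seeded synthetic-data generators for calibration and deblurring studies.

Every generator is a pure function of its spec (including the seed), emits no
NaN/Inf, and preserves nonnegativity except under additive Gaussian noise.
Test objects are procedural mixtures of filaments, discs and point scatterers
rather than downloaded photographs, so nothing here needs network access.

SNR convention: ``snr_db = 10*log10(mean signal power / noise variance)`` —
stated explicitly because "-20 dB SNR" is otherwise ambiguous for sparse
images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .calibrate import CalibrationImage, DetectedSource, build_calibration_image
from .lri import RingOperator, true_blur
from .lsfm import LSFMPSFModel, lsfm_psf
from .seidel import OpticalGrid, SeidelCoefficients, centroid_shift, render_psf, \
    render_radial_psf_stack

__all__ = [
    "NoiseSpec",
    "DatasetSpec",
    "sample_seidel_coefficients",
    "add_noise",
    "make_phantom",
    "make_calibration_image",
    "make_blurred_dataset",
    "make_bead_volume",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: additive Gaussian at a target SNR, Poisson, or none."""

    kind: str = "none"
    snr_db: float = 20.0
    photon_scale: float = 1e4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "poisson", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if not self.photon_scale > 0:
            raise ValueError("photon_scale must be positive")


@dataclass(frozen=True)
class DatasetSpec:
    """Specification for a synthetic blurred-image dataset."""

    n_images: int = 5
    image_size: int = 64
    coeff_sampler: str = "uniform"
    coeff_range: tuple[float, float] = (0.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.coeff_sampler not in ("uniform", "perturbed_grid"):
            raise ValueError(f"unknown sampler {self.coeff_sampler!r}")
        lo, hi = self.coeff_range
        if lo < 0 or hi < lo:
            raise ValueError("coeff_range must satisfy 0 <= lo <= hi")


def sample_seidel_coefficients(spec: DatasetSpec) -> list[SeidelCoefficients]:
    """Draw one coefficient set per image.

    ``uniform``: each coefficient i.i.d. uniform on the range. ``perturbed_grid``:
    per-coefficient uniform grid points jittered by seeded noise (10% of the
    grid spacing), clipped back into the range.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.coeff_range
    if spec.coeff_sampler == "uniform":
        draws = rng.uniform(lo, hi, size=(spec.n_images, 5))
    else:
        # one grid per coefficient, shuffled independently, then jittered
        base = np.linspace(lo, hi, spec.n_images)
        draws = np.empty((spec.n_images, 5))
        spacing = (hi - lo) / max(spec.n_images - 1, 1)
        for k in range(5):
            col = rng.permutation(base) + rng.normal(0.0, 0.1 * spacing,
                                                     size=spec.n_images)
            draws[:, k] = np.clip(col, lo, hi)
    return [SeidelCoefficients.from_array(row) for row in draws]


def add_noise(data: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    """Apply the configured noise model (identity for kind='none')."""
    data = np.asarray(data, dtype=float)
    if noise.kind == "none":
        return data.copy()
    rng = np.random.default_rng(noise.seed)
    if noise.kind == "gaussian":
        power = float(np.mean(data**2))
        sigma = math.sqrt(power / 10.0 ** (noise.snr_db / 10.0))
        return data + rng.normal(0.0, sigma, size=data.shape)
    if np.any(data < 0):
        raise ValueError("Poisson noise requires nonnegative input")
    return rng.poisson(noise.photon_scale * data) / noise.photon_scale


def make_phantom(n: int, seed: int = 0, kind: str = "mixed") -> np.ndarray:
    """Procedural test object in [0, 1]: filaments + discs + point scatterers.

    Energy is tapered away from the border so band-limited comparisons are not
    dominated by boundary resampling effects.
    """
    rng = np.random.default_rng(seed)
    img = np.zeros((n, n))
    yy, xx = np.mgrid[:n, :n]
    if kind in ("mixed", "filaments"):
        for _ in range(max(3, n // 16)):
            pos = rng.uniform(0.15 * n, 0.85 * n, size=2)
            ang = rng.uniform(0, 2 * np.pi)
            vel = np.array([np.sin(ang), np.cos(ang)])
            amp = rng.uniform(0.4, 1.0)
            for _ in range(int(0.7 * n)):
                r, c = int(round(pos[0])), int(round(pos[1]))
                if 0 <= r < n and 0 <= c < n:
                    img[r, c] += amp
                ang += rng.normal(0.0, 0.25)
                vel = np.array([np.sin(ang), np.cos(ang)])
                pos = pos + vel
    if kind in ("mixed", "discs"):
        for _ in range(max(2, n // 21)):
            cy, cx = rng.uniform(0.2 * n, 0.8 * n, size=2)
            rad = rng.uniform(0.04 * n, 0.12 * n)
            img[np.hypot(yy - cy, xx - cx) <= rad] += rng.uniform(0.2, 0.6)
    if kind in ("mixed", "points"):
        for _ in range(max(5, n // 6)):
            r, c = rng.integers(int(0.1 * n), int(0.9 * n), size=2)
            img[r, c] += rng.uniform(0.5, 1.5)
    img = gaussian_filter(img, 1.0)
    # smooth border taper (cosine) over ~8% of the side
    m = max(3, int(0.08 * n))
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(m) / m))
    win = np.ones(n)
    win[:m] = ramp
    win[-m:] = ramp[::-1]
    img = img * win[:, None] * win[None, :]
    return img / img.max() if img.max() > 0 else img


@dataclass
class GroundTruthSource:
    """Generator-side record of one synthetic point source."""

    radius: float
    angle: float
    amplitude: float
    position: tuple[float, float]           # unaberrated image point
    apparent_position: tuple[float, float]  # first-order centroid prediction


def make_calibration_image(
    coeffs: SeidelCoefficients,
    num_sources: int,
    grid: OpticalGrid,
    noise: NoiseSpec | None = None,
    min_separation: float = 12.0,
    margin: float = 3.0,
    seed: int = 0,
    sources: str = "truth",
) -> tuple[CalibrationImage, list[GroundTruthSource]]:
    """Render a sparse image of randomly placed point sources.

    Positions are uniform over the sensor square (minus ``margin``) with
    pairwise separation at least ``min_separation`` (rejection sampling);
    amplitudes are uniform in [0.5, 1]; noise is applied last.

    ``sources`` selects what the returned :class:`CalibrationImage` carries:
    ``"truth"`` (the generated unaberrated positions — the simulation
    protocol, which keeps distortion identifiable), ``"detect"`` (run peak
    detection on the final image, as for a real acquisition) or ``"none"``.
    The ground-truth records are returned either way.
    """
    if num_sources < 1:
        raise ValueError("need at least one source")
    rng = np.random.default_rng(seed)
    n = grid.n
    cy, cx = grid.center
    positions: list[tuple[float, float]] = []
    tries = 0
    while len(positions) < num_sources:
        cand = tuple(rng.uniform(margin, n - 1 - margin, size=2))
        if all(np.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_separation
               for p in positions):
            positions.append(cand)
        tries += 1
        if tries > 10_000:
            raise RuntimeError(
                f"could not place {num_sources} sources with separation "
                f"{min_separation} in {tries} rejection-sampling tries")
    img = np.zeros((n, n))
    truth: list[GroundTruthSource] = []
    for (row, col) in positions:
        dy, dx = row - cy, col - cx
        r = float(np.hypot(dy, dx))
        th = float(np.arctan2(dy, dx))
        amp = float(rng.uniform(0.5, 1.0))
        img += amp * render_psf(coeffs, r, th, grid)
        shift = centroid_shift(coeffs, grid.field_height(r))
        truth.append(GroundTruthSource(
            radius=r, angle=th, amplitude=amp, position=(row, col),
            apparent_position=(cy + (r + shift) * math.sin(th),
                               cx + (r + shift) * math.cos(th))))
    if noise is not None:
        img = add_noise(img, noise)
    if sources == "detect":
        cal = build_calibration_image(img, center="geometric",
                                      min_separation=0.6 * min_separation)
    elif sources == "truth":
        recs = [DetectedSource(row=t.position[0], col=t.position[1],
                               radius=t.radius, angle=t.angle,
                               amplitude=t.amplitude) for t in truth]
        recs.sort(key=lambda s: s.radius)
        cal = CalibrationImage(image=img, center=grid.center, sources=recs)
    elif sources == "none":
        cal = CalibrationImage(image=img, center=grid.center, sources=[])
    else:
        raise ValueError(f"unknown sources mode {sources!r}")
    return cal, truth


def make_blurred_dataset(
    source_images: list[np.ndarray],
    spec: DatasetSpec,
    forward: str = "ring",
    num_radii: int | None = None,
) -> list[dict]:
    """Pair each source image with sampled coefficients and a blurred version.

    ``forward='ring'`` uses ring convolution; ``forward='true'`` the
    brute-force superposition oracle.  Each record carries the seeds needed to
    replay it bit-identically.
    """
    if forward not in ("ring", "true"):
        raise ValueError(f"unknown forward model {forward!r}")
    coeff_sets = sample_seidel_coefficients(
        DatasetSpec(n_images=len(source_images), image_size=spec.image_size,
                    coeff_sampler=spec.coeff_sampler,
                    coeff_range=spec.coeff_range, seed=spec.seed))
    records = []
    for idx, (img, coeffs) in enumerate(zip(source_images, coeff_sets)):
        img = np.asarray(img, dtype=float)
        n = img.shape[0]
        grid = OpticalGrid(n=n)
        if forward == "ring":
            k = num_radii or (math.ceil(n * math.sqrt(2) / 2) + 1)
            stack = render_radial_psf_stack(coeffs, grid, k)
            blurred = RingOperator(stack).apply(img)
        else:
            blurred = true_blur(img, coeffs, grid)
        records.append({
            "index": idx,
            "truth": img,
            "blurred": blurred,
            "coefficients": coeffs,
            "forward": forward,
            "seed": spec.seed,
        })
    return records


def make_bead_volume(
    model: LSFMPSFModel,
    n_beads: int,
    shape: tuple[int, int, int],
    noise: NoiseSpec | None = None,
    min_separation: float = 8.0,
    margin: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Sparse fluorescent-bead volume under the light-sheet forward model.

    Beads sit at seeded random voxels with a minimum separation; each
    contributes the model PSF at its focus coordinate ``u`` (measured from the
    waist at the centre of axis 0).  Noise is applied last.
    """
    if n_beads < 1:
        raise ValueError("need at least one bead")
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    kx, ky, kz = model.kernel_shape
    if margin is None:
        margin = max(kx, ky, kz) // 2
    waist = (nx - 1) / 2.0
    positions: list[tuple[int, int, int]] = []
    tries = 0
    while len(positions) < n_beads:
        cand = (int(rng.integers(margin, nx - margin)),
                int(rng.integers(margin, ny - margin)),
                int(rng.integers(margin, nz - margin)))
        if all(np.linalg.norm(np.subtract(cand, p)) >= min_separation
               for p in positions):
            positions.append(cand)
        tries += 1
        if tries > 10_000:
            raise RuntimeError("could not place beads at the requested separation")
    vol = np.zeros(shape)
    for (bx, by, bz) in positions:
        ker = lsfm_psf(model, bx - waist)
        sx = slice(bx - kx // 2, bx - kx // 2 + kx)
        sy = slice(by - ky // 2, by - ky // 2 + ky)
        sz = slice(bz - kz // 2, bz - kz // 2 + kz)
        vol[sx, sy, sz] += ker
    if noise is not None:
        vol = add_noise(vol, noise)
    return vol, positions
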