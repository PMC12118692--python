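"""2D structured-illumination reconstruction of the registered projections.

For each pattern orientation the three phase-stepped frames are transformed
to Fourier space, where a 3x3 linear system is solved per pixel to separate
the zero-order band from the two sidebands.  Sidebands are shifted to their
true position in reciprocal space (sub-pixel exact, via a linear phase ramp
in real space on a 2x upsampled grid), all bands of all orientations are
combined — plain averaging over overlapping OTF supports, or a generalized
Wiener filter — and the result is inverse-transformed.  The final step is
either Wiener apodization or a few iterations of Richardson-Lucy
deconvolution with the effective (band-averaged) PSF.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .frames import FrameSet, PatternParams
from .geometry import OpticalConfig

logger = logging.getLogger(__name__)

__all__ = [
    "BandSet",
    "ReconSettings",
    "ReconResult",
    "SeparationError",
    "ReconstructionError",
    "widefield_projection",
    "separate_bands",
    "shift_band",
    "combine_bands",
    "rl_deconvolve",
    "reconstruct",
    "gaussian_otf",
    "pattern_phase_offset",
]

_ORDERS = (0, 1, -1)


class SeparationError(RuntimeError):
    pass


class ReconstructionError(RuntimeError):
    pass


@dataclass
class BandSet:
    """Separated Fourier bands for one orientation (orders 0, +1, -1)."""

    bands: np.ndarray  # (3, H, W) complex, standard FFT layout
    k_cycles_per_nm: tuple[float, float]
    modulation: float
    pixel_size: float
    condition_number: float
    orders: tuple[int, ...] = _ORDERS


@dataclass(frozen=True)
class ReconSettings:
    """Reconstruction method and its numerical knobs.

    ``wiener_parameter`` is relative to unit-peak OTFs; ``rl_iterations``
    follows the 5-10 range that is typical for this kind of data (default
    5).  ``support_epsilon`` defines the OTF support used for overlap
    averaging and the extended cutoff of the apodization.
    """

    method: str = "wiener"
    wiener_parameter: float = 1e-2
    rl_iterations: int = 5
    apodization: str = "triangle"
    upsample: int = 2
    support_epsilon: float = 1e-3

    def __post_init__(self) -> None:
        if self.method not in ("wiener", "rl"):
            raise ValueError("method must be 'wiener' or 'rl'")
        if self.wiener_parameter <= 0:
            raise ValueError("wiener_parameter must be > 0")
        if self.rl_iterations < 1:
            raise ValueError("rl_iterations must be >= 1")
        if self.apodization not in ("triangle", "cosine", "none"):
            raise ValueError("apodization must be 'triangle', 'cosine' or 'none'")
        if self.upsample not in (1, 2):
            raise ValueError("upsample must be 1 or 2")


@dataclass
class ReconResult:
    reconstruction: np.ndarray
    widefield: np.ndarray
    effective_otf: np.ndarray
    bandsets: list[BandSet]
    settings: ReconSettings
    pixel_size: float  # of the reconstruction grid
    widefield_pixel_size: float
    max_imag_ratio: float = 0.0  # Hermitian-consistency diagnostic


def widefield_projection(frames: FrameSet) -> np.ndarray:
    """Uniform-illumination projection: the sum of all raw frames.

    For equidistant phases spanning one pattern period the sinusoids cancel
    in the sum, leaving the unmodulated projection (times the frame count).
    """
    images = np.asarray(frames.images, dtype=float)
    if images.size == 0 or not np.all(np.isfinite(images)):
        raise ValueError("frame set is empty or contains non-finite frames")
    return images.sum(axis=(0, 1))


def _mixing_matrix(phases: np.ndarray, m: float) -> np.ndarray:
    """M[p, j] = (m/2)^{|j|} exp(i j phi_p) for orders (0, +1, -1)."""
    cols = []
    for j in _ORDERS:
        cols.append((m / 2.0) ** abs(j) * np.exp(1j * j * phases))
    return np.stack(cols, axis=1)


def separate_bands(
    phase_images: np.ndarray,
    phases: np.ndarray,
    modulation: float,
    k_cycles_per_nm: tuple[float, float] = (0.0, 0.0),
    pixel_size: float = 1.0,
    max_condition: float = 1e8,
) -> BandSet:
    """Solve the per-pixel linear system separating the information bands.

    Each phase image's spectrum is a known mixture of the zero-order band
    and the two sidebands; with at least three distinct phases the 3x3
    mixing matrix is inverted and applied pixelwise to the image spectra.
    """
    phase_images = np.asarray(phase_images, dtype=float)
    phases = np.asarray(phases, dtype=float)
    if phase_images.ndim != 3 or phase_images.shape[0] < 3:
        raise ValueError("need at least 3 phase images of identical shape")
    if len(phases) != phase_images.shape[0]:
        raise ValueError("one phase per image required")

    m_mat = _mixing_matrix(phases, modulation)
    cond = float(np.linalg.cond(m_mat))
    if not np.isfinite(cond) or cond > max_condition:
        raise SeparationError(
            f"degenerate phase set: mixing-matrix condition number {cond:.3g}"
        )
    inv = np.linalg.pinv(m_mat)
    spectra = np.fft.fft2(phase_images, axes=(-2, -1))
    bands = np.einsum("jp,phw->jhw", inv, spectra)
    return BandSet(bands, tuple(k_cycles_per_nm), modulation, pixel_size, cond)


def _upsample_spectrum(spectrum: np.ndarray, factor: int) -> np.ndarray:
    """Zero-pad a standard-layout spectrum onto a ``factor``x finer grid."""
    if factor == 1:
        return spectrum.copy()
    h, w = spectrum.shape
    hf, wf = h * factor, w * factor
    sh = np.fft.fftshift(spectrum).copy()
    # zero the unpaired Nyquist row/column of even-sized grids: embedding
    # them asymmetrically would break Hermitian symmetry of real content
    if h % 2 == 0:
        sh[0, :] = 0.0
    if w % 2 == 0:
        sh[:, 0] = 0.0
    out = np.zeros((hf, wf), dtype=complex)
    y0, x0 = (hf - h) // 2, (wf - w) // 2
    out[y0 : y0 + h, x0 : x0 + w] = sh
    return np.fft.ifftshift(out) * factor**2


def shift_band(
    band: np.ndarray,
    k_shift: tuple[float, float],
    pixel_size: float,
    upsample: int = 2,
) -> np.ndarray:
    """Translate a band by ``k_shift`` (cycles/nm) in reciprocal space.

    The band is embedded in an ``upsample``-times finer grid and multiplied
    by a linear phase ramp in real space, which shifts the spectrum by
    exactly ``k_shift`` (no interpolation).  Shifts beyond the upsampled
    Nyquist frequency alias and are rejected.
    """
    kx, ky = k_shift
    pitch_fine = pixel_size / upsample
    if math.hypot(kx, ky) >= 1.0 / (2.0 * pitch_fine):
        raise ValueError(
            f"band shift |k|={math.hypot(kx, ky):.4g} cycles/nm exceeds the "
            f"upsampled Nyquist {1.0 / (2 * pitch_fine):.4g} cycles/nm"
        )
    fine = _upsample_spectrum(np.asarray(band, dtype=complex), upsample)
    if kx == 0.0 and ky == 0.0:
        return fine
    real = np.fft.ifft2(fine)
    hy, wx = fine.shape
    jy = np.arange(hy)[:, None]
    jx = np.arange(wx)[None, :]
    # C(f) = B(f + k)  <=>  multiply by exp(-2 pi i k . r) on the index grid
    ramp = np.exp(-2j * np.pi * pitch_fine * (kx * jx + ky * jy))
    return np.fft.fft2(real * ramp)


def gaussian_otf(
    shape: tuple[int, int],
    pixel_size: float,
    psf_sigma_nm: float,
    k_offset: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Unit-peak Gaussian OTF sampled on the FFT frequency grid.

    ``k_offset`` (cycles/nm) evaluates the OTF at ``f + k``, i.e. the OTF
    of a sideband after shifting.
    """
    fy = np.fft.fftfreq(shape[0], d=pixel_size)[:, None]
    fx = np.fft.fftfreq(shape[1], d=pixel_size)[None, :]
    f2 = (fx + k_offset[0]) ** 2 + (fy + k_offset[1]) ** 2
    return np.exp(-2.0 * np.pi**2 * psf_sigma_nm**2 * f2)


def _apodization(
    shape: tuple[int, int], pixel_size: float, cutoff: float, kind: str
) -> np.ndarray:
    if kind == "none":
        return np.ones(shape)
    fy = np.fft.fftfreq(shape[0], d=pixel_size)[:, None]
    fx = np.fft.fftfreq(shape[1], d=pixel_size)[None, :]
    fr = np.sqrt(fx**2 + fy**2)
    if kind == "triangle":
        return np.clip(1.0 - fr / cutoff, 0.0, 1.0)
    if kind == "cosine":
        return np.where(fr < cutoff, np.cos(0.5 * np.pi * fr / cutoff), 0.0)
    raise ValueError(f"unknown apodization {kind!r}")


def combine_bands(
    bands: list[np.ndarray],
    otfs: list[np.ndarray],
    settings: ReconSettings,
    pixel_size: float,
    extended_cutoff: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Merge shifted bands of all orientations in reciprocal space.

    Plain combination averages bands wherever several OTF supports overlap
    (sum divided by the local support count); the Wiener path computes the
    generalized-Wiener combination
    ``sum(OTF_i * band_i) / (sum |OTF_i|^2 + w)`` followed by apodization
    to the extended cutoff.  Returns the combined spectrum and the
    support-averaged effective OTF.
    """
    if len(bands) != len(otfs) or not bands:
        raise ValueError("need matching non-empty band and OTF lists")
    shape = bands[0].shape
    for b, o in zip(bands, otfs):
        if b.shape != shape or o.shape != shape:
            raise ValueError("all bands and OTFs must share one grid")

    eps = settings.support_epsilon
    supports = [o > eps for o in otfs]
    count = np.sum(supports, axis=0)
    safe = np.maximum(count, 1)

    eff_otf = np.zeros(shape)
    for o, s in zip(otfs, supports):
        eff_otf += np.where(s, o, 0.0)
    eff_otf = eff_otf / safe

    if settings.method == "wiener":
        num = np.zeros(shape, dtype=complex)
        den = np.full(shape, settings.wiener_parameter)
        for b, o in zip(bands, otfs):
            num += o * b
            den += o**2
        combined = num / den
        if extended_cutoff is not None:
            combined = combined * _apodization(
                shape, pixel_size, extended_cutoff, settings.apodization
            )
    else:
        combined = np.zeros(shape, dtype=complex)
        for b, s in zip(bands, supports):
            combined += np.where(s, b, 0.0)
        combined = combined / safe
    return combined, eff_otf


def rl_deconvolve(
    image: np.ndarray, psf: np.ndarray, n_iterations: int = 5, eps: float = 1e-12
) -> np.ndarray:
    """Richardson-Lucy deconvolution (multiplicative update).

    Negative input pixels are clipped to zero (the clipped fraction is
    logged); the PSF is normalized to unit sum.  The output is non-negative
    and conserves interior flux.
    """
    psf = np.asarray(psf, dtype=float)
    if psf.sum() <= 0:
        raise ValueError("PSF must have positive total")
    psf = psf / psf.sum()
    psf_flip = psf[::-1, ::-1]

    image = np.asarray(image, dtype=float)
    neg = image < 0
    if neg.any():
        frac = float(neg.mean())
        logger.info("rl_deconvolve: clipped %.2f%% negative pixels", 100 * frac)
        image = np.clip(image, 0.0, None)

    est = np.full_like(image, max(image.mean(), eps))
    for _ in range(n_iterations):
        blurred = fftconvolve(est, psf, mode="same")
        ratio = image / np.maximum(blurred, eps)
        est = est * fftconvolve(ratio, psf_flip, mode="same")
    return est


def pattern_phase_offset(
    k_cycles_per_nm: tuple[float, float], shape: tuple[int, int], pixel_size: float
) -> float:
    """Phase correction between center-origin pattern phases and the FFT grid.

    Pattern phases are defined with lateral coordinates centered on the
    image; the FFT places its origin at pixel (0, 0).  The separation
    matrix must use the phase as seen from the FFT origin, which differs by
    ``-2 pi k . r_center``.
    """
    kx, ky = k_cycles_per_nm
    h, w = shape
    return -2.0 * np.pi * pixel_size * (kx * (w - 1) / 2.0 + ky * (h - 1) / 2.0)


def _support_radius(psf_sigma_nm: float, eps: float) -> float:
    """Frequency (cycles/nm) where the unit-peak Gaussian OTF falls to eps."""
    return math.sqrt(math.log(1.0 / eps) / (2.0 * np.pi**2 * psf_sigma_nm**2))


def reconstruct(
    frames: FrameSet,
    optics: OpticalConfig | None = None,
    settings: ReconSettings | None = None,
) -> ReconResult:
    """Full SIM reconstruction of a registered frame set.

    Pipeline: per-orientation band separation -> sideband shifting on the
    upsampled grid -> band combination (Wiener with apodization, or plain
    overlap averaging followed by Richardson-Lucy deconvolution with the
    effective PSF) -> inverse transform.
    """
    optics = optics or OpticalConfig()
    settings = settings or ReconSettings()
    if not frames.registered:
        raise ReconstructionError(
            "frames must be registered to the common frame before reconstruction"
        )
    if not frames.patterns:
        raise ReconstructionError("frame set carries no pattern metadata")

    pixel = frames.pixel_size
    h, w = frames.frame_shape
    u = settings.upsample
    fine_shape = (h * u, w * u)
    pitch_fine = pixel / u
    sigma = optics.psf_sigma

    widefield = widefield_projection(frames)

    all_bands: list[np.ndarray] = []
    all_otfs: list[np.ndarray] = []
    bandsets: list[BandSet] = []
    kmax = 0.0
    for i, pattern in enumerate(frames.patterns):
        k = pattern.k_lateral
        kmax = max(kmax, math.hypot(*k))
        offset = pattern_phase_offset(k, (h, w), pixel)
        phases = np.asarray(pattern.phases) + offset
        bs = separate_bands(
            frames.images[i], phases, pattern.modulation_depth, k, pixel
        )
        bandsets.append(bs)
        for order, band in zip(bs.orders, bs.bands):
            kj = (order * k[0], order * k[1])
            all_bands.append(shift_band(band, kj, pixel, u))
            all_otfs.append(gaussian_otf(fine_shape, pitch_fine, sigma, kj))

    cutoff = _support_radius(sigma, settings.support_epsilon) + kmax
    combined, eff_otf = combine_bands(
        all_bands, all_otfs, settings, pitch_fine, extended_cutoff=cutoff
    )

    spatial = np.fft.ifft2(combined)
    imag_ratio = np.abs(spatial.imag).max() / max(np.abs(spatial.real).max(), 1e-30)
    if imag_ratio > 1e-3:
        logger.warning("combined spectrum not Hermitian: imag/real = %.3g", imag_ratio)
    recon = spatial.real

    if settings.method == "rl":
        psf_eff = np.fft.fftshift(np.fft.ifft2(eff_otf).real)
        psf_eff = np.clip(psf_eff, 0.0, None)
        recon = rl_deconvolve(recon, psf_eff, settings.rl_iterations)

    return ReconResult(
        reconstruction=recon,
        widefield=widefield,
        effective_otf=eff_otf,
        bandsets=bandsets,
        settings=settings,
        pixel_size=pitch_fine,
        widefield_pixel_size=pixel,
        max_imag_ratio=float(imag_ratio),
    )
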