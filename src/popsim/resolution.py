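"""Resolution quantification: bead detection, FWHM statistics, decorrelation.

The operational resolution metric is the full width at half maximum of
isolated bead images, obtained from 2D elliptical Gaussian fits
(FWHM = 2 sqrt(2 ln 2) sigma per axis).  A complementary parameter-free
estimate is provided by image decorrelation analysis, which locates the
highest spatial frequency at which the image spectrum still correlates
with its phase-normalized (whitened) copy under low-pass masking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize


__all__ = [
    "ResolutionReport",
    "AnalysisError",
    "detect_beads",
    "fwhm_stats",
    "decorrelation_resolution",
    "two_frame_average",
    "FWHM_PER_SIGMA",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

BEAD_COLUMNS = ["x_nm", "y_nm", "fwhm_x_nm", "fwhm_y_nm", "residual", "amplitude"]


class AnalysisError(RuntimeError):
    pass


@dataclass
class ResolutionReport:
    """Mean +/- sd of bead FWHM along x and y, with provenance."""

    mean_fwhm_x: float
    sd_fwhm_x: float
    mean_fwhm_y: float
    sd_fwhm_y: float
    n: int
    n_excluded: int = 0
    decorrelation_nm: float | None = None
    method: str = "gaussian-fit"
    beads: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise AnalysisError("resolution report requires at least one bead")
        if self.sd_fwhm_x < 0 or self.sd_fwhm_y < 0:
            raise ValueError("standard deviations must be >= 0")
        for v in (self.mean_fwhm_x, self.mean_fwhm_y):
            if not 50.0 <= v <= 2000.0:
                warnings.warn(
                    f"mean FWHM {v:.0f} nm outside the plausible 50-2000 nm range",
                    stacklevel=2,
                )

    @property
    def mean_fwhm(self) -> float:
        return 0.5 * (self.mean_fwhm_x + self.mean_fwhm_y)

    def to_dict(self) -> dict:
        return {
            "mean_fwhm_x_nm": self.mean_fwhm_x,
            "sd_fwhm_x_nm": self.sd_fwhm_x,
            "mean_fwhm_y_nm": self.mean_fwhm_y,
            "sd_fwhm_y_nm": self.sd_fwhm_y,
            "n": self.n,
            "n_excluded": self.n_excluded,
            "decorrelation_nm": self.decorrelation_nm,
            "method": self.method,
        }


def detect_beads(
    image: np.ndarray,
    pixel_size: float,
    min_separation: float = 1000.0,
    threshold: float | None = None,
    exclude_border_px: int = 3,
) -> np.ndarray:
    """Local-maximum bead candidates, centroid-refined to sub-pixel.

    The default threshold is ``median + 5 * MAD`` (with a small relative floor); peaks closer than
    ``min_separation`` (nm) keep only the brighter one (non-maximum
    suppression).  Returns an (N, 2) array of (row, col) positions in
    (fractional) pixels; empty when nothing exceeds the threshold.
    """
    image = np.asarray(image, dtype=float)
    if image.std() == 0:
        return np.empty((0, 2))
    if threshold is None:
        med = np.median(image)
        mad = np.median(np.abs(image - med))
        # the relative floor guards against a degenerate MAD on sparse,
        # mostly-background (e.g. noiseless) images
        threshold = max(med + 5.0 * 1.4826 * mad, med + 0.02 * (image.max() - med))
    sep_px = max(int(round(min_separation / pixel_size)), 1)

    footprint = np.ones((2 * sep_px + 1, 2 * sep_px + 1), dtype=bool)
    local_max = (ndimage.maximum_filter(image, footprint=footprint) == image) & (
        image > threshold
    )
    if exclude_border_px:
        local_max[:exclude_border_px, :] = False
        local_max[-exclude_border_px:, :] = False
        local_max[:, :exclude_border_px] = False
        local_max[:, -exclude_border_px:] = False
    peaks = np.argwhere(local_max)
    if len(peaks) == 0:
        return np.empty((0, 2))

    # order by brightness so NMS ties resolve towards the stronger peak
    order = np.argsort(-image[peaks[:, 0], peaks[:, 1]])
    peaks = peaks[order]
    kept: list[np.ndarray] = []
    for p in peaks:
        if all(np.hypot(*(p - q)) >= sep_px for q in kept):
            kept.append(p)

    # sub-pixel refinement by local background-subtracted centroid
    refined = []
    r = max(2, sep_px // 2)
    ny, nx = image.shape
    for p in kept:
        y0, y1 = max(p[0] - r, 0), min(p[0] + r + 1, ny)
        x0, x1 = max(p[1] - r, 0), min(p[1] + r + 1, nx)
        win = image[y0:y1, x0:x1] - threshold
        win = np.clip(win, 0.0, None)
        total = win.sum()
        if total <= 0:
            refined.append(p.astype(float))
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        refined.append(np.array([(yy * win).sum() / total, (xx * win).sum() / total]))
    return np.asarray(refined)


def _gauss2d(coords, amp, x0, y0, sx, sy, offset):
    x, y = coords
    return (
        amp * np.exp(-((x - x0) ** 2 / (2 * sx**2) + (y - y0) ** 2 / (2 * sy**2)))
        + offset
    )


def fwhm_stats(
    image: np.ndarray,
    positions: np.ndarray,
    pixel_size: float,
    window_px: int | None = None,
    expected_fwhm_nm: float | None = None,
    residual_threshold: float = 0.2,
    decorrelation_nm: float | None = None,
    method_label: str = "gaussian-fit",
) -> ResolutionReport:
    """Per-bead elliptical Gaussian fits and their FWHM statistics.

    Each position gets a square fit window (default 9 px, or sized to
    about three expected FWHM when ``expected_fwhm_nm`` is given); beads
    whose window leaves the image, that have a neighbor within 3x the
    expected FWHM, or whose normalized fit residual exceeds
    ``residual_threshold`` are excluded and counted.
    """
    image = np.asarray(image, dtype=float)
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if window_px is None:
        if expected_fwhm_nm is not None:
            window_px = int(round(3.0 * expected_fwhm_nm / pixel_size)) | 1
            window_px = max(window_px, 9)
        else:
            window_px = 9
    half = window_px // 2
    ny, nx = image.shape

    exclusion_nm = 3.0 * expected_fwhm_nm if expected_fwhm_nm else None

    rows = []
    n_excluded = 0
    for i, (py, px) in enumerate(positions):
        if exclusion_nm is not None and len(positions) > 1:
            d = np.hypot(positions[:, 0] - py, positions[:, 1] - px) * pixel_size
            d[i] = np.inf
            if d.min() < exclusion_nm:
                n_excluded += 1
                continue
        iy, ix = int(round(py)), int(round(px))
        if iy - half < 0 or iy + half >= ny or ix - half < 0 or ix + half >= nx:
            n_excluded += 1
            continue
        win = image[iy - half : iy + half + 1, ix - half : ix + half + 1]
        yy, xx = np.mgrid[iy - half : iy + half + 1, ix - half : ix + half + 1]
        amp0 = win.max() - win.min()
        sigma0 = (expected_fwhm_nm or 2.5 * pixel_size) / FWHM_PER_SIGMA / pixel_size
        p0 = [amp0, px, py, sigma0, sigma0, win.min()]
        try:
            popt, _ = optimize.curve_fit(
                _gauss2d,
                (xx.ravel(), yy.ravel()),
                win.ravel(),
                p0=p0,
                maxfev=2000,
                bounds=(
                    [0, ix - half, iy - half, 0.3, 0.3, -np.inf],
                    [np.inf, ix + half, iy + half, window_px, window_px, np.inf],
                ),
            )
        except RuntimeError:
            n_excluded += 1
            continue
        fit = _gauss2d((xx.ravel(), yy.ravel()), *popt)
        resid = np.sqrt(np.mean((fit - win.ravel()) ** 2)) / max(popt[0], 1e-30)
        if resid > residual_threshold:
            n_excluded += 1
            continue
        rows.append(
            {
                "x_nm": popt[1] * pixel_size,
                "y_nm": popt[2] * pixel_size,
                "fwhm_x_nm": FWHM_PER_SIGMA * abs(popt[3]) * pixel_size,
                "fwhm_y_nm": FWHM_PER_SIGMA * abs(popt[4]) * pixel_size,
                "residual": resid,
                "amplitude": popt[0],
            }
        )
    if not rows:
        raise AnalysisError("no beads passed the fit acceptance criteria")
    beads = pd.DataFrame(rows, columns=BEAD_COLUMNS)
    return ResolutionReport(
        mean_fwhm_x=float(beads.fwhm_x_nm.mean()),
        sd_fwhm_x=float(beads.fwhm_x_nm.std(ddof=1)) if len(beads) > 1 else 0.0,
        mean_fwhm_y=float(beads.fwhm_y_nm.mean()),
        sd_fwhm_y=float(beads.fwhm_y_nm.std(ddof=1)) if len(beads) > 1 else 0.0,
        n=len(beads),
        n_excluded=n_excluded,
        decorrelation_nm=decorrelation_nm,
        method=method_label,
        beads=beads,
    )


def _edge_taper(shape: tuple[int, int], fraction: float = 0.1) -> np.ndarray:
    wins = []
    for n in shape:
        edge = max(int(n * fraction), 2)
        w = np.ones(n)
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
        w[:edge] = ramp
        w[-edge:] = ramp[::-1]
        wins.append(w)
    return wins[0][:, None] * wins[1][None, :]


def decorrelation_resolution(
    image: np.ndarray,
    pixel_size: float,
    n_radii: int = 20,
    n_highpass: int = 10,
) -> float | None:
    """Image-decorrelation resolution estimate (parameter free).

    Computes the Pearson-type correlation between the image spectrum and
    its phase-normalized copy restricted by binary low-pass masks of
    increasing radius, repeated over a series of Gaussian high-pass
    pre-filters.  The estimate is ``2 * pixel_size / r0`` where ``r0`` is
    the largest mask radius (as a fraction of Nyquist) at which any curve
    has a local maximum; returns None when no curve peaks (e.g. for white
    noise, whose correlation rises monotonically to the full bandwidth).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 64:
        raise ValueError("decorrelation analysis needs a 2D image >= 64x64")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")

    img = (image - image.mean()) * _edge_taper(image.shape)
    spectrum = np.fft.fftshift(np.fft.fft2(img))
    mag = np.abs(spectrum)
    normalized = np.where(mag > 0, spectrum / np.where(mag > 0, mag, 1.0), 0.0)

    ny, nx = image.shape
    fy = (np.arange(ny) - ny // 2) / (ny / 2)
    fx = (np.arange(nx) - nx // 2) / (nx / 2)
    fr = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)  # fraction of Nyquist

    radii = np.linspace(1.0 / n_radii, 1.0, n_radii)
    sigmas = np.geomspace(min(image.shape) / 4.0, 1.0, n_highpass)

    def curve(spec: np.ndarray) -> np.ndarray:
        d = np.empty(len(radii))
        norm_spec = np.linalg.norm(spec)
        for i, r in enumerate(radii):
            mask = fr < r
            masked = normalized * mask
            denom = norm_spec * np.linalg.norm(masked)
            d[i] = (
                np.real(np.vdot(spec, masked)) / denom if denom > 0 else 0.0
            )
        return d

    def local_max_radius(d: np.ndarray) -> float | None:
        best = None
        dr = radii[1] - radii[0]
        for i in range(1, len(d) - 1):
            if d[i] > d[i - 1] and d[i] >= d[i + 1] and d[i] > 1e-3:
                # parabolic sub-bin refinement of the peak position
                denom = d[i - 1] - 2 * d[i] + d[i + 1]
                delta = 0.5 * (d[i - 1] - d[i + 1]) / denom if denom != 0 else 0.0
                best = radii[i] + np.clip(delta, -0.5, 0.5) * dr
        return best

    best_r = None
    specs = [spectrum]
    for s in sigmas:
        hp = image - ndimage.gaussian_filter(image, s)
        hp = (hp - hp.mean()) * _edge_taper(image.shape)
        specs.append(np.fft.fftshift(np.fft.fft2(hp)))
    for spec in specs:
        r = local_max_radius(curve(spec))
        if r is not None and (best_r is None or r > best_r):
            best_r = r
    if best_r is None:
        return None
    return 2.0 * pixel_size / best_r


def two_frame_average(stack: np.ndarray, mode: str = "paired") -> np.ndarray:
    """Average consecutive frames of a time series.

    ``mode="paired"`` averages disjoint pairs (output length ``T // 2``);
    ``mode="sliding"`` averages each frame with its successor (length
    ``T - 1``).  Suppresses frame-alternating reconstruction artifacts.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim < 3 or stack.shape[0] < 2:
        warnings.warn("two_frame_average needs >= 2 frames; returning input unchanged")
        return stack
    if mode == "paired":
        t = stack.shape[0] // 2 * 2
        return 0.5 * (stack[0:t:2] + stack[1:t:2])
    if mode == "sliding":
        return 0.5 * (stack[:-1] + stack[1:])
    raise ValueError(f"unknown mode {mode!r}")
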