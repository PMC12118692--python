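"""2D registration of the three pattern-orientation projections.

The raw camera frame of each orientation shows the sample stretched by
``1/cos(tilt)`` along its shear axis and rotated by the pattern azimuth.
Mapping into the common top-down frame therefore applies the fixed
geometric normalization (compress by the inverse stretch, rotate by
0/+60/-60 degrees), followed by data-driven refinement: a coarse
cross-correlation translation and a coarsest-first pyramidal affine fit
optimized with a derivative-free simplex on normalized cross-correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage, optimize
from skimage import transform as sktransform


__all__ = [
    "AffineTransform2D",
    "RegistrationResult",
    "RegistrationError",
    "raw_frame_transform",
    "to_common_frame",
    "warp",
    "coarse_register",
    "multiscale_affine",
    "register_pair",
    "register_orientations",
]

_DEFAULT_AZIMUTHS = (0.0, 60.0, -60.0)


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class AffineTransform2D:
    """Homogeneous 2D affine mapping source-frame (x, y) to target-frame (x, y).

    ``matrix`` is 3x3 row-major acting on column vectors ``(x, y, 1)`` with
    x = column index, y = row index (pixel centers, origin at the top-left
    pixel).  The bottom row must be (0, 0, 1) and the linear block must be
    invertible.
    """

    matrix: np.ndarray
    source: str = "moving"
    target: str = "fixed"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("matrix must be 3x3")
        if not np.allclose(m[2], (0.0, 0.0, 1.0), atol=1e-12):
            raise ValueError("bottom row must be (0, 0, 1)")
        if abs(np.linalg.det(m[:2, :2])) <= 1e-6:
            raise ValueError("linear block is (near-)singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls, source: str = "moving", target: str = "fixed") -> "AffineTransform2D":
        return cls(np.eye(3), source, target)

    @classmethod
    def from_params(
        cls,
        translation: tuple[float, float] = (0.0, 0.0),
        rotation_deg: float = 0.0,
        log_scale: tuple[float, float] = (0.0, 0.0),
        shear: float = 0.0,
        center: tuple[float, float] = (0.0, 0.0),
        source: str = "moving",
        target: str = "fixed",
    ) -> "AffineTransform2D":
        """Compose T(translation) R(rotation) Shear Scale about ``center``.

        ``center`` is in (x, y) pixels; rotations, scales and shears act
        about it so that level-to-level pyramid initialization only needs
        the translation rescaled.
        """
        th = math.radians(rotation_deg)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        sh = np.array([[1.0, shear], [0.0, 1.0]])
        sc = np.diag([math.exp(log_scale[0]), math.exp(log_scale[1])])
        lin = rot @ sh @ sc
        cx, cy = center
        tx, ty = translation
        m = np.eye(3)
        m[:2, :2] = lin
        m[:2, 2] = np.array([tx + cx, ty + cy]) - lin @ np.array([cx, cy])
        return cls(m, source, target)

    def inverse(self) -> "AffineTransform2D":
        return AffineTransform2D(np.linalg.inv(self.matrix), self.target, self.source)

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return the transform applying ``other`` first, then ``self``."""
        return AffineTransform2D(self.matrix @ other.matrix, other.source, self.target)

    def __matmul__(self, other: "AffineTransform2D") -> "AffineTransform2D":
        return self.compose(other)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.hstack([pts, np.ones((len(pts), 1))])
        return (self.matrix @ hom.T).T[:, :2]

    def to_dict(self) -> dict[str, Any]:
        return {"matrix": self.matrix.tolist(), "source": self.source, "target": self.target}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AffineTransform2D":
        return cls(np.asarray(d["matrix"]), d.get("source", "moving"), d.get("target", "fixed"))


@dataclass
class RegistrationResult:
    """Affine fit plus its per-pyramid-level similarity trace."""

    transform: AffineTransform2D
    score: float
    score_trace: list[float] = field(default_factory=list)
    converged: bool = True


def _center(shape: tuple[int, int]) -> tuple[float, float]:
    return ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)


def _centered(linear: np.ndarray, center_xy: tuple[float, float]) -> np.ndarray:
    m = np.eye(3)
    m[:2, :2] = linear
    c = np.asarray(center_xy)
    m[:2, 2] = c - linear @ c
    return m


def raw_frame_transform(
    shape: tuple[int, int], tilt_angle: float, azimuth: float
) -> AffineTransform2D:
    """Common-frame -> raw-frame mapping for one orientation.

    Rotates by ``-azimuth`` (so the orientation's shear axis lands on the
    frame's +x axis) and stretches by ``1/cos(tilt)`` along x, about the
    image center.
    """
    from .geometry import stretch_factor  # local import to avoid a cycle

    th = math.radians(-azimuth)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    stretch = np.diag([stretch_factor(tilt_angle), 1.0])
    return AffineTransform2D(
        _centered(stretch @ rot, _center(shape)), source="common", target="raw"
    )


def warp(
    image: np.ndarray,
    transform: AffineTransform2D,
    order: int = 1,
    output_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Resample ``image`` under ``transform`` (inverse-mapped, zero-filled).

    The output pixel at target coordinate ``x`` takes the value of the
    source image at ``transform^{-1} x`` (bilinear by default); pixels
    mapped from outside the source are exactly 0.
    """
    if output_shape is None and np.allclose(transform.matrix, np.eye(3), atol=0):
        return image.copy()
    inv = np.linalg.inv(transform.matrix)
    return sktransform.warp(
        np.asarray(image, dtype=float),
        inverse_map=sktransform.AffineTransform(matrix=inv),
        order=order,
        mode="constant",
        cval=0.0,
        preserve_range=True,
        output_shape=output_shape,
    )


def to_common_frame(
    image: np.ndarray,
    orientation_index: int,
    tilt_angle: float = 45.0,
    azimuths: tuple[float, float, float] = _DEFAULT_AZIMUTHS,
    conserve_flux: bool = True,
) -> np.ndarray:
    """Fixed geometric normalization of one orientation's raw projection.

    Compresses by ``cos(tilt)`` (= 1/sqrt(2) at 45 degrees) along the
    orientation's shear/stretch axis (the raw frame's x axis), then rotates
    by the orientation azimuth (0 / +60 / -60 degrees for orientations
    1/2/3) about the image center.  Out-of-frame regions are zero-filled.
    """
    if orientation_index not in (1, 2, 3):
        raise ValueError(f"orientation_index must be 1, 2 or 3, got {orientation_index}")
    from .geometry import stretch_factor

    stretch = stretch_factor(tilt_angle)
    az = azimuths[orientation_index - 1]
    th = math.radians(az)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    compress = np.diag([1.0 / stretch, 1.0])
    t = AffineTransform2D(
        _centered(rot @ compress, _center(image.shape)), source="raw", target="common"
    )
    out = warp(image, t)
    if conserve_flux:
        out *= stretch
    return out


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def coarse_register(fixed: np.ndarray, moving: np.ndarray) -> tuple[float, float]:
    """Translation (dx, dy) in pixels that best aligns ``moving`` onto ``fixed``.

    Integer-pixel estimate from the FFT cross-correlation peak, refined to
    sub-pixel precision by derivative-free simplex maximization of the
    normalized cross-correlation under bilinear shifts.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must have the same shape")
    if fixed.std() == 0 or moving.std() == 0:
        raise RegistrationError("cannot register a flat (zero-variance) image")

    f = np.fft.fft2(fixed - fixed.mean())
    g = np.fft.fft2(moving - moving.mean())
    xc = np.fft.ifft2(f * np.conj(g)).real
    peak = np.unravel_index(np.argmax(xc), xc.shape)
    dy, dx = peak
    # wrap to signed shifts
    if dy > fixed.shape[0] // 2:
        dy -= fixed.shape[0]
    if dx > fixed.shape[1] // 2:
        dx -= fixed.shape[1]

    def neg_ncc(shift_xy: np.ndarray) -> float:
        shifted = ndimage.shift(moving, (shift_xy[1], shift_xy[0]), order=1, mode="constant")
        return -_ncc(fixed, shifted)

    res = optimize.minimize(
        neg_ncc,
        x0=np.array([dx, dy], dtype=float),
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-8, "maxfev": 200},
    )
    return float(res.x[0]), float(res.x[1])


def _pyramid_level(image: np.ndarray, ds: int) -> np.ndarray:
    """Anti-alias blur (sigma = 2*ds/6) then decimate by ``ds``."""
    if ds == 1:
        return image
    blurred = ndimage.gaussian_filter(image, 2.0 * ds / 6.0, mode="nearest")
    return blurred[::ds, ::ds]


def _level_transform(params: np.ndarray, ds: int, level_shape: tuple[int, int]) -> AffineTransform2D:
    """Full-resolution parameters expressed on a downsampled grid.

    Rotation/scale/shear are scale-invariant; only the translation shrinks
    by the downsampling factor.
    """
    tx, ty, rot, lsx, lsy, sh = params
    return AffineTransform2D.from_params(
        translation=(tx / ds, ty / ds),
        rotation_deg=rot,
        log_scale=(lsx, lsy),
        shear=sh,
        center=_center(level_shape),
    )


def multiscale_affine(
    fixed: np.ndarray,
    moving: np.ndarray,
    levels: tuple[int, ...] = (16, 8, 4, 2, 1),
    metric: str = "ncc",
    init_translation: tuple[float, float] = (0.0, 0.0),
    max_evals: int = 400,
    xtol: float = 1e-4,
    score_tol: float = 1e-3,
    min_level_size: int = 16,
) -> RegistrationResult:
    """Coarsest-first pyramidal affine registration.

    A 6-parameter affine (translation x2, rotation, two log-scales, shear,
    all about the image center) is fitted with a derivative-free simplex at
    the coarsest pyramid level; the fit initializes the next finer level
    until full resolution.  The similarity metric is normalized
    cross-correlation (``metric="mse"`` selects mean squared error).

    Returns the transform mapping ``moving`` onto ``fixed``; ``converged``
    is True when the finest level's score improvement fell below
    ``score_tol``.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must have the same shape")
    if not (np.all(np.isfinite(fixed)) and np.all(np.isfinite(moving))):
        raise ValueError("images must be finite")

    if metric == "ncc":
        def score_fn(a, b):
            return _ncc(a, b)
    elif metric == "mse":
        rng_span = max(fixed.max() - fixed.min(), 1e-12)
        def score_fn(a, b):
            return -float(np.mean((a - b) ** 2)) / rng_span**2
    else:
        raise ValueError(f"unknown metric {metric!r}")

    usable = [ds for ds in sorted(set(levels), reverse=True)
              if min(fixed.shape) // ds >= min_level_size]
    if not usable:
        usable = [1]

    params = np.array([init_translation[0], init_translation[1], 0, 0, 0, 0], dtype=float)
    trace: list[float] = []
    last_improvement = np.inf
    for ds in usable:
        f_lvl = _pyramid_level(fixed, ds)
        m_lvl = _pyramid_level(moving, ds)

        def neg_score(p: np.ndarray) -> float:
            t = _level_transform(p, ds, f_lvl.shape)
            return -score_fn(f_lvl, warp(m_lvl, t))

        before = -neg_score(params)
        steps = np.array([2.0 * ds, 2.0 * ds, 1.0, 0.02, 0.02, 0.02])
        simplex = np.vstack([params, params + np.diag(steps)])
        res = optimize.minimize(
            neg_score,
            x0=params,
            method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "maxfev": max_evals,
                "xatol": xtol,
                "fatol": 1e-8,
            },
        )
        if -res.fun >= before:
            params = res.x
            after = -res.fun
        else:  # keep the better of init vs fit (never regress)
            after = before
        last_improvement = after - before
        trace.append(after)

    final = AffineTransform2D.from_params(
        translation=(params[0], params[1]),
        rotation_deg=params[2],
        log_scale=(params[3], params[4]),
        shear=params[5],
        center=_center(fixed.shape),
    )
    converged = bool(np.isfinite(trace[-1]) and last_improvement < score_tol)
    return RegistrationResult(final, float(trace[-1]), trace, converged)


def register_pair(
    fixed: np.ndarray,
    moving: np.ndarray,
    levels: tuple[int, ...] = (16, 8, 4, 2, 1),
    **kwargs,
) -> RegistrationResult:
    """Coarse cross-correlation translation followed by the pyramid affine."""
    dx, dy = coarse_register(fixed, moving)
    return multiscale_affine(fixed, moving, levels=levels, init_translation=(dx, dy), **kwargs)


def register_orientations(
    images: list[np.ndarray] | np.ndarray,
    levels: tuple[int, ...] = (16, 8, 4, 2, 1),
    **kwargs,
) -> list[RegistrationResult]:
    """Register orientations 2 and 3 pairwise onto the fixed orientation 1.

    ``images`` are the three projections already mapped by
    :func:`to_common_frame`.  Returns one result per orientation; the first
    is the identity.
    """
    images = list(images)
    if len(images) != 3:
        raise ValueError("expected exactly 3 orientation images")
    results = [RegistrationResult(AffineTransform2D.identity(), 1.0, [1.0], True)]
    for img in images[1:]:
        results.append(register_pair(images[0], img, levels=levels, **kwargs))
    return results
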