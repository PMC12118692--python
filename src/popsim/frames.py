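"""Pattern metadata and the raw-frame container shared across the pipeline."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np


__all__ = ["PatternParams", "FrameSet", "default_pattern_set"]


@dataclass(frozen=True)
class PatternParams:
    """Sinusoidal structured-illumination pattern for one orientation.

    The illumination is ``1 + m * cos(2*pi*k.r + phi_p)`` with a purely
    lateral wave vector ``k`` of magnitude ``1/line_spacing`` at the given
    azimuth (an optional axial component models a depth mis-calibration of
    the pattern).

    Parameters
    ----------
    line_spacing : float
        Pattern period in nm (default 390, chosen close to the cutoff of
        the projection OTF; the practical lower limit of the optics is
        about 300 nm at 488 nm excitation).
    azimuth : float
        In-plane pattern direction, degrees from +x towards +y.
    phases : tuple of float
        Pattern phases in radians; equidistant steps spanning one period
        make the phase sum exactly uniform.
    modulation_depth : float
        Contrast ``m`` of the sinusoid, in [0, 1].
    axial_tilt_cycles_per_nm : float
        Optional axial component of the wave vector (cycles/nm); nonzero
        values emulate projections whose pattern plane is tilted in depth.
    """

    line_spacing: float = 390.0
    azimuth: float = 0.0
    phases: tuple[float, ...] = (0.0, 2 * math.pi / 3, 4 * math.pi / 3)
    modulation_depth: float = 0.8
    axial_tilt_cycles_per_nm: float = 0.0
    min_line_spacing: float = 300.0

    def __post_init__(self) -> None:
        if self.line_spacing < self.min_line_spacing:
            raise ValueError(
                f"line_spacing={self.line_spacing} nm below the configured "
                f"lower bound {self.min_line_spacing} nm"
            )
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must be in [0, 1]")
        ph = np.asarray(self.phases, dtype=float)
        if len(ph) < 1 or np.any(np.diff(ph) <= 0):
            raise ValueError("phases must be strictly increasing")
        if ph[-1] - ph[0] >= 2 * math.pi:
            raise ValueError("phases must span at most one period")

    @property
    def k_lateral(self) -> tuple[float, float]:
        """Lateral wave vector (kx, ky) in cycles/nm."""
        az = math.radians(self.azimuth)
        return (math.cos(az) / self.line_spacing, math.sin(az) / self.line_spacing)

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def to_dict(self) -> dict[str, Any]:
        return {
            "line_spacing": self.line_spacing,
            "azimuth": self.azimuth,
            "phases": list(self.phases),
            "modulation_depth": self.modulation_depth,
            "axial_tilt_cycles_per_nm": self.axial_tilt_cycles_per_nm,
            "min_line_spacing": self.min_line_spacing,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PatternParams":
        d = dict(d)
        d["phases"] = tuple(d["phases"])
        return cls(**d)


def default_pattern_set(
    line_spacing: float = 390.0,
    modulation_depth: float = 0.8,
    azimuths: tuple[float, float, float] = (0.0, 60.0, -60.0),
) -> tuple[PatternParams, ...]:
    """The three-orientation pattern set (azimuths 0, +60, -60 degrees)."""
    return tuple(
        PatternParams(
            line_spacing=line_spacing, azimuth=az, modulation_depth=modulation_depth
        )
        for az in azimuths
    )


@dataclass
class FrameSet:
    """Raw (or registered) 2D projection frames indexed by orientation and phase.

    Attributes
    ----------
    images : ndarray, shape (n_orientations, n_phases, H, W)
    patterns : tuple of PatternParams, one per orientation.
    pixel_size : float
        Pixel pitch in nm of the frames' common grid.
    registered : bool
        True once the frames have been mapped into the common top-down
        frame (prerequisite for reconstruction).
    meta : dict
        Free-form provenance (optics, shear, seed, ...).
    """

    images: np.ndarray
    patterns: tuple[PatternParams, ...]
    pixel_size: float
    registered: bool = False
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        if self.images.ndim != 4:
            raise ValueError("images must have shape (n_orientations, n_phases, H, W)")
        if len(self.patterns) != self.images.shape[0]:
            raise ValueError(
                f"{self.images.shape[0]} orientations but "
                f"{len(self.patterns)} pattern descriptors"
            )
        for pat in self.patterns:
            if pat.n_phases != self.images.shape[1]:
                raise ValueError("pattern phase count does not match frame layout")

    @property
    def n_orientations(self) -> int:
        return self.images.shape[0]

    @property
    def n_phases(self) -> int:
        return self.images.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.images.shape[2:]

    def frame(self, orientation: int, phase: int) -> np.ndarray:
        """Single frame; ``orientation`` is 1-based, ``phase`` 0-based."""
        return self.images[orientation - 1, phase]

    def with_images(self, images: np.ndarray, registered: bool | None = None) -> "FrameSet":
        return FrameSet(
            images,
            self.patterns,
            self.pixel_size,
            self.registered if registered is None else registered,
            dict(self.meta),
        )
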