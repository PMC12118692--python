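"""Run configuration: nested sections with strict (unknown-key) validation.

Every field has a default; the fully materialized configuration is echoed
into each run's provenance file so that reruns are reproducible from the
artifacts alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .frames import PatternParams
from .geometry import OpticalConfig, ShearParams


__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


def _from_dict(cls, data: dict[str, Any], section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in section '{section}': {sorted(unknown)}")
    return cls(**data)


@dataclass
class OpticsSection:
    na: float = 1.35
    lambda_exc_nm: float = 488.0
    lambda_em_nm: float = 520.0
    tilt_deg: float = 45.0
    pixel_nm: float = 100.0
    psf_fwhm_nm: float = 381.0
    lightsheet_axial_range_nm: float = 10000.0

    def to_optical_config(self) -> OpticalConfig:
        return OpticalConfig(
            numerical_aperture=self.na,
            excitation_wavelength=self.lambda_exc_nm,
            emission_wavelength=self.lambda_em_nm,
            tilt_angle=self.tilt_deg,
            raw_pixel_size=self.pixel_nm,
            lightsheet_axial_range=self.lightsheet_axial_range_nm,
            projection_psf_fwhm=self.psf_fwhm_nm,
        )


@dataclass
class PatternSection:
    line_spacing_nm: float = 390.0
    azimuths_deg: tuple[float, float, float] = (0.0, 60.0, -60.0)
    modulation: float = 0.8

    def to_patterns(self) -> tuple[PatternParams, ...]:
        return tuple(
            PatternParams(
                line_spacing=self.line_spacing_nm,
                azimuth=az,
                modulation_depth=self.modulation,
            )
            for az in self.azimuths_deg
        )


@dataclass
class ShearSection:
    factor: float = 1.0
    axis_deg: float = 0.0

    def to_shear_params(self) -> ShearParams:
        import math

        th = math.radians(self.axis_deg)
        return ShearParams(self.factor, (math.cos(th), math.sin(th)))


@dataclass
class NoiseSection:
    enabled: bool = False
    photon_scale: float = 1.0
    read_noise_sd: float = 1.6
    offset: float = 100.0
    gain: float = 2.0


@dataclass
class SimulationSection:
    phantom: str = "beads"  # or "dual-layer"
    placement: str = "disc"
    n_beads: int = 30
    field_size_nm: float = 16000.0
    grid_extent_nm: float = 25600.0
    height_nm: float = 0.0
    bead_diameter_nm: float = 100.0
    min_separation_nm: float = 2000.0
    brightness: float = 1000.0
    voxel_pitch_lateral_nm: float = 50.0
    voxel_pitch_axial_nm: float = 200.0
    camera_binning: int = 2
    gap_nm: float = 30000.0
    n_bottom: int = 24
    n_top: int = 6


@dataclass
class RegistrationSection:
    levels: tuple[int, ...] = (16, 8, 4, 2, 1)
    metric: str = "ncc"
    max_evals: int = 400


@dataclass
class ReconstructionSection:
    method: str = "rl"
    wiener_parameter: float = 1e-2
    rl_iterations: int = 5
    apodization: str = "triangle"
    upsample: int = 2


@dataclass
class AnalysisSection:
    min_separation_nm: float = 1500.0
    expected_fwhm_nm: float | None = None
    decorrelation: bool = True


@dataclass
class CalibrationSection:
    candidate_start: float = 0.9
    candidate_stop: float = 1.1
    candidate_step: float = 0.01

    def candidates(self) -> list[float]:
        import numpy as np

        return [
            float(c)
            for c in np.round(
                np.arange(
                    self.candidate_start,
                    self.candidate_stop + self.candidate_step / 2,
                    self.candidate_step,
                ),
                6,
            )
        ]


@dataclass
class RunConfig:
    optics: OpticsSection = field(default_factory=OpticsSection)
    pattern: PatternSection = field(default_factory=PatternSection)
    shear: ShearSection = field(default_factory=ShearSection)
    noise: NoiseSection = field(default_factory=NoiseSection)
    simulation: SimulationSection = field(default_factory=SimulationSection)
    registration: RegistrationSection = field(default_factory=RegistrationSection)
    reconstruction: ReconstructionSection = field(default_factory=ReconstructionSection)
    analysis: AnalysisSection = field(default_factory=AnalysisSection)
    calibration: CalibrationSection = field(default_factory=CalibrationSection)
    seed: int = 0
    outdir: str = "popsim_run"

    _SECTIONS = {
        "optics": OpticsSection,
        "pattern": PatternSection,
        "shear": ShearSection,
        "noise": NoiseSection,
        "simulation": SimulationSection,
        "registration": RegistrationSection,
        "reconstruction": ReconstructionSection,
        "analysis": AnalysisSection,
        "calibration": CalibrationSection,
    }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data or {})
        kwargs: dict[str, Any] = {}
        for name, section_cls in cls._SECTIONS.items():
            if name in data:
                section = data.pop(name)
                if not isinstance(section, dict):
                    raise ConfigError(f"section '{name}' must be a mapping")
                # lists from YAML -> tuples where the dataclass expects them
                for key in ("azimuths_deg", "levels"):
                    if key in section and isinstance(section[key], list):
                        section[key] = tuple(section[key])
                kwargs[name] = _from_dict(section_cls, section, name)
        for scalar in ("seed", "outdir"):
            if scalar in data:
                kwargs[scalar] = data.pop(scalar)
        if data:
            raise ConfigError(f"unknown top-level key(s): {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)
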