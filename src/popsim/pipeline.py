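"""Top-level pipeline: simulate -> register -> calibrate -> reconstruct -> analyze.

Each stage reads only files produced by earlier stages (never mutating
them), writes its artifacts into the run directory, and appends wall-time
and configuration provenance to ``provenance.json``.  Reruns with the same
seed reproduce all artifacts exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .frames import FrameSet
from .geometry import ShearParams
from .io import (
    read_frameset,
    read_image,
    read_transforms,
    write_frameset,
    write_image,
    write_transforms,
)
from .phantom import make_bead_phantom, make_dual_layer_phantom
from .registration import register_orientations, to_common_frame, warp
from .resolution import decorrelation_resolution, detect_beads, fwhm_stats
from .shear_calibration import calibrate_shear
from .sim_recon import ReconSettings, reconstruct
from .simulate import NoiseModel, simulate_raw_frames

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "DependencyError", "STAGES"]

STAGES = ("simulate", "register", "calibrate", "reconstruct", "analyze")


class DependencyError(RuntimeError):
    pass


def _require(outdir: Path, filename: str, produced_by: str) -> Path:
    path = outdir / filename
    if not path.exists():
        raise DependencyError(
            f"missing upstream artifact {filename!r}; run the "
            f"'{produced_by}' stage first"
        )
    return path


def _build_phantom(config: RunConfig):
    sim = config.simulation
    if sim.phantom == "beads":
        return make_bead_phantom(
            n_beads=sim.n_beads,
            field_size=sim.field_size_nm,
            height=sim.height_nm,
            bead_diameter=sim.bead_diameter_nm,
            min_separation=sim.min_separation_nm,
            brightness=sim.brightness,
            voxel_pitch_lateral=sim.voxel_pitch_lateral_nm,
            voxel_pitch_axial=sim.voxel_pitch_axial_nm,
            grid_extent=sim.grid_extent_nm,
            placement=sim.placement,
            seed=config.seed,
        )
    if sim.phantom == "dual-layer":
        return make_dual_layer_phantom(
            gap=sim.gap_nm,
            n_bottom=sim.n_bottom,
            n_top=sim.n_top,
            field_size=sim.field_size_nm,
            grid_extent=sim.grid_extent_nm,
            min_separation=sim.min_separation_nm,
            brightness=sim.brightness,
            voxel_pitch_lateral=sim.voxel_pitch_lateral_nm,
            voxel_pitch_axial=sim.voxel_pitch_axial_nm,
            placement=sim.placement,
            seed=config.seed,
        )
    raise ValueError(f"unknown phantom kind {config.simulation.phantom!r}")


def _stage_simulate(config: RunConfig, outdir: Path) -> None:
    phantom = _build_phantom(config)
    noise = None
    if config.noise.enabled:
        noise = NoiseModel(
            photon_scale=config.noise.photon_scale,
            read_noise_sd=config.noise.read_noise_sd,
            offset=config.noise.offset,
            gain=config.noise.gain,
            seed=config.seed + 1,
        )
    frames = simulate_raw_frames(
        phantom,
        config.optics.to_optical_config(),
        config.pattern.to_patterns(),
        shear=config.shear.to_shear_params(),
        noise=noise,
        camera_binning=config.simulation.camera_binning,
    )
    write_frameset(outdir / "frames.tif", frames)
    phantom.emitters.to_csv(outdir / "emitters.csv", index=False)


def _registered_common_frames(config: RunConfig, outdir: Path):
    frames = read_frameset(_require(outdir, "frames.tif", "simulate"))
    tilt = config.optics.tilt_deg
    azimuths = config.pattern.azimuths_deg
    common = np.stack(
        [
            np.stack(
                [
                    to_common_frame(frames.images[i, p], i + 1, tilt, azimuths)
                    for p in range(frames.n_phases)
                ]
            )
            for i in range(frames.n_orientations)
        ]
    )
    return frames, common


def _stage_register(config: RunConfig, outdir: Path) -> None:
    frames, common = _registered_common_frames(config, outdir)
    widefields = [common[i].sum(axis=0) for i in range(frames.n_orientations)]
    results = register_orientations(
        widefields,
        levels=config.registration.levels,
        metric=config.registration.metric,
        max_evals=config.registration.max_evals,
    )
    write_transforms(outdir / "transforms.json", results)


def _stage_reconstruct(config: RunConfig, outdir: Path) -> None:
    frames, common = _registered_common_frames(config, outdir)
    results = read_transforms(_require(outdir, "transforms.json", "register"))
    registered = np.stack(
        [
            np.stack(
                [warp(common[i, p], results[i].transform) for p in range(frames.n_phases)]
            )
            for i in range(frames.n_orientations)
        ]
    )
    reg_frames = FrameSet(
        registered, frames.patterns, frames.pixel_size, registered=True, meta=frames.meta
    )
    settings = ReconSettings(
        method=config.reconstruction.method,
        wiener_parameter=config.reconstruction.wiener_parameter,
        rl_iterations=config.reconstruction.rl_iterations,
        apodization=config.reconstruction.apodization,
        upsample=config.reconstruction.upsample,
    )
    result = reconstruct(reg_frames, config.optics.to_optical_config(), settings)
    write_image(outdir / "recon.tif", result.reconstruction, result.pixel_size)
    write_image(outdir / "widefield.tif", result.widefield, result.widefield_pixel_size)
    (outdir / "recon_settings.json").write_text(
        json.dumps(dataclasses.asdict(settings), indent=2)
    )


def _stage_analyze(config: RunConfig, outdir: Path) -> None:
    image, pixel = read_image(_require(outdir, "recon.tif", "reconstruct"))
    if pixel is None:
        pixel = config.optics.pixel_nm / config.reconstruction.upsample
    positions = detect_beads(image, pixel, config.analysis.min_separation_nm)
    decorr = None
    if config.analysis.decorrelation and min(image.shape) >= 64:
        decorr = decorrelation_resolution(image, pixel)
    report = fwhm_stats(
        image,
        positions,
        pixel,
        expected_fwhm_nm=config.analysis.expected_fwhm_nm,
        decorrelation_nm=decorr,
    )
    (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    if report.beads is not None:
        report.beads.to_csv(outdir / "beads.csv", index=False)


def _stage_calibrate(config: RunConfig, outdir: Path) -> None:
    sim = dataclasses.replace(config.simulation, phantom="dual-layer")
    cal_config = dataclasses.replace(config, simulation=sim)
    phantom = _build_phantom(cal_config)
    sweep = calibrate_shear(
        phantom,
        config.optics.to_optical_config(),
        config.pattern.to_patterns(),
        candidates=config.calibration.candidates(),
        camera_binning=config.simulation.camera_binning,
    )
    pd.DataFrame(
        {"shear": sweep.candidates, "score": sweep.scores, "success": sweep.success}
    ).to_csv(outdir / "sweep.csv", index=False)
    (outdir / "sweep_summary.json").write_text(
        json.dumps(
            {"best_shear": sweep.best_shear, "identifiable": sweep.identifiable},
            indent=2,
        )
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "register": _stage_register,
    "calibrate": _stage_calibrate,
    "reconstruct": _stage_reconstruct,
    "analyze": _stage_analyze,
}


def run_pipeline(
    config: RunConfig,
    stages: tuple[str, ...] | list[str] = STAGES,
    outdir: str | Path | None = None,
) -> Path:
    """Execute the requested stages in dependency order.

    Returns the run directory.  A machine-readable ``provenance.json``
    records the fully materialized configuration, the seed, the package
    version and per-stage wall times.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; valid: {STAGES}")
    ordered = [s for s in STAGES if s in stages]

    timings: dict[str, float] = {}
    for stage in ordered:
        t0 = time.perf_counter()
        logger.info("running stage %s", stage)
        _STAGE_FUNCS[stage](config, outdir)
        timings[stage] = time.perf_counter() - t0

    provenance_file = outdir / "provenance.json"
    provenance = (
        json.loads(provenance_file.read_text()) if provenance_file.exists() else {}
    )
    provenance.update(
        {
            "config": config.to_dict(),
            "seed": config.seed,
            "version": __version__,
            "stage_wall_times_s": {**provenance.get("stage_wall_times_s", {}), **timings},
        }
    )
    provenance_file.write_text(json.dumps(provenance, indent=2))
    return outdir
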