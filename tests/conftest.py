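"""Shared fixtures: the default simulated resolution experiment.

The heavy end-to-end chain (phantom -> 9 frames -> common frame ->
registration -> Wiener and RL reconstructions) is simulated once per
session and reused by the reconstruction, resolution and acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import popsim as ps


@dataclass
class ResolutionRun:
    phantom: object
    frames: object
    registered: object  # FrameSet in the common frame
    widefield: np.ndarray
    widefield_pixel: float
    wiener: object  # ReconResult
    rl: object  # ReconResult
    report_widefield: object
    report_wiener: object
    report_rl: object


def match_to_ground_truth(
    positions_px: np.ndarray,
    emitters,
    image_shape: tuple[int, int],
    pixel_size: float,
    gate_nm: float = 300.0,
) -> np.ndarray:
    """Keep only detections within ``gate_nm`` of a ground-truth emitter."""
    if len(positions_px) == 0:
        return positions_px
    h, w = image_shape
    x = (positions_px[:, 1] - (w - 1) / 2) * pixel_size
    y = (positions_px[:, 0] - (h - 1) / 2) * pixel_size
    gt = emitters[["x_nm", "y_nm"]].to_numpy()
    keep = []
    for i in range(len(positions_px)):
        d = np.hypot(gt[:, 0] - x[i], gt[:, 1] - y[i])
        if d.min() <= gate_nm:
            keep.append(i)
    return positions_px[keep]


def simulate_and_register(phantom, optics=None, patterns=None, shear=None, noise=None):
    """Raw 9-frame simulation followed by the full registration chain."""
    optics = optics or ps.OpticalConfig()
    frames = ps.simulate_raw_frames(
        phantom, optics, patterns, shear=shear, noise=noise
    )
    common = np.stack(
        [
            np.stack(
                [
                    ps.to_common_frame(frames.images[i, p], i + 1, optics.tilt_angle)
                    for p in range(frames.n_phases)
                ]
            )
            for i in range(frames.n_orientations)
        ]
    )
    results = ps.register_orientations(
        [common[i].sum(axis=0) for i in range(3)], levels=(8, 4, 2, 1)
    )
    registered = np.stack(
        [
            np.stack(
                [
                    ps.warp(common[i, p], results[i].transform)
                    for p in range(frames.n_phases)
                ]
            )
            for i in range(3)
        ]
    )
    return frames, ps.FrameSet(
        registered, frames.patterns, frames.pixel_size, registered=True, meta=frames.meta
    ), results


@pytest.fixture(scope="session")
def resolution_run() -> ResolutionRun:
    """25 isolated 100 nm beads through the default projection-SIM chain."""
    phantom = ps.make_bead_phantom(
        n_beads=25,
        field_size=13000,
        grid_extent=19200,
        min_separation=1800,
        placement="disc",
        seed=5,
    )
    frames, registered, _ = simulate_and_register(phantom)

    wiener = ps.reconstruct(registered, settings=ps.ReconSettings(method="wiener"))
    rl = ps.reconstruct(registered, settings=ps.ReconSettings(method="rl"))
    widefield = wiener.widefield
    wf_pixel = wiener.widefield_pixel_size

    def report(image, pixel, expected):
        pos = ps.detect_beads(image, pixel, min_separation=1500)
        pos = match_to_ground_truth(pos, phantom.emitters, image.shape, pixel)
        return ps.fwhm_stats(image, pos, pixel, expected_fwhm_nm=expected)

    return ResolutionRun(
        phantom=phantom,
        frames=frames,
        registered=registered,
        widefield=widefield,
        widefield_pixel=wf_pixel,
        wiener=wiener,
        rl=rl,
        report_widefield=report(widefield, wf_pixel, 381.0),
        report_wiener=report(wiener.reconstruction, wiener.pixel_size, 200.0),
        report_rl=report(rl.reconstruction, rl.pixel_size, 150.0),
    )
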