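"""Empirical recovery of the projection shear factor.

The shear applied during the focal sweep must make all three pattern
orientations project along the same (z) axis, otherwise features from
different depths cannot be overlapped after registration.  Calibration
images a dual-layer bead phantom (dense small beads on the bottom plane,
sparse large beads a known gap above), sweeps candidate shear factors, and
scores how well the bead sets of the three registered orientations overlap
in *both* layers.  The bottom layer always registers (it carries no height
information); the top layer walks laterally with the shear error, so the
combined residual is minimized at the true shear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .frames import PatternParams, default_pattern_set
from .geometry import OpticalConfig, ShearParams
from .phantom import Phantom3D
from .registration import RegistrationError, register_orientations, to_common_frame, warp
from .resolution import detect_beads


__all__ = ["CalibrationSweep", "CalibrationError", "overlap_score", "calibrate_shear"]


class CalibrationError(RuntimeError):
    pass


@dataclass
class CalibrationSweep:
    """Scores of candidate shear factors and the selected optimum."""

    candidates: list[float]
    scores: list[float]
    per_layer: list[dict[str, float]]
    success: list[bool]
    best_shear: float
    identifiable: bool

    def __post_init__(self) -> None:
        n = len(self.candidates)
        if not (len(self.scores) == len(self.per_layer) == len(self.success) == n):
            raise ValueError("sweep lists must have equal length")
        if not all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if self.best_shear not in self.candidates:
            raise ValueError("best_shear must be one of the candidates")


def _detections_nm(image: np.ndarray, pixel_size: float, min_separation: float) -> np.ndarray:
    """Bead detections as (x_nm, y_nm) in center-origin coordinates."""
    pos = detect_beads(image, pixel_size, min_separation=min_separation)
    if len(pos) == 0:
        return np.empty((0, 2))
    h, w = image.shape
    x = (pos[:, 1] - (w - 1) / 2) * pixel_size
    y = (pos[:, 0] - (h - 1) / 2) * pixel_size
    return np.column_stack([x, y])


def _layer_labels(points: np.ndarray, emitters, gate: float) -> np.ndarray:
    """Label each detection with the layer of its nearest ground-truth emitter."""
    if "layer" not in getattr(emitters, "columns", []):
        return np.array(["all"] * len(points))
    gt = emitters[["x_nm", "y_nm"]].to_numpy()
    labels = emitters["layer"].to_numpy()
    if len(gt) == 0 or len(points) == 0:
        return np.array(["all"] * len(points))
    d = cdist(points, gt)
    idx = d.argmin(axis=1)
    out = labels[idx].astype(object)
    out[d.min(axis=1) > 3 * gate] = "unmatched"
    return out


def _mutual_matches(a: np.ndarray, b: np.ndarray, gate: float):
    """Mutually-nearest pairs within the gate; returns index pairs and distances."""
    if len(a) == 0 or len(b) == 0:
        return [], np.empty(0)
    d = cdist(a, b)
    nn_ab = d.argmin(axis=1)
    nn_ba = d.argmin(axis=0)
    pairs, dists = [], []
    for i, j in enumerate(nn_ab):
        if nn_ba[j] == i and d[i, j] <= gate:
            pairs.append((i, j))
            dists.append(d[i, j])
    return pairs, np.asarray(dists)


def overlap_score(
    registered_images: list[np.ndarray],
    emitters,
    pixel_size: float,
    gate_nm: float = 1000.0,
    detection_min_separation_nm: float = 700.0,
) -> tuple[float, dict[str, float]]:
    """Mean matched-bead residual (nm) across the three orientation pairs.

    Detections in each registered image are matched mutually-nearest
    within ``gate_nm`` for every orientation pair; unmatched detections
    incur the gate distance as penalty.  Returns the overall mean residual
    and a per-layer breakdown (layers taken from the ground-truth emitter
    table when present).
    """
    if len(registered_images) != 3:
        raise ValueError("expected three registered orientation images")
    det = [
        _detections_nm(img, pixel_size, detection_min_separation_nm)
        for img in registered_images
    ]
    if all(len(d) == 0 for d in det):
        raise CalibrationError("no bead detections in any registered image")
    labels = [_layer_labels(d, emitters, gate_nm) for d in det]

    residuals: list[float] = []
    layer_residuals: dict[str, list[float]] = {}

    def add(value: float, layer: str) -> None:
        residuals.append(value)
        layer_residuals.setdefault(str(layer), []).append(value)

    for ia, ib in ((0, 1), (0, 2), (1, 2)):
        pairs, dists = _mutual_matches(det[ia], det[ib], gate_nm)
        matched_a = {i for i, _ in pairs}
        matched_b = {j for _, j in pairs}
        for (i, j), dist in zip(pairs, dists):
            add(float(dist), labels[ia][i])
        for i in range(len(det[ia])):
            if i not in matched_a:
                add(gate_nm, labels[ia][i])
        for j in range(len(det[ib])):
            if j not in matched_b:
                add(gate_nm, labels[ib][j])

    score = float(np.mean(residuals)) if residuals else gate_nm
    breakdown = {k: float(np.mean(v)) for k, v in layer_residuals.items()}
    return score, breakdown


def calibrate_shear(
    phantom: Phantom3D,
    optics: OpticalConfig | None = None,
    patterns: tuple[PatternParams, ...] | None = None,
    candidates: list[float] | np.ndarray | None = None,
    camera_binning: int = 2,
    registration_levels: tuple[int, ...] = (8, 4, 2, 1),
    gate_nm: float = 1000.0,
    success_threshold_px: float = 1.0,
    detection_min_separation_nm: float = 700.0,
    flat_tol_nm: float | None = None,
) -> CalibrationSweep:
    """Sweep candidate shear factors on a dual-layer phantom.

    For each candidate, the three orientations' uniform-illumination
    projections are simulated at that shear, mapped to the common frame,
    registered (orientation 1 fixed), and scored with
    :func:`overlap_score`.  The best shear is the argmin of the score; a
    candidate is flagged successful when both layers' residuals stay below
    ``success_threshold_px`` camera pixels.  When the score is flat across
    the sweep (range below ``flat_tol_nm``, default half a camera pixel)
    the sweep is flagged non-identifiable — a zero-gap phantom carries no
    height lever arm and cannot constrain the shear.
    """
    # simulate lazily to avoid a hard module cycle at import time
    from .simulate import simulate_raw_frames

    optics = optics or OpticalConfig()
    base_patterns = tuple(patterns) if patterns is not None else default_pattern_set()
    if candidates is None:
        candidates = np.round(np.arange(0.90, 1.1001, 0.01), 4)
    candidates = [float(c) for c in candidates]
    if not candidates:
        raise ValueError("candidates must be non-empty")

    # geometry only: a single unmodulated frame per orientation suffices
    flat_patterns = tuple(
        replace(p, modulation_depth=0.0, phases=(0.0,)) for p in base_patterns
    )

    scores: list[float] = []
    per_layer: list[dict[str, float]] = []
    success: list[bool] = []
    pixel = phantom.voxel_pitch_lateral * camera_binning
    ceiling = 2.0 * gate_nm

    for cand in candidates:
        try:
            frames = simulate_raw_frames(
                phantom,
                optics,
                flat_patterns,
                shear=ShearParams(shear_factor=cand),
                camera_binning=camera_binning,
            )
            common = [
                to_common_frame(frames.images[i, 0], i + 1, optics.tilt_angle)
                for i in range(3)
            ]
            results = register_orientations(common, levels=registration_levels)
            registered = [common[0]] + [
                warp(common[i], results[i].transform) for i in (1, 2)
            ]
            score, breakdown = overlap_score(
                registered,
                phantom.emitters,
                pixel,
                gate_nm=gate_nm,
                detection_min_separation_nm=detection_min_separation_nm,
            )
            ok = bool(
                breakdown
                and all(v < success_threshold_px * pixel for v in breakdown.values())
                and all(r.converged for r in results)
            )
        except (RegistrationError, CalibrationError) as exc:
            warnings.warn(f"candidate {cand}: {exc}; scored at the penalty ceiling")
            score, breakdown, ok = ceiling, {}, False
        scores.append(score)
        per_layer.append(breakdown)
        success.append(ok)

    best = candidates[int(np.argmin(scores))]
    if flat_tol_nm is None:
        flat_tol_nm = 0.5 * pixel
    identifiable = (max(scores) - min(scores)) > flat_tol_nm
    if not identifiable:
        warnings.warn(
            "shear sweep is flat: the phantom does not constrain the shear "
            "factor (zero or too-small layer gap)"
        )
    return CalibrationSweep(candidates, scores, per_layer, success, best, identifiable)
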