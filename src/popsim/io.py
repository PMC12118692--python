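"""File formats: multi-page TIFF frame sets with JSON sidecars, transforms,
reports and sweep tables.

TIFF is the only image format.  All physics metadata (pattern parameters,
optics, shear, seed) travels in a JSON sidecar next to the TIFF rather
than in TIFF tags, so runs are diffable with standard tools.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .frames import FrameSet, PatternParams
from .geometry import OpticalConfig, ShearParams
from .registration import AffineTransform2D, RegistrationResult


__all__ = [
    "FormatError",
    "sidecar_path",
    "write_frameset",
    "read_frameset",
    "write_transforms",
    "read_transforms",
    "write_image",
    "read_image",
]


class FormatError(ValueError):
    pass


def sidecar_path(tiff_path: str | Path) -> Path:
    return Path(tiff_path).with_suffix(".json")


def _optics_to_dict(optics: OpticalConfig | None) -> dict | None:
    return dataclasses.asdict(optics) if optics is not None else None


def write_frameset(path: str | Path, frames: FrameSet, dtype: str | None = None) -> Path:
    """Write a frame set as multi-page TIFF plus JSON sidecar.

    Page order is orientation-major, phase-minor.  ``dtype`` defaults to
    32-bit float; ``"uint16"`` is intended for noisy (integer-valued)
    data and rejects values outside the 16-bit range.
    """
    path = Path(path)
    images = np.asarray(frames.images)
    n_o, n_p, h, w = images.shape
    pages = images.reshape(n_o * n_p, h, w)
    if dtype is None:
        dtype = "float32"
    if dtype == "uint16":
        if pages.min() < 0 or pages.max() > np.iinfo(np.uint16).max:
            raise FormatError("frame values outside the uint16 range")
        pages = np.round(pages).astype(np.uint16)
    elif dtype == "float32":
        pages = pages.astype(np.float32)
    else:
        raise FormatError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(path, pages)

    meta = frames.meta or {}
    optics = meta.get("optics")
    shear = meta.get("shear")
    sidecar = {
        "n_orientations": n_o,
        "n_phases": n_p,
        "pixel_size_nm": frames.pixel_size,
        "registered": frames.registered,
        "patterns": [p.to_dict() for p in frames.patterns],
        "optics": _optics_to_dict(optics),
        "shear": dataclasses.asdict(shear) if isinstance(shear, ShearParams) else None,
        "seed": meta.get("seed"),
        "camera_binning": meta.get("camera_binning"),
        "page_order": "orientation-major, phase-minor",
    }
    sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_frameset(path: str | Path) -> FrameSet:
    """Read a frame set written by :func:`write_frameset`.

    Validates page count against the sidecar and requires grayscale pages.
    """
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing JSON sidecar: {side}")
    meta = json.loads(side.read_text())
    for key in ("n_orientations", "n_phases", "pixel_size_nm", "patterns"):
        if key not in meta:
            raise FormatError(f"sidecar missing required field {key!r}")

    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise FormatError("TIFF pages must be grayscale (2D)")
    n_o, n_p = int(meta["n_orientations"]), int(meta["n_phases"])
    if pages.shape[0] != n_o * n_p:
        raise FormatError(
            f"page-count mismatch: TIFF has {pages.shape[0]} pages but the "
            f"sidecar declares n_orientations*n_phases = {n_o * n_p}"
        )
    images = pages.reshape(n_o, n_p, *pages.shape[1:]).astype(float)
    patterns = tuple(PatternParams.from_dict(d) for d in meta["patterns"])
    optics = OpticalConfig(**meta["optics"]) if meta.get("optics") else None
    shear = (
        ShearParams(
            meta["shear"]["shear_factor"],
            tuple(meta["shear"]["shear_axis"]),
            meta["shear"].get("view_direction", "top-down"),
        )
        if meta.get("shear")
        else None
    )
    return FrameSet(
        images,
        patterns,
        float(meta["pixel_size_nm"]),
        registered=bool(meta.get("registered", False)),
        meta={
            "optics": optics,
            "shear": shear,
            "seed": meta.get("seed"),
            "camera_binning": meta.get("camera_binning"),
        },
    )


def write_transforms(path: str | Path, results: list[RegistrationResult]) -> Path:
    path = Path(path)
    payload = [
        {
            "transform": r.transform.to_dict(),
            "score": r.score,
            "score_trace": list(r.score_trace),
            "converged": r.converged,
            "metric": "ncc",
        }
        for r in results
    ]
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_transforms(path: str | Path) -> list[RegistrationResult]:
    payload = json.loads(Path(path).read_text())
    out = []
    for item in payload:
        out.append(
            RegistrationResult(
                AffineTransform2D.from_dict(item["transform"]),
                float(item["score"]),
                [float(s) for s in item.get("score_trace", [])],
                bool(item.get("converged", True)),
            )
        )
    return out


def write_image(path: str | Path, image: np.ndarray, pixel_size_nm: float | None = None) -> Path:
    """32-bit float single-page TIFF; pixel size recorded in a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    if pixel_size_nm is not None:
        sidecar_path(path).write_text(json.dumps({"pixel_size_nm": pixel_size_nm}))
    return path


def read_image(path: str | Path) -> tuple[np.ndarray, float | None]:
    image = tifffile.imread(path).astype(float)
    side = sidecar_path(path)
    pixel = None
    if side.exists():
        pixel = json.loads(side.read_text()).get("pixel_size_nm")
    return image, pixel
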