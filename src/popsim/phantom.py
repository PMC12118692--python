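"""Ground-truth phantoms: bead fields and dual-layer calibration samples.

Lateral coordinates (x, y) are in nm with the origin at the *center* of the
lateral grid (the rotation/stretch center used everywhere in the package);
z is in nm measured from the bottom plane (z index 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


__all__ = ["Phantom3D", "make_bead_phantom", "make_dual_layer_phantom", "PackingError"]


class PackingError(RuntimeError):
    """Raised when beads cannot be placed at the requested separation."""


EMITTER_COLUMNS = ["x_nm", "y_nm", "z_nm", "diameter_nm", "brightness"]


@dataclass
class Phantom3D:
    """Ground-truth 3D fluorophore density plus its emitter table.

    Attributes
    ----------
    density : ndarray, shape (nz, ny, nx)
        Non-negative photon density per voxel per unit exposure.
    voxel_pitch_lateral, voxel_pitch_axial : float
        Voxel pitches in nm.
    emitters : pandas.DataFrame
        One row per emitter with columns ``x_nm, y_nm, z_nm, diameter_nm,
        brightness`` (and optionally ``layer``).
    """

    density: np.ndarray
    voxel_pitch_lateral: float
    voxel_pitch_axial: float
    emitters: pd.DataFrame

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.ndim != 3:
            raise ValueError("density must be 3D (z, y, x)")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        nz, ny, nx = self.density.shape
        if len(self.emitters):
            half_x = (nx - 1) / 2 * self.voxel_pitch_lateral
            half_y = (ny - 1) / 2 * self.voxel_pitch_lateral
            zmax = (nz - 1) * self.voxel_pitch_axial
            e = self.emitters
            inside = (
                (e.x_nm.abs() <= half_x + self.voxel_pitch_lateral)
                & (e.y_nm.abs() <= half_y + self.voxel_pitch_lateral)
                & (e.z_nm >= -self.voxel_pitch_axial)
                & (e.z_nm <= zmax + self.voxel_pitch_axial)
            )
            if not inside.all():
                raise ValueError("emitters must lie inside the grid")

    @property
    def lateral_shape(self) -> tuple[int, int]:
        return self.density.shape[1:]

    def lateral_extent_nm(self) -> tuple[float, float]:
        ny, nx = self.lateral_shape
        return (ny * self.voxel_pitch_lateral, nx * self.voxel_pitch_lateral)


def _render_emitters(
    shape: tuple[int, int, int],
    emitters: pd.DataFrame,
    pitch_lat: float,
    pitch_ax: float,
    supersample: int = 4,
) -> np.ndarray:
    """Rasterize spherical emitters onto the voxel grid.

    Beads larger than a voxel are rendered as solid spheres via supersampled
    occupancy; sub-voxel beads are deposited as points with trilinear
    weights.  Each bead's in-grid mass is normalized to its brightness, so
    spheres clipped by the grid boundary keep their nominal flux.
    """
    nz, ny, nx = shape
    density = np.zeros(shape, dtype=float)
    cx = (nx - 1) / 2 * pitch_lat
    cy = (ny - 1) / 2 * pitch_lat

    for row in emitters.itertuples(index=False):
        # grid (fractional voxel) position of the bead center
        gx = (row.x_nm + cx) / pitch_lat
        gy = (row.y_nm + cy) / pitch_lat
        gz = row.z_nm / pitch_ax
        radius = row.diameter_nm / 2.0
        if radius < 0.5 * pitch_lat:
            # point emitter with trilinear weights
            iz, iy, ix = int(np.floor(gz)), int(np.floor(gy)), int(np.floor(gx))
            fz, fy, fx = gz - iz, gy - iy, gx - ix
            block = np.zeros((2, 2, 2))
            for dz in (0, 1):
                for dy in (0, 1):
                    for dx in (0, 1):
                        w = (
                            (fz if dz else 1 - fz)
                            * (fy if dy else 1 - fy)
                            * (fx if dx else 1 - fx)
                        )
                        block[dz, dy, dx] = w
            zs = slice(max(iz, 0), min(iz + 2, nz))
            ys = slice(max(iy, 0), min(iy + 2, ny))
            xs = slice(max(ix, 0), min(ix + 2, nx))
            sub = block[zs.start - iz : zs.stop - iz,
                        ys.start - iy : ys.stop - iy,
                        xs.start - ix : xs.stop - ix]
            total = sub.sum()
            if total > 0:
                density[zs, ys, xs] += row.brightness * sub / total
            continue

        # solid sphere: supersampled occupancy over the bounding box
        rz = radius / pitch_ax
        rl = radius / pitch_lat
        z0, z1 = int(np.floor(gz - rz - 1)), int(np.ceil(gz + rz + 1))
        y0, y1 = int(np.floor(gy - rl - 1)), int(np.ceil(gy + rl + 1))
        x0, x1 = int(np.floor(gx - rl - 1)), int(np.ceil(gx + rl + 1))
        z0c, z1c = max(z0, 0), min(z1 + 1, nz)
        y0c, y1c = max(y0, 0), min(y1 + 1, ny)
        x0c, x1c = max(x0, 0), min(x1 + 1, nx)
        if z0c >= z1c or y0c >= y1c or x0c >= x1c:
            continue
        s = supersample
        offs = (np.arange(s) + 0.5) / s - 0.5
        zz = (np.arange(z0c, z1c)[:, None] + offs[None, :]).ravel() * pitch_ax
        yy = (np.arange(y0c, y1c)[:, None] + offs[None, :]).ravel() * pitch_lat
        xx = (np.arange(x0c, x1c)[:, None] + offs[None, :]).ravel() * pitch_lat
        dz2 = (zz - gz * pitch_ax) ** 2
        dy2 = (yy - gy * pitch_lat) ** 2
        dx2 = (xx - gx * pitch_lat) ** 2
        inside = (
            dz2[:, None, None] + dy2[None, :, None] + dx2[None, None, :]
        ) <= radius**2
        occ = inside.reshape(z1c - z0c, s, y1c - y0c, s, x1c - x0c, s).mean(axis=(1, 3, 5))
        total = occ.sum()
        if total > 0:
            density[z0c:z1c, y0c:y1c, x0c:x1c] += row.brightness * occ / total
    return density


def _sample_positions(
    rng: np.random.Generator,
    n: int,
    half_extent: float,
    z_range: tuple[float, float],
    min_separation: float,
    exclude_lateral: np.ndarray | None = None,
    placement: str = "square",
    max_attempts_per_bead: int = 1000,
) -> np.ndarray:
    """Rejection-sample bead centers with a minimum pairwise 3D distance.

    ``exclude_lateral`` optionally lists (x, y) positions that candidates
    must also clear laterally (used to keep the two layers of a dual-layer
    phantom from overlapping in projection).  ``placement="disc"``
    restricts centers to the inscribed disc — content inside a centered
    disc survives the rotation and sqrt(2) stretch of every orientation's
    raw frame without clipping at the corners.
    """
    if placement not in ("square", "disc"):
        raise ValueError(f"unknown placement {placement!r}")
    positions: list[np.ndarray] = []
    attempts = 0
    budget = max_attempts_per_bead * max(n, 1)
    while len(positions) < n:
        if attempts >= budget:
            raise PackingError(
                f"could not place {n} beads with min_separation="
                f"{min_separation} nm in a {2*half_extent:.0f} nm field "
                f"after {budget} attempts"
            )
        attempts += 1
        x, y = rng.uniform(-half_extent, half_extent, size=2)
        if placement == "disc" and math.hypot(x, y) > half_extent:
            continue
        z = rng.uniform(*z_range) if z_range[1] > z_range[0] else z_range[0]
        cand = np.array([x, y, z])
        if positions:
            d = np.linalg.norm(np.asarray(positions) - cand, axis=1)
            if d.min() < min_separation:
                continue
        if exclude_lateral is not None and len(exclude_lateral):
            d_lat = np.hypot(
                exclude_lateral[:, 0] - x, exclude_lateral[:, 1] - y
            )
            if d_lat.min() < min_separation:
                continue
        positions.append(cand)
    return np.asarray(positions).reshape(n, 3)


def make_bead_phantom(
    n_beads: int,
    field_size: float = 25600.0,
    height: float = 0.0,
    bead_diameter: float = 100.0,
    min_separation: float = 2000.0,
    brightness: float = 1000.0,
    voxel_pitch_lateral: float = 50.0,
    voxel_pitch_axial: float = 200.0,
    grid_extent: float | None = None,
    placement_margin: float = 0.0,
    placement: str = "square",
    seed: int = 0,
) -> Phantom3D:
    """Random field of fluorescent nanospheres.

    Parameters
    ----------
    n_beads : int
        Number of beads; 0 gives an empty phantom.
    field_size : float
        Side length (nm) of the square region in which bead centers are
        placed (centered in the grid).
    height : float
        Axial extent (nm) over which bead centers are distributed; 0 puts
        every bead in the bottom plane.
    bead_diameter, min_separation, brightness :
        Bead diameter (nm), minimum pairwise center distance (nm), and
        photons per bead per unit exposure.
    grid_extent : float, optional
        Side length (nm) of the rendered lateral grid; defaults to
        ``field_size``.  A grid larger than the placement field leaves a
        border so that rotations/stretches of the projection geometry do
        not clip content.
    placement_margin : float
        Extra margin (nm) inside ``field_size`` kept free of bead centers.
    seed : int
        Seed for the bead-placement RNG; a fixed seed reproduces the
        phantom exactly.
    """
    if n_beads < 0:
        raise ValueError("n_beads must be >= 0")
    extent = float(grid_extent if grid_extent is not None else field_size)
    n_lat = int(round(extent / voxel_pitch_lateral))
    nz = max(int(round(height / voxel_pitch_axial)) + 1, 1)
    half = field_size / 2 - placement_margin - bead_diameter / 2
    if n_beads > 0 and half <= 0:
        raise PackingError("field_size too small for the requested beads")

    rng = np.random.default_rng(seed)
    if n_beads > 0:
        pos = _sample_positions(
            rng, n_beads, half, (0.0, height), min_separation, placement=placement
        )
        emitters = pd.DataFrame(
            {
                "x_nm": pos[:, 0],
                "y_nm": pos[:, 1],
                "z_nm": pos[:, 2],
                "diameter_nm": bead_diameter,
                "brightness": brightness,
            }
        )
    else:
        emitters = pd.DataFrame(columns=EMITTER_COLUMNS)

    density = _render_emitters(
        (nz, n_lat, n_lat), emitters, voxel_pitch_lateral, voxel_pitch_axial
    )
    return Phantom3D(density, voxel_pitch_lateral, voxel_pitch_axial, emitters)


def make_dual_layer_phantom(
    gap: float = 30000.0,
    n_bottom: int = 80,
    n_top: int = 10,
    bottom_diameter: float = 100.0,
    top_diameter: float = 500.0,
    field_size: float = 12800.0,
    min_separation: float = 1500.0,
    brightness: float = 1000.0,
    voxel_pitch_lateral: float = 50.0,
    voxel_pitch_axial: float = 200.0,
    grid_extent: float | None = None,
    placement: str = "disc",
    seed: int = 0,
) -> Phantom3D:
    """Two bead-coated planes separated by a known axial gap.

    Emulates a sandwich of two coverslips: the bottom plane densely coated
    with small (100 nm) nanospheres at z=0, the top plane sparsely coated
    with large (500 nm) nanospheres at z=gap (~30 um in the physical
    sample).  The known gap makes the projection shear factor identifiable:
    only the correct shear projects both layers consistently for all three
    pattern orientations.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    extent = float(grid_extent if grid_extent is not None else field_size)
    n_lat = int(round(extent / voxel_pitch_lateral))
    nz = max(int(round(gap / voxel_pitch_axial)) + 1, 1)
    rng = np.random.default_rng(seed)

    frames = []
    placed_lateral: np.ndarray | None = None
    for layer, n, diam, z in (
        ("bottom", n_bottom, bottom_diameter, 0.0),
        ("top", n_top, top_diameter, gap),
    ):
        if n == 0:
            continue
        half = field_size / 2 - diam / 2
        pos = _sample_positions(
            rng, n, half, (z, z), min_separation,
            exclude_lateral=placed_lateral, placement=placement
        )
        placed_lateral = (
            pos[:, :2]
            if placed_lateral is None
            else np.vstack([placed_lateral, pos[:, :2]])
        )
        frames.append(
            pd.DataFrame(
                {
                    "x_nm": pos[:, 0],
                    "y_nm": pos[:, 1],
                    "z_nm": z,
                    "diameter_nm": diam,
                    "brightness": brightness,
                    "layer": layer,
                }
            )
        )
    emitters = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=EMITTER_COLUMNS + ["layer"])
    )
    density = _render_emitters(
        (nz, n_lat, n_lat), emitters, voxel_pitch_lateral, voxel_pitch_axial
    )
    return Phantom3D(density, voxel_pitch_lateral, voxel_pitch_axial, emitters)
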