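"""Density maps: CCP4/MRC I/O, trilinear interpolation, synthetic blobs.

A :class:`DensityMap` is a regular 3D scalar field on an orthogonal grid,
addressed as ``values[ix, iy, iz]`` with X the first axis (the canonical
axis order; arbitrary on-disk axis orders are permuted on read).  Map values
are used unscaled; every threshold in the pipeline is expressed relative to
``sigma_level``, the standard deviation of the values over the whole grid.

The synthetic simulator renders each atom as an isotropic Gaussian of peak
height equal to its atomic number and width ``s = 0.25 x resolution``;
at 1.0 A resolution atoms a bond length apart are resolved as separate
peaks, while by 2.5 A resolution short bonds (~1.2 A) blur into a single
maximum, mimicking how real difference density degrades.
The same kernel is reused to compute model density during refinement, so
synthetic maps and model maps are commensurable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import yaml
from scipy import ndimage

from .errors import (
    FormatError,
    InvalidSceneError,
    OutOfBoundsError,
    UnsupportedCellError,
)

__all__ = [
    "DensityMap",
    "SyntheticScene",
    "read_map",
    "write_map",
    "interpolate",
    "interpolate_many",
    "gaussian_atom_density",
    "simulate_difference_map",
]

#: header words (1-based) holding the MRC2014 origin, in A
_ORIGIN_WORDS = (50, 51, 52)

#: exponent cutoff beyond which an atom's Gaussian is treated as zero
_EXP_CUTOFF = 60.0


@dataclass
class DensityMap:
    """Regular 3D scalar field with origin and spacing in Angstrom."""

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    sigma_level: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise FormatError("map grid must be 3D with >= 2 points per axis")
        if np.any(self.spacing <= 0):
            raise FormatError("map spacing must be positive")
        self.sigma_level = float(np.std(self.values))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def upper(self) -> np.ndarray:
        """Cartesian coordinate of the last grid node on each axis."""
        return self.origin + self.spacing * (np.array(self.shape) - 1)

    def to_fractional_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous grid indices of Cartesian points (A)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.origin) / self.spacing

    def node_coords(self, idx: np.ndarray) -> np.ndarray:
        """Cartesian coordinates (A) of integer grid indices."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def contains(self, points: np.ndarray) -> np.ndarray:
        frac = self.to_fractional_index(points)
        n = np.array(self.shape) - 1
        tol = 1e-9
        return np.all((frac >= -tol) & (frac <= n + tol), axis=1)


@dataclass
class SyntheticScene:
    """Description of a synthetic difference-density blob.

    ``decoys`` is an optional second coordinate set representing nearby
    density not belonging to the ligand (adjacent solvent or another
    molecule); decoy atoms default to carbon.
    """

    atom_coords: np.ndarray
    elements: list[str]
    resolution: float
    noise_frac: float = 0.0
    decoys: np.ndarray | None = None
    decoy_elements: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.atom_coords = np.asarray(self.atom_coords, dtype=float)
        if self.atom_coords.size and not np.all(np.isfinite(self.atom_coords)):
            raise InvalidSceneError("non-finite atom coordinates")
        if self.resolution <= 0:
            raise InvalidSceneError("resolution must be positive")
        if self.noise_frac < 0:
            raise InvalidSceneError("noise_frac must be >= 0")
        if self.decoys is not None:
            self.decoys = np.asarray(self.decoys, dtype=float)
            if self.decoy_elements is None:
                self.decoy_elements = ["C"] * len(self.decoys)

    @classmethod
    def from_mapping(cls, data: dict) -> "SyntheticScene":
        atoms = data["atoms"]
        coords = np.array([a["xyz"] for a in atoms], dtype=float)
        elements = [a.get("element", "C") for a in atoms]
        decoys = data.get("decoys")
        dcoords = delems = None
        if decoys:
            dcoords = np.array([a["xyz"] for a in decoys], dtype=float)
            delems = [a.get("element", "C") for a in decoys]
        return cls(
            atom_coords=coords,
            elements=elements,
            resolution=float(data.get("resolution", 1.5)),
            noise_frac=float(data.get("noise_frac", 0.0)),
            decoys=dcoords,
            decoy_elements=delems,
            seed=int(data.get("seed", 0)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticScene":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise InvalidSceneError(f"scene file must be a mapping: {path}")
        return cls.from_mapping(data)


def _check_orthogonal(cell: gemmi.UnitCell) -> None:
    angles = np.array([cell.alpha, cell.beta, cell.gamma])
    if np.any(np.abs(angles - 90.0) > 1e-3):
        raise UnsupportedCellError(
            f"non-orthogonal cell (angles {angles}); only orthogonal "
            "P1 cells are supported"
        )


def read_map(path: str | Path) -> DensityMap:
    """Read an MRC2014/CCP4 volume, normalizing axis order to X-fastest."""
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot read map {path}: {exc}") from exc
    _check_orthogonal(ccp4.grid.unit_cell)
    # permute axes to the canonical X, Y, Z order without interpolation
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid = ccp4.grid
    values = np.array(grid.array, dtype=float)
    if values.ndim != 3 or min(values.shape) < 2:
        raise FormatError(f"map {path} is not a 3D volume")
    if np.any(~np.isfinite(values)):
        raise FormatError(f"map {path} contains non-finite values")
    cell = grid.unit_cell
    spacing = np.array(
        [cell.a / values.shape[0], cell.b / values.shape[1], cell.c / values.shape[2]]
    )
    origin = np.array([ccp4.header_float(w) for w in _ORIGIN_WORDS])
    if not np.any(origin):
        start = np.array(
            [ccp4.header_i32(5), ccp4.header_i32(6), ccp4.header_i32(7)], dtype=float
        )
        origin = start * spacing
    return DensityMap(origin=origin, spacing=spacing, values=values)


def write_map(dmap: DensityMap, path: str | Path) -> None:
    """Write a map as MRC2014/CCP4 (mode 2, X-fastest, origin in header)."""
    nx, ny, nz = dmap.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    grid.set_unit_cell(
        gemmi.UnitCell(
            nx * dmap.spacing[0], ny * dmap.spacing[1], nz * dmap.spacing[2],
            90.0, 90.0, 90.0,
        )
    )
    grid.spacegroup = gemmi.SpaceGroup("P1")
    np.asarray(grid.array)[...] = dmap.values.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, value in zip(_ORIGIN_WORDS, dmap.origin):
        ccp4.set_header_float(word, float(value))
    ccp4.write_ccp4_map(str(path))


def interpolate_many(dmap: DensityMap, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation at Cartesian points (A), vectorized."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    inside = dmap.contains(pts)
    if not np.all(inside):
        bad = pts[~inside][0]
        raise OutOfBoundsError(f"point {bad} outside map bounding box")
    frac = dmap.to_fractional_index(pts)
    n = np.array(dmap.shape) - 1
    frac = np.clip(frac, 0.0, n)  # pull rounding slop back onto the grid
    return ndimage.map_coordinates(dmap.values, frac.T, order=1, mode="nearest")


def interpolate(dmap: DensityMap, point: np.ndarray) -> float:
    """Trilinear interpolation of the 8 voxels surrounding one point."""
    return float(interpolate_many(dmap, np.asarray(point, dtype=float))[0])


def _atomic_numbers(elements: list[str]) -> np.ndarray:
    numbers = []
    for el in elements:
        z = gemmi.Element(el).atomic_number
        if z == 0:
            raise InvalidSceneError(f"unknown element symbol {el!r}")
        numbers.append(z)
    return np.array(numbers, dtype=float)


def gaussian_atom_density(
    coords: np.ndarray,
    elements: list[str],
    origin: np.ndarray,
    spacing: np.ndarray,
    shape: tuple[int, int, int],
    resolution: float,
) -> np.ndarray:
    """Gaussian-atom density field on a given grid geometry.

    density(x) = sum_atoms Z * exp(-|x - r|^2 / (2 s^2)),  s = 0.25 * resolution.

    Each atom contributes only within the radius where its exponent exceeds
    the cutoff (contributions < 1e-26 of the peak are dropped), which keeps
    the evaluation local and identical wherever the kernel is reused.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    origin = np.asarray(origin, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    z = _atomic_numbers(elements)
    s = 0.25 * resolution
    r_cut = s * np.sqrt(2.0 * _EXP_CUTOFF)
    values = np.zeros(shape, dtype=float)
    axes = [origin[d] + spacing[d] * np.arange(shape[d]) for d in range(3)]
    for (x0, y0, z0), zi in zip(coords, z):
        lo = np.maximum(
            0, np.ceil((np.array([x0, y0, z0]) - r_cut - origin) / spacing)
        ).astype(int)
        hi = np.minimum(
            np.array(shape),
            np.floor((np.array([x0, y0, z0]) + r_cut - origin) / spacing) + 1,
        ).astype(int)
        if np.any(lo >= hi):
            continue
        dx = axes[0][lo[0]:hi[0]] - x0
        dy = axes[1][lo[1]:hi[1]] - y0
        dz = axes[2][lo[2]:hi[2]] - z0
        expo = (
            dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        ) / (2.0 * s * s)
        np.clip(expo, None, _EXP_CUTOFF, out=expo)
        values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += zi * np.exp(-expo)
    return values


def simulate_difference_map(
    scene: SyntheticScene, spacing: float | np.ndarray = 0.3, pad: float = 4.0
) -> DensityMap:
    """Render a synthetic difference-density blob for a scene.

    The grid covers all atoms (ligand and decoys) with at least ``pad`` A
    of margin, its origin snapped to the spacing lattice so that shifting
    the scene by whole voxels shifts the field identically.  Seeded Gaussian
    noise of SD ``noise_frac x peak`` is added and ``sigma_level`` is the
    standard deviation of the final noisy field.
    """
    if scene.atom_coords.size == 0:
        raise InvalidSceneError("scene has no atoms")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if np.any(spacing <= 0):
        raise InvalidSceneError("spacing must be positive")
    coords = scene.atom_coords
    elements = list(scene.elements)
    if scene.decoys is not None and len(scene.decoys):
        coords = np.vstack([coords, scene.decoys])
        elements = elements + list(scene.decoy_elements)
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    # snap with an epsilon so whole-voxel scene shifts move the grid exactly
    origin = np.floor(lo / spacing + 1e-9) * spacing
    shape = tuple((np.ceil((hi - origin) / spacing - 1e-9)).astype(int) + 1)
    values = gaussian_atom_density(
        coords, elements, origin, spacing, shape, scene.resolution
    )
    if scene.noise_frac > 0:
        rng = np.random.default_rng(scene.seed)
        peak = float(values.max())
        values = values + rng.normal(0.0, scene.noise_frac * peak, size=values.shape)
    return DensityMap(origin=origin, spacing=spacing, values=values)
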