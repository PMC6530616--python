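"""Voxel phantoms and structure masks.

Coordinate convention (IEC-style): axis ``y`` is the couch-travel
(longitudinal) axis; axis ``z`` is vertical, with a gantry-0 beam
travelling along ``-z``; axis ``x`` completes a right-handed frame.
World coordinates are continuous cm with the grid origin at the corner
of voxel (0, 0, 0); voxels occupy half-open intervals
``[origin + i*spacing, origin + (i+1)*spacing)``.

Density is mass density relative to water (water 1.0); air is modelled
as 0 — the dose engine works on radiological depth, where the
difference from 0.0012 is negligible at phantom scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "VoxelGrid",
    "StructureMask",
    "PointOfInterest",
    "make_cheese_phantom",
    "make_slab_phantom",
    "make_hetero_phantom",
    "add_cylinder_mask",
    "write_grid_nrrd",
    "read_grid_nrrd",
    "write_mask_nrrd",
    "read_mask_nrrd",
    "write_mask_json",
    "read_mask_json",
]


@dataclass(frozen=True)
class VoxelGrid:
    """A rectilinear density lattice.

    ``density`` has shape ``dims`` indexed ``[ix, iy, iz]`` with values
    in [0, 3] (relative to water).
    """

    origin: np.ndarray  # (3,) cm, corner of voxel (0,0,0)
    spacing: np.ndarray  # (3,) cm
    density: np.ndarray  # (nx, ny, nz)

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        density = np.ascontiguousarray(self.density, dtype=float)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "density", density)
        if np.any(spacing <= 0):
            raise ValueError("spacing must be > 0 on all axes")
        if density.ndim != 3 or min(density.shape) < 1:
            raise ValueError("density must be a 3-D array with dims >= 1")
        if np.any(density < 0) or np.any(density > 3):
            raise ValueError("density values must lie in [0, 3]")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.density.shape

    def axis_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        n = self.dims[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def voxel_center(self, index) -> np.ndarray:
        return self.origin + (np.asarray(index, dtype=float) + 0.5) * self.spacing

    def contains_point(self, point) -> bool:
        p = np.asarray(point, dtype=float)
        extent = self.origin + self.spacing * np.asarray(self.dims)
        return bool(np.all(p >= self.origin) and np.all(p <= extent))

    def translated(self, offset) -> "VoxelGrid":
        """Shift the grid origin; the density lattice is unchanged."""
        return VoxelGrid(self.origin + np.asarray(offset, dtype=float), self.spacing, self.density)


@dataclass(frozen=True)
class StructureMask:
    """Named voxel membership on a :class:`VoxelGrid` lattice."""

    name: str
    member: np.ndarray  # boolean, same shape as the grid's density

    def __post_init__(self) -> None:
        object.__setattr__(self, "member", np.asarray(self.member, dtype=bool))

    @property
    def voxel_count(self) -> int:
        return int(self.member.sum())

    @property
    def indices(self) -> np.ndarray:
        """(n, 3) integer voxel indices of the members."""
        return np.argwhere(self.member)


@dataclass(frozen=True)
class PointOfInterest:
    """A measurement point, optionally averaged over a chamber-like
    segment along IEC-Y (``averaging_length`` 0.44 cm emulates the A1SL
    chamber's 4.4-mm collector; 0 is a point sample)."""

    position: np.ndarray
    averaging_length: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float).reshape(3))
        if self.averaging_length < 0:
            raise ValueError("averaging_length must be >= 0")


def _centered_grid(extent_xyz, spacing: float) -> VoxelGrid:
    dims = [max(1, int(round(e / spacing))) for e in extent_xyz]
    origin = -0.5 * spacing * np.asarray(dims, dtype=float)
    return VoxelGrid(origin, np.full(3, spacing), np.zeros(dims))


def _center_meshes(grid: VoxelGrid):
    return np.meshgrid(
        grid.axis_centers(0), grid.axis_centers(1), grid.axis_centers(2), indexing="ij"
    )


def make_cheese_phantom(
    diameter: float = 30.0,
    length: float = 18.0,
    spacing: float = 0.25,
    split: bool = False,
    air_margin: float = 1.0,
) -> VoxelGrid:
    """Cylindrical water-equivalent dosimetry phantom ("cheese" phantom).

    The cylinder (density 1.0) is aligned with IEC-Y, its axis through the
    world origin at the grid center; surrounding voxels are air (0).
    ``split=True`` removes the lower half (z < 0), emulating the divided
    phantom used for chamber measurements on the couch.
    """
    if diameter <= 0 or length <= 0 or spacing <= 0:
        raise ValueError("diameter, length and spacing must be > 0")
    if spacing > diameter:
        raise ValueError("spacing exceeds phantom diameter: degenerate grid")
    extent = (diameter + 2 * air_margin, length + 2 * air_margin, diameter + 2 * air_margin)
    grid = _centered_grid(extent, spacing)
    cx, cy, cz = _center_meshes(grid)
    inside = (cx**2 + cz**2 <= (diameter / 2.0) ** 2) & (np.abs(cy) <= length / 2.0)
    if split:
        inside &= cz >= 0.0
    grid.density[inside] = 1.0
    return grid


def make_slab_phantom(
    width: float, length: float, height: float, spacing: float = 0.25, air_margin: float = 1.0
) -> VoxelGrid:
    """Homogeneous water box (width IEC-X, length IEC-Y, height IEC-Z)
    centered at the world origin, air outside a margin."""
    if min(width, length, height) <= 0 or spacing <= 0:
        raise ValueError("all dimensions and spacing must be > 0")
    if spacing > min(width, length, height):
        raise ValueError("spacing exceeds a phantom dimension: degenerate grid")
    extent = (width + 2 * air_margin, length + 2 * air_margin, height + 2 * air_margin)
    grid = _centered_grid(extent, spacing)
    cx, cy, cz = _center_meshes(grid)
    inside = (
        (np.abs(cx) <= width / 2.0) & (np.abs(cy) <= length / 2.0) & (np.abs(cz) <= height / 2.0)
    )
    grid.density[inside] = 1.0
    return grid


def make_hetero_phantom(base: VoxelGrid, insert_region, insert_density: float) -> VoxelGrid:
    """Copy of ``base`` with the density inside an axis-aligned world-space
    box replaced by ``insert_density``.

    ``insert_region`` is ``((xmin, ymin, zmin), (xmax, ymax, zmax))`` in cm;
    membership is by voxel-center test.
    """
    lo = np.asarray(insert_region[0], dtype=float)
    hi = np.asarray(insert_region[1], dtype=float)
    if not (0.0 <= insert_density <= 3.0):
        raise ValueError("insert_density must lie in [0, 3]")
    extent = base.origin + base.spacing * np.asarray(base.dims)
    if np.any(lo < base.origin - 1e-9) or np.any(hi > extent + 1e-9) or np.any(hi < lo):
        raise ValueError("insert region outside the grid")
    cx, cy, cz = _center_meshes(base)
    inside = (
        (cx >= lo[0]) & (cx <= hi[0]) & (cy >= lo[1]) & (cy <= hi[1]) & (cz >= lo[2]) & (cz <= hi[2])
    )
    density = base.density.copy()
    density[inside] = insert_density
    return VoxelGrid(base.origin.copy(), base.spacing.copy(), density)


def add_cylinder_mask(
    grid: VoxelGrid, name: str, axis_point, radius: float, half_length: float
) -> StructureMask:
    """Mask of voxels whose centers fall inside an IEC-Y-aligned cylinder
    (synthetic "organ" for dose reporting).  An empty mask is returned
    as-is (reporting operations reject it)."""
    if radius <= 0 or half_length <= 0:
        raise ValueError("radius and half_length must be > 0")
    p = np.asarray(axis_point, dtype=float).reshape(3)
    cx, cy, cz = _center_meshes(grid)
    inside = ((cx - p[0]) ** 2 + (cz - p[2]) ** 2 <= radius**2) & (np.abs(cy - p[1]) <= half_length)
    return StructureMask(name, inside)


# -- NRRD / JSON I/O --------------------------------------------------------
# SimpleITK images index (x, y, z) through GetPixel but store arrays as
# (z, y, x); transpose at the boundary so package arrays stay [ix, iy, iz].

def write_grid_nrrd(grid: VoxelGrid, path, array: np.ndarray | None = None) -> None:
    """Write a density (default) or companion scalar array as NRRD."""
    data = grid.density if array is None else np.asarray(array, dtype=float)
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(grid.spacing))
    # NRRD origin is the center of voxel (0,0,0)
    img.SetOrigin(tuple(grid.origin + 0.5 * grid.spacing))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_grid_nrrd(path) -> VoxelGrid:
    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    origin = np.asarray(img.GetOrigin(), dtype=float) - 0.5 * spacing
    return VoxelGrid(origin, spacing, data)


def read_dose_nrrd(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a scalar NRRD raster; returns (array[ix,iy,iz], origin, spacing)."""
    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    origin = np.asarray(img.GetOrigin(), dtype=float) - 0.5 * spacing
    return data, origin, spacing


def write_mask_nrrd(mask: StructureMask, grid: VoxelGrid, path) -> None:
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(mask.member.astype(np.uint8).transpose(2, 1, 0))
    )
    img.SetSpacing(tuple(grid.spacing))
    img.SetOrigin(tuple(grid.origin + 0.5 * grid.spacing))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_mask_nrrd(path, name: str | None = None) -> StructureMask:
    img = sitk.ReadImage(str(path))
    member = sitk.GetArrayFromImage(img).transpose(2, 1, 0) > 0
    return StructureMask(name or Path(path).stem, member)


def write_mask_json(mask: StructureMask, path) -> None:
    doc = {"name": mask.name, "dims": list(mask.member.shape), "indices": mask.indices.tolist()}
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def read_mask_json(path) -> StructureMask:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    member = np.zeros(tuple(doc["dims"]), dtype=bool)
    idx = np.asarray(doc["indices"], dtype=int)
    if idx.size:
        member[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return StructureMask(doc["name"], member)
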