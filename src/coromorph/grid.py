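"""Voxel grid container and standard-format image I/O.

A :class:`VoxelGrid` is a 3D binary occupancy lattice with anisotropic
voxel spacing in micrometers.  Array axes are ordered ``(x, y, z)`` and the
physical center of voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``.
Connectivity conventions throughout the package are 26-neighbor foreground
and 6-neighbor background.

Masks are read and written as multi-page TIFF (z-stack, uint8 0/255, with
spacing/origin stored as JSON in the image description) or as NRRD (spacing
carried in the native header, via SimpleITK).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

__all__ = ["VoxelGrid", "read_mask", "write_mask"]

DEFAULT_SPACING = (0.97, 0.97, 2.00)  # light-sheet acquisition voxel, µm


@dataclass
class VoxelGrid:
    """Binary occupancy volume with anisotropic spacing.

    Parameters
    ----------
    occupancy
        Boolean array with axes ``(x, y, z)``.
    spacing
        Voxel pitch in µm per axis, ``(sx, sy, sz)``.  All components > 0.
    origin
        Physical µm coordinate of the center of voxel ``(0, 0, 0)``.
    """

    occupancy: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    thin_radius_warning: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    # -- coordinate transforms -------------------------------------------
    def world_to_index(self, xyz_um) -> np.ndarray:
        """Map µm coordinates to (possibly fractional) voxel indices."""
        p = np.atleast_2d(np.asarray(xyz_um, dtype=float))
        idx = (p - np.asarray(self.origin)) / np.asarray(self.spacing)
        return idx[0] if np.asarray(xyz_um).ndim == 1 else idx

    def index_to_world(self, ijk) -> np.ndarray:
        """Map voxel indices to µm coordinates of voxel centers."""
        idx = np.atleast_2d(np.asarray(ijk, dtype=float))
        p = idx * np.asarray(self.spacing) + np.asarray(self.origin)
        return p[0] if np.asarray(ijk).ndim == 1 else p

    def nearest_index(self, xyz_um) -> tuple[int, int, int]:
        idx = np.rint(self.world_to_index(xyz_um)).astype(int)
        idx = np.clip(idx, 0, np.asarray(self.occupancy.shape) - 1)
        return tuple(int(v) for v in idx)

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.occupancy.copy(), self.spacing, self.origin,
                         self.thin_radius_warning)


# ---------------------------------------------------------------------------
# I/O


def write_mask(grid: VoxelGrid, path: str | Path) -> None:
    """Write a mask as multi-page TIFF (``.tif``/``.tiff``) or NRRD (``.nrrd``).

    TIFF pages are z-slices (axes ``z, y, x``) of uint8 0/255; spacing and
    origin are embedded as JSON in the image description.  NRRD carries
    spacing/origin in its native header.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        data = (grid.occupancy.transpose(2, 1, 0).astype(np.uint8)) * 255
        meta = {"spacing_um": list(grid.spacing), "origin_um": list(grid.origin)}
        tifffile.imwrite(path, data, description=json.dumps(meta))
    elif suffix == ".nrrd":
        img = sitk.GetImageFromArray(grid.occupancy.transpose(2, 1, 0).astype(np.uint8))
        img.SetSpacing(tuple(grid.spacing))
        img.SetOrigin(tuple(grid.origin))
        sitk.WriteImage(img, str(path), useCompression=False)
    else:
        raise ValueError(f"unsupported mask format: {path.suffix!r}")


def read_mask(path: str | Path,
              spacing: tuple[float, float, float] | None = None,
              origin: tuple[float, float, float] | None = None) -> VoxelGrid:
    """Read a mask written by :func:`write_mask`.

    Explicit ``spacing``/``origin`` override any metadata found in the file
    (TIFFs from other tools may carry none; the default is then the
    light-sheet voxel ``(0.97, 0.97, 2.00)`` µm).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description or ""
        meta = {}
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            pass
        sp = spacing or tuple(meta.get("spacing_um", DEFAULT_SPACING))
        og = origin or tuple(meta.get("origin_um", (0.0, 0.0, 0.0)))
        occ = np.asarray(data) > 0
        if occ.ndim != 3:
            raise ValueError(f"expected a 3D z-stack in {path}")
        return VoxelGrid(occ.transpose(2, 1, 0), sp, og)
    if suffix == ".nrrd":
        img = sitk.ReadImage(str(path))
        occ = sitk.GetArrayFromImage(img) > 0
        sp = spacing or tuple(img.GetSpacing())
        og = origin or tuple(img.GetOrigin())
        return VoxelGrid(occ.transpose(2, 1, 0), sp, og)
    raise ValueError(f"unsupported mask format: {path.suffix!r}")
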