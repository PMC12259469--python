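"""Morphological preparation of binary masks before skeletonization.

Binary closing fills interior cavities of the segmented vessels (small holes
and cracks left by surface-based segmentation); component hygiene keeps the
components containing the labeled root points plus anything above a size
floor, discarding disconnected debris.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid

__all__ = ["binary_close", "keep_components", "ball_element"]

#: 26-connectivity structuring element for foreground labeling.
CONN26 = np.ones((3, 3, 3), dtype=bool)


def ball_element(radius_vox: int,
                 spacing: tuple[float, float, float] | None = None) -> np.ndarray:
    """Discrete ball of the given radius.

    With ``spacing`` the ball is calibrated in µm (an ellipsoid in voxel
    units, ``radius_vox`` interpreted in units of the smallest pitch);
    without it the ball is isotropic in voxels.
    """
    r = int(radius_vox)
    if spacing is None:
        ax = [np.arange(-r, r + 1)] * 3
        scale = np.ones(3)
    else:
        sp = np.asarray(spacing, dtype=float)
        r_um = r * sp.min()
        ext = np.ceil(r_um / sp).astype(int)
        ax = [np.arange(-e, e + 1) for e in ext]
        scale = sp / sp.min()
        r = r_um / sp.min()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    d2 = (X * scale[0]) ** 2 + (Y * scale[1]) ** 2 + (Z * scale[2]) ** 2
    return d2 <= r * r + 1e-9


def binary_close(grid: VoxelGrid, radius_vox: int = 2,
                 calibrated_um: bool = False) -> VoxelGrid:
    """Morphological closing (dilation then erosion) with a ball element.

    The element is a discrete ball of ``radius_vox`` voxels, isotropic in
    voxel units by default (set ``calibrated_um`` for a µm-calibrated
    ellipsoid).  The volume border is zero-padded by the element radius so
    dimensions are unchanged and no border artifacts arise; cavities smaller
    than the element are filled.
    """
    if radius_vox < 1:
        raise ValueError("radius_vox must be >= 1")
    el = ball_element(radius_vox, grid.spacing if calibrated_um else None)
    pad = tuple((s // 2, s // 2) for s in el.shape)
    occ = np.pad(grid.occupancy, pad)
    closed = ndimage.binary_erosion(ndimage.binary_dilation(occ, structure=el),
                                    structure=el)
    sl = tuple(slice(p[0], occ.shape[a] - p[1]) for a, p in enumerate(pad))
    return VoxelGrid(closed[sl], grid.spacing, grid.origin, grid.thin_radius_warning)


def keep_components(grid: VoxelGrid, min_voxels: int = 0,
                    keep_points: list | None = None) -> VoxelGrid:
    """Retain 26-connected components holding a keep point or >= ``min_voxels``.

    ``keep_points`` are µm coordinates (typically the labeled artery root
    points); a keep point falling on background raises with the offending
    coordinate and its distance to the nearest foreground voxel.
    """
    labels, n = ndimage.label(grid.occupancy, structure=CONN26)
    keep = np.zeros(n + 1, dtype=bool)
    if min_voxels <= 0:
        keep[1:] = True
    else:
        counts = np.bincount(labels.ravel(), minlength=n + 1)
        keep[1:] = counts[1:] >= min_voxels
    for p in keep_points or []:
        ijk = grid.nearest_index(p)
        lab = labels[ijk]
        if lab == 0:
            d = _distance_to_foreground(grid, p)
            raise ValueError(
                f"keep point {tuple(np.asarray(p, float))} lies on background "
                f"(nearest foreground voxel {d:.2f} µm away)")
        keep[lab] = True
    return VoxelGrid(keep[labels], grid.spacing, grid.origin,
                     grid.thin_radius_warning)


def _distance_to_foreground(grid: VoxelGrid, point_um) -> float:
    if not grid.occupancy.any():
        return float("inf")
    fg = np.argwhere(grid.occupancy)
    p = np.asarray(point_um, dtype=float)
    d = np.linalg.norm(grid.index_to_world(fg) - p, axis=1)
    return float(d.min())
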