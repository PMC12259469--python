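"""Digital-topology primitives for 3D thinning.

A foreground voxel is *simple* when its deletion changes neither the
26-connectivity of the foreground nor the 6-connectivity of the background.
The local characterization used here: the voxel is simple iff

* the foreground restricted to its 26-neighborhood has exactly one
  26-connected component, and
* the background restricted to its 18-neighborhood has exactly one
  6-connected component that touches a face neighbor of the voxel.

Both numbers are evaluated on the 3x3x3 neighborhood alone, which makes the
test O(1) per voxel; the kernels are numba-compiled and operate on flattened
27-element neighborhoods.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["is_simple_point", "thin_pass", "neighbor_count_26"]


def _build_tables():
    pos = np.array([(dx, dy, dz) for dx in (-1, 0, 1)
                    for dy in (-1, 0, 1) for dz in (-1, 0, 1)], dtype=np.int64)
    n = 27
    center = 13
    adj26 = np.full((n, 26), -1, dtype=np.int64)
    adj6 = np.full((n, 6), -1, dtype=np.int64)
    in18 = np.zeros(n, dtype=np.bool_)
    face6 = np.zeros(n, dtype=np.bool_)
    for a in range(n):
        k26 = k6 = 0
        for b in range(n):
            if a == b:
                continue
            d = np.abs(pos[a] - pos[b])
            if d.max() == 1:
                adj26[a, k26] = b
                k26 += 1
            if d.sum() == 1:
                adj6[a, k6] = b
                k6 += 1
        nz = np.count_nonzero(pos[a])
        in18[a] = (a != center) and nz <= 2 and np.abs(pos[a]).max() == 1 and nz >= 1
        face6[a] = nz == 1 and np.abs(pos[a]).sum() == 1
    return pos, adj26, adj6, in18, face6


_POS, _ADJ26, _ADJ6, _IN18, _FACE6 = _build_tables()
_CENTER = 13


@njit(cache=True)
def _fg_components_26(cube):
    """Number of 26-components of foreground in the punctured neighborhood."""
    visited = np.zeros(27, dtype=np.bool_)
    stack = np.empty(27, dtype=np.int64)
    ncomp = 0
    for s in range(27):
        if s == _CENTER or not cube[s] or visited[s]:
            continue
        ncomp += 1
        top = 0
        stack[top] = s
        top += 1
        visited[s] = True
        while top > 0:
            top -= 1
            v = stack[top]
            for k in range(26):
                w = _ADJ26[v, k]
                if w < 0:
                    break
                if w != _CENTER and cube[w] and not visited[w]:
                    visited[w] = True
                    stack[top] = w
                    top += 1
    return ncomp


@njit(cache=True)
def _bg_components_6_in_18(cube):
    """6-components of background within N18 that touch a face neighbor."""
    visited = np.zeros(27, dtype=np.bool_)
    stack = np.empty(27, dtype=np.int64)
    ncomp = 0
    for s in range(27):
        if not _FACE6[s] or cube[s] or visited[s]:
            continue
        ncomp += 1
        top = 0
        stack[top] = s
        top += 1
        visited[s] = True
        while top > 0:
            top -= 1
            v = stack[top]
            for k in range(6):
                w = _ADJ6[v, k]
                if w < 0:
                    break
                if _IN18[w] and not cube[w] and not visited[w]:
                    visited[w] = True
                    stack[top] = w
                    top += 1
    return ncomp


@njit(cache=True)
def _extract_cube(occ, i, j, k, cube):
    t = 0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            for dz in range(-1, 2):
                cube[t] = occ[i + dx, j + dy, k + dz]
                t += 1


@njit(cache=True)
def _simple_from_cube(cube):
    return _fg_components_26(cube) == 1 and _bg_components_6_in_18(cube) == 1


def is_simple_point(occ: np.ndarray, ijk) -> bool:
    """Whether deleting voxel ``ijk`` preserves local topology.

    ``occ`` must not have foreground on its outermost planes at ``ijk``'s
    neighborhood (callers pad by one voxel).
    """
    i, j, k = (int(v) for v in ijk)
    cube = np.zeros(27, dtype=np.bool_)
    _extract_cube(occ, i, j, k, cube)
    return bool(_simple_from_cube(cube))


@njit(cache=True)
def neighbor_count_26(occ, i, j, k):
    c = 0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            for dz in range(-1, 2):
                if dx == 0 and dy == 0 and dz == 0:
                    continue
                if occ[i + dx, j + dy, k + dz]:
                    c += 1
    return c


@njit(cache=True)
def thin_pass(occ, protected, cand_i, cand_j, cand_k):
    """Sequentially delete simple, non-protected, non-endpoint candidates.

    Candidates are visited in the given order; the simple-point test is
    evaluated against the *current* state, so every individual deletion
    preserves topology.  Returns the number of voxels deleted.
    """
    cube = np.zeros(27, dtype=np.bool_)
    deleted = 0
    for t in range(cand_i.shape[0]):
        i, j, k = cand_i[t], cand_j[t], cand_k[t]
        if not occ[i, j, k] or protected[i, j, k]:
            continue
        nc = neighbor_count_26(occ, i, j, k)
        if nc <= 1:   # endpoint (or isolated voxel): never deleted
            continue
        _extract_cube(occ, i, j, k, cube)
        if _simple_from_cube(cube):
            occ[i, j, k] = False
            deleted += 1
    return deleted
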