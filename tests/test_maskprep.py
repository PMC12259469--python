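"""Morphological closing and component hygiene against brute-force references."""

import numpy as np
import pytest
from scipy import ndimage

from coromorph import maskprep
from coromorph import vesselgen as vg
from coromorph.grid import VoxelGrid
from tests.conftest import random_blob_grid


def brute_force_close(occ: np.ndarray, element: np.ndarray) -> np.ndarray:
    """Closing via explicit Minkowski shifts (independent of scipy morphology)."""
    pad = tuple((s // 2, s // 2) for s in element.shape)
    a = np.pad(occ, pad)
    offs = np.argwhere(element) - np.asarray(element.shape) // 2
    dil = np.zeros_like(a)
    for o in offs:
        dil |= np.roll(a, o, axis=(0, 1, 2))
    ero = np.ones_like(a)
    for o in offs:
        ero &= np.roll(dil, -o, axis=(0, 1, 2))
    sl = tuple(slice(p[0], a.shape[i] - p[1]) for i, p in enumerate(pad))
    return ero[sl]


class TestBinaryClose:
    def test_matches_brute_force_on_random_grids(self, rng):
        el = maskprep.ball_element(2)
        for _ in range(5):
            g = random_blob_grid(rng, shape=(18, 18, 18), p=0.3)
            got = maskprep.binary_close(g, 2).occupancy
            want = brute_force_close(g.occupancy, el)
            np.testing.assert_array_equal(got, want)

    def test_extensive_and_idempotent(self, rng):
        for _ in range(5):
            g = random_blob_grid(rng, shape=(16, 16, 16), p=0.25)
            once = maskprep.binary_close(g, 2)
            twice = maskprep.binary_close(once, 2)
            assert np.all(once.occupancy >= g.occupancy)          # extensive
            np.testing.assert_array_equal(once.occupancy, twice.occupancy)

    def test_convex_solid_unchanged(self):
        occ = np.zeros((12, 12, 12), bool)
        occ[3:9, 3:9, 3:9] = True
        g = VoxelGrid(occ, (1, 1, 1))
        np.testing.assert_array_equal(
            maskprep.binary_close(g, 2).occupancy, occ)

    def test_empty_grid_maps_to_empty(self):
        g = VoxelGrid(np.zeros((8, 8, 8), bool), (1, 1, 1))
        assert not maskprep.binary_close(g, 2).occupancy.any()

    def test_fills_interior_hole_deletions(self):
        spec = vg.straight_tube_spec(40, 6.0)
        clean, _ = vg.voxelize(spec, spacing=(1, 1, 1))
        holey, _ = vg.voxelize(spec, spacing=(1, 1, 1),
                               noise=vg.NoiseSpec(hole_rate=0.02, hole_size=2,
                                                  seed=4))
        closed = maskprep.binary_close(holey, 2)
        # equal to the noise-free tube within a one-voxel surface shell
        interior = ndimage.binary_erosion(clean.occupancy)
        assert np.all(closed.occupancy[interior])

    def test_never_creates_interior_cavities(self, rng):
        s6 = ndimage.generate_binary_structure(3, 1)
        for _ in range(5):
            g = random_blob_grid(rng, shape=(14, 14, 14), p=0.4)
            def cavities(occ):
                bg = np.pad(~occ, 1, constant_values=True)
                return ndimage.label(bg, structure=s6)[1] - 1
            closed = maskprep.binary_close(g, 1)
            assert cavities(closed.occupancy) <= cavities(g.occupancy)

    def test_rejects_nonpositive_radius(self):
        g = VoxelGrid(np.ones((4, 4, 4), bool), (1, 1, 1))
        with pytest.raises(ValueError):
            maskprep.binary_close(g, 0)


def blobs_grid():
    occ = np.zeros((30, 30, 30), bool)
    occ[2:8, 2:8, 2:8] = True          # 216 voxels
    occ[12:16, 12:16, 12:16] = True    # 64 voxels
    occ[22:25, 22:25, 22:25] = True    # 27 voxels
    return VoxelGrid(occ, (1, 1, 1)), [216, 64, 27]


class TestKeepComponents:
    def test_root_blob_survives_size_filter(self):
        g, sizes = blobs_grid()
        out = maskprep.keep_components(g, min_voxels=100, keep_points=[(5, 5, 5)])
        assert out.occupancy.sum() == 216

    def test_min_voxels_zero_is_identity(self):
        g, _ = blobs_grid()
        out = maskprep.keep_components(g, min_voxels=0)
        np.testing.assert_array_equal(out.occupancy, g.occupancy)

    def test_surviving_count_is_sum_of_retained_blobs(self):
        g, sizes = blobs_grid()
        out = maskprep.keep_components(g, min_voxels=50)
        assert out.occupancy.sum() == sum(s for s in sizes if s >= 50)

    def test_background_keep_point_raises_with_coordinate(self):
        g, _ = blobs_grid()
        with pytest.raises(ValueError, match="28"):
            maskprep.keep_components(g, keep_points=[(28.0, 28.0, 28.0)])

    def test_keep_point_rescues_small_blob(self):
        g, sizes = blobs_grid()
        out = maskprep.keep_components(g, min_voxels=1000,
                                       keep_points=[(23, 23, 23)])
        assert out.occupancy.sum() == 27
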