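"""Phantom generator: junction counts, determinism, raster fidelity."""

import numpy as np
import pytest

from coromorph import vesselgen as vg


def count_junctions_brute_force(spec: vg.TreeSpec) -> int:
    """Independent junction census: scan for points where >= 2 child
    polylines attach to the same parent location."""
    joints = {}
    for seg in spec.segments:
        if seg.parent_id is not None:
            joints.setdefault(tuple(np.round(seg.points[0], 6)), 0)
            joints[tuple(np.round(seg.points[0], 6))] += 1
    return sum(1 for c in joints.values() if c >= 2)


class TestGenerateTreeSpec:
    def test_unbranched_degenerate_case(self):
        spec = vg.generate_tree_spec(0, seed=1)
        assert len(spec.segments) == 1
        assert count_junctions_brute_force(spec) == 0

    def test_single_bifurcation_is_y(self):
        spec = vg.generate_tree_spec(1, seed=1)
        gt = vg.ground_truth_from_spec(spec)
        assert gt.n_branch_points == 1
        assert len(spec.segments) == 3

    def test_junction_count_and_repeatability(self):
        a = vg.generate_tree_spec(7, seed=42)
        b = vg.generate_tree_spec(7, seed=42)
        assert count_junctions_brute_force(a) == 7
        assert vg.ground_truth_from_spec(a).n_branch_points == 7
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_array_equal(sa.points, sb.points)
            np.testing.assert_array_equal(sa.radii, sb.radii)

    def test_trifurcation_counts_once(self):
        spec = vg.generate_tree_spec(1, seed=3, children_per_junction=3)
        gt = vg.ground_truth_from_spec(spec)
        assert gt.n_branch_points == 1
        assert len(spec.segments) == 4

    @pytest.mark.parametrize("kwargs", [
        dict(n_bifurcations=-1),
        dict(n_bifurcations=1, radius_root=0.0),
        dict(n_bifurcations=1, radius_decay=0.0),
        dict(n_bifurcations=1, radius_decay=1.5),
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            vg.generate_tree_spec(**{"seed": 0, **kwargs})

    def test_radius_decay_per_generation(self):
        spec = vg.generate_tree_spec(2, seed=5, radius_root=10.0,
                                     radius_decay=0.8)
        by_id = {s.segment_id: s for s in spec.segments}
        for s in spec.segments:
            if s.parent_id is not None:
                assert s.radii[0] == pytest.approx(
                    by_id[s.parent_id].radii[0] * 0.8)


class TestVoxelize:
    def test_straight_tube_cross_section_area(self):
        # analytic cross-section pi*r^2 vs voxel count, one-voxel shell band
        spec = vg.straight_tube_spec(40, 10.0, direction=(1, 0, 0))
        grid, _ = vg.voxelize(spec, spacing=(1, 1, 1))
        i_mid = grid.occupancy.shape[0] // 2
        count = grid.occupancy[i_mid].sum()
        area = np.pi * 10.0 ** 2
        band = 2 * np.pi * 10.0 + 4  # one-voxel perimeter shell
        assert abs(count - area) <= band

    def test_volume_ratio_against_analytic(self):
        r = 6.5   # >= 3 voxels on the coarsest (2 µm) axis
        spec = vg.straight_tube_spec(80, r)
        grid, _ = vg.voxelize(spec)
        analytic = np.pi * r ** 2 * 80 + 4 / 3 * np.pi * r ** 3  # capsule
        ratio = grid.occupancy.sum() * grid.voxel_volume_um3 / analytic
        assert 0.9 <= ratio <= 1.1

    def test_border_planes_empty(self):
        spec = vg.generate_tree_spec(2, seed=7)
        grid, _ = vg.voxelize(spec)
        occ = grid.occupancy
        assert not occ[0].any() and not occ[-1].any()
        assert not occ[:, 0].any() and not occ[:, -1].any()
        assert not occ[:, :, 0].any() and not occ[:, :, -1].any()

    def test_noise_is_seeded_deterministic(self):
        spec = vg.generate_tree_spec(3, seed=11)
        noise = vg.NoiseSpec(hole_rate=0.02, seed=99)
        g1, _ = vg.voxelize(spec, noise=noise)
        g2, _ = vg.voxelize(spec, noise=vg.NoiseSpec(hole_rate=0.02, seed=99))
        np.testing.assert_array_equal(g1.occupancy, g2.occupancy)
        g3, _ = vg.voxelize(spec, noise=vg.NoiseSpec(hole_rate=0.02, seed=100))
        assert not np.array_equal(g1.occupancy, g3.occupancy)

    def test_thin_radius_warning_flag(self):
        spec = vg.straight_tube_spec(30, 1.2)
        grid, _ = vg.voxelize(spec, spacing=(0.97, 0.97, 2.0))
        assert grid.thin_radius_warning
        spec2 = vg.straight_tube_spec(30, 8.0)
        grid2, _ = vg.voxelize(spec2, spacing=(0.97, 0.97, 2.0))
        assert not grid2.thin_radius_warning

    def test_invalid_spacing(self):
        spec = vg.straight_tube_spec(30, 4.0)
        with pytest.raises(ValueError):
            vg.voxelize(spec, spacing=(1, 0, 1))


class TestGroundTruth:
    @pytest.mark.parametrize("seed", range(6))
    def test_self_consistency(self, seed):
        spec = vg.generate_tree_spec(4, seed=seed)
        gt = vg.ground_truth_from_spec(spec)
        d = gt.root_to_branch_distances
        assert gt.first_branch_distance == pytest.approx(d.min())
        assert np.all(d > 0)
        assert np.all(np.diff(d) >= 0)
        total = sum(s.length_um for s in spec.segments)
        assert d.max() <= total

    def test_station_diameters_follow_radius_profile(self):
        spec = vg.straight_tube_spec(500, 20.0, taper_to=10.0)
        gt = vg.ground_truth_from_spec(spec, stations_um=[100, 250, 400, 600])
        assert gt.station_diameters[100.0] == pytest.approx(2 * 18.0)
        assert gt.station_diameters[250.0] == pytest.approx(2 * 15.0)
        assert gt.station_diameters[400.0] == pytest.approx(2 * 12.0)
        assert np.isnan(gt.station_diameters[600.0])
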