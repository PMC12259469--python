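"""Skeleton graphs: topology metrics, pruning, SWC interchange."""

import numpy as np
import pytest

from coromorph import treegraph
from coromorph.skeletonize import SkeletonVoxels


def skel_from_voxels(voxels, shape=(60, 40, 5), roots=(), spacing=(1, 1, 1)):
    mask = np.zeros(shape, bool)
    for v in voxels:
        mask[v] = True
    return SkeletonVoxels(mask, [tuple(r) for r in roots], spacing, (0, 0, 0))


def straight_path(n=50):
    return [(i + 2, 3, 2) for i in range(n)]


def y_voxels():
    stem = [(i, 10, 2) for i in range(2, 12)]
    arm1 = [(12 + i, 10 + i, 2) for i in range(8)]
    arm2 = [(12 + i, 10 - i, 2) for i in range(8)]
    return stem + arm1 + arm2


class TestBuildGraph:
    def test_simple_path(self):
        g = treegraph.build_graph(skel_from_voxels(straight_path(),
                                                   roots=[(2, 3, 2)]))
        kinds = [g.g.nodes[n]["kind"] for n in g.g.nodes]
        assert g.g.number_of_edges() == 1
        assert sorted(kinds) == ["end", "root"]
        assert not g.has_cycles

    def test_y_topology(self):
        g = treegraph.build_graph(skel_from_voxels(y_voxels(),
                                                   roots=[(2, 10, 2)]))
        assert len(g.branch_nodes()) == 1
        assert sum(1 for n in g.g.nodes if g.g.degree(n) == 1) == 3
        assert g.g.number_of_edges() == 3

    def test_voxel_ring_flags_cycle_and_returns(self):
        ring = set()
        for t in np.linspace(0, 2 * np.pi, 200):
            ring.add((int(15 + 8 * np.cos(t)), int(15 + 8 * np.sin(t)), 2))
        g = treegraph.build_graph(skel_from_voxels(sorted(ring)))
        assert g.has_cycles
        assert g.g.number_of_edges() >= 1

    def test_empty_skeleton_rejected(self):
        with pytest.raises(ValueError):
            treegraph.build_graph(skel_from_voxels([]))

    def test_arc_length_at_least_chord(self):
        g = treegraph.build_graph(skel_from_voxels(y_voxels(),
                                                   roots=[(2, 10, 2)]))
        for *_, d in g.g.edges(data=True):
            chord = np.linalg.norm(d["polyline"][0] - d["polyline"][-1])
            assert d["length_um"] >= chord - 1e-9


class TestPruneSpurs:
    def test_zero_threshold_is_identity(self):
        g = treegraph.build_graph(skel_from_voxels(y_voxels(),
                                                   roots=[(2, 10, 2)]))
        out = treegraph.prune_spurs(g, 0.0)
        assert len(out.branch_nodes()) == len(g.branch_nodes())
        assert out.total_length_um() == pytest.approx(g.total_length_um())

    def test_hair_spur_removed(self):
        vox = straight_path(30) + [(15, 3 + i, 2) for i in range(1, 5)]  # 4 µm hair
        g = treegraph.build_graph(skel_from_voxels(vox, roots=[(2, 3, 2)]))
        assert len(g.branch_nodes()) == 1
        out = treegraph.prune_spurs(g, 10.0)
        assert len(out.branch_nodes()) == 0

    def test_long_arms_survive(self):
        g = treegraph.build_graph(skel_from_voxels(y_voxels(),
                                                   roots=[(2, 10, 2)]))
        out = treegraph.prune_spurs(g, 5.0)
        assert len(out.branch_nodes()) == 1

    def test_never_increases_branch_count(self, phantom_suite_clean):
        for _, metrics, _ in phantom_suite_clean:
            g = metrics.graph
            for thr in (5.0, 20.0, 60.0):
                out = treegraph.prune_spurs(g, thr)
                assert len(out.branch_nodes()) <= len(g.branch_nodes())


class TestDistances:
    def test_unbranched_tube_has_no_landmark(self):
        g = treegraph.build_graph(skel_from_voxels(straight_path(),
                                                   roots=[(2, 3, 2)]))
        root = g.root_ids[0]
        assert treegraph.count_branch_points(g, root) == 0
        assert treegraph.distances_to_branch_points(g, root) == []
        with pytest.raises(ValueError, match="no landmark"):
            treegraph.landmark_segment_length(g, root)

    def test_y_stem_length(self):
        g = treegraph.build_graph(skel_from_voxels(y_voxels(),
                                                   roots=[(2, 10, 2)]))
        root = g.root_ids[0]
        d = treegraph.distances_to_branch_points(g, root)
        assert len(d) == 1
        assert d[0][1] == pytest.approx(10.0, abs=1.5)   # 10-voxel stem
        assert treegraph.landmark_segment_length(g, root) == d[0][1]

    def test_unknown_root_raises(self):
        g = treegraph.build_graph(skel_from_voxels(straight_path()))
        with pytest.raises(KeyError):
            treegraph.count_branch_points(g, 10 ** 6)

    def test_cycle_component_raises(self):
        ring = set()
        for t in np.linspace(0, 2 * np.pi, 200):
            ring.add((int(15 + 8 * np.cos(t)), int(15 + 8 * np.sin(t)), 2))
        g = treegraph.build_graph(skel_from_voxels(sorted(ring)))
        node = next(iter(g.g.nodes))
        with pytest.raises(treegraph.CycleError):
            treegraph.distances_to_branch_points(g, node)

    def test_distances_sorted_nonnegative(self, phantom_suite_clean):
        for _, metrics, _ in phantom_suite_clean:
            d = metrics.branch_distances_um
            assert all(x >= 0 for x in d)
            assert d == sorted(d)

    def test_explicit_landmark_matches_distance_list(self, phantom_suite_clean):
        gt, metrics, spec = phantom_suite_clean[4]
        g = metrics.graph
        pairs = treegraph.distances_to_branch_points(g, metrics.root_node)
        assert len(pairs) >= 2
        node, dist = pairs[-1]
        assert treegraph.landmark_segment_length(g, metrics.root_node,
                                                 node) == dist


class TestRecoveryAgainstGroundTruth:
    def test_branch_point_counts_match(self, phantom_suite_clean):
        for gt, metrics, _ in phantom_suite_clean:
            assert metrics.n_branch_points == gt.n_branch_points

    def test_first_branch_distance_recovery(self, phantom_suite_clean):
        for gt, metrics, _ in phantom_suite_clean:
            tol = max(2 * 2.0, 0.02 * gt.first_branch_distance)  # 2 coarse voxels
            assert metrics.first_branch_um == pytest.approx(
                gt.first_branch_distance, abs=tol)


class TestSWC:
    def test_round_trip_preserves_graph(self, phantom_suite_clean, tmp_path):
        _, metrics, _ = phantom_suite_clean[2]
        g = metrics.graph
        path = tmp_path / "tree.swc"
        treegraph.write_swc(g, path)
        back = treegraph.read_swc(path)
        assert len(back.branch_nodes()) == len(g.branch_nodes())
        assert back.total_length_um() == pytest.approx(g.total_length_um(),
                                                       rel=1e-6)
        radii_out = sorted(round(float(g.g.nodes[n].get("radius") or 1.0), 4)
                           for n in g.g.nodes)
        radii_in = sorted(round(float(back.g.nodes[n]["radius"]), 4)
                          for n in back.g.nodes)
        assert radii_in == radii_out

    def test_hand_written_two_segment_path(self, tmp_path):
        p = tmp_path / "hand.swc"
        p.write_text("1 1 0 0 0 1.0 -1\n"
                     "2 0 3 4 0 1.0 1\n"
                     "3 0 3 4 12 1.0 2\n")
        g = treegraph.read_swc(p)
        assert g.total_length_um() == pytest.approx(5.0 + 12.0)
        assert len(g.branch_nodes()) == 0

    def test_forward_parent_reference_accepted(self, tmp_path):
        p = tmp_path / "fwd.swc"
        p.write_text("1 0 0 0 0 1.0 2\n"
                     "2 1 1 0 0 1.0 -1\n")
        g = treegraph.read_swc(p)
        assert g.total_length_um() == pytest.approx(1.0)

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 1.0 -1\nnot a line\n")
        with pytest.raises(ValueError, match="line 2"):
            treegraph.read_swc(p)
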