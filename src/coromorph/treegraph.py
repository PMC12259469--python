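"""Rooted spatial graphs from skeleton voxels: branch-point topology,
geodesic distances, spur pruning, and SWC interchange.

A :class:`SkeletonGraph` keeps junctions, endpoints and roots as graph nodes
and the runs of degree-2 skeleton voxels as edge polylines with anisotropic
arc lengths.  26-adjacent junction-voxel clusters collapse to a single
branch node at their centroid, so a k-furcation counts once regardless of k.

Arc lengths are measured on lightly smoothed polylines (small moving average
with anchored endpoints): raw voxel-center paths overestimate oblique curve
lengths by up to ~8% through stair-stepping, and the smoothing removes that
digitization bias without introducing spline parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import ndimage

__all__ = [
    "SkeletonGraph", "build_graph", "prune_spurs", "collapse_small_cycles",
    "count_branch_points", "distances_to_branch_points",
    "landmark_segment_length", "write_swc", "read_swc", "CycleError",
]

_OFFSETS = np.array([(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                     for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)])


class CycleError(RuntimeError):
    """Raised when an operation requires a tree but the component has cycles."""


@dataclass
class SkeletonGraph:
    """Spatial graph over skeleton voxels.

    ``g`` is a ``networkx.MultiGraph``; node attributes: ``pos`` (µm),
    ``kind`` in {root, branch, end, slab}, optional ``radius`` (µm).  Edge
    attributes: ``length_um``, ``polyline`` ((N, 3) µm, oriented from
    ``nodes[0]`` to ``nodes[1]``), optional ``point_radii``.
    """
    g: nx.MultiGraph
    root_ids: list[int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    has_cycles: bool = False

    def component_of(self, node_id: int) -> set[int]:
        return nx.node_connected_component(self.g, node_id)

    def branch_nodes(self, component: set[int] | None = None) -> list[int]:
        nodes = component if component is not None else self.g.nodes
        return [n for n in nodes if self.g.degree(n) >= 3]

    def total_length_um(self) -> float:
        return float(sum(d["length_um"] for *_, d in self.g.edges(data=True)))

    def refresh_kinds(self) -> None:
        for n in self.g.nodes:
            if n in self.root_ids:
                self.g.nodes[n]["kind"] = "root"
            else:
                deg = self.g.degree(n)
                self.g.nodes[n]["kind"] = ("branch" if deg >= 3
                                           else "end" if deg <= 1 else "slab")


def _polyline_length(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def _smooth_polyline(points: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average smoothing with anchored endpoints (digitization de-bias)."""
    n = len(points)
    if n <= 2 or window <= 1:
        return points
    half = window // 2
    out = points.copy()
    for t in range(1, n - 1):
        a = max(0, t - half)
        b = min(n, t + half + 1)
        out[t] = points[a:b].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# Graph construction


def build_graph(skel) -> SkeletonGraph:
    """Convert :class:`~coromorph.skeletonize.SkeletonVoxels` to a graph.

    Every skeleton voxel lands in exactly one node cluster or one edge
    polyline; junction clusters collapse to centroid nodes.  Cycles (e.g.
    toroidal skeletons) are flagged on the result, never an error here.
    """
    mask = skel.mask
    spacing = np.asarray(skel.spacing)
    origin = np.asarray(skel.origin)
    if not mask.any():
        raise ValueError("empty skeleton")

    kernel = np.ones((3, 3, 3), dtype=np.uint8)
    kernel[1, 1, 1] = 0
    ncount = ndimage.convolve(mask.astype(np.uint8), kernel, mode="constant")
    ncount[~mask] = 0

    node_mask = mask & (ncount != 2)
    for r in skel.roots:
        node_mask[r] = True

    # absorb slab voxels squeezed between voxels of one junction cluster
    labels, n_clusters = ndimage.label(node_mask, structure=np.ones((3, 3, 3)))
    changed = True
    while changed:
        changed = False
        slabs = np.argwhere(mask & ~node_mask)
        for v in slabs:
            labs = set()
            for off in _OFFSETS:
                w = v + off
                if np.all(w >= 0) and np.all(w < mask.shape) and node_mask[tuple(w)]:
                    labs.add(labels[tuple(w)])
            if len(labs) == 1:
                nb = [tuple(v + off) for off in _OFFSETS
                      if np.all(v + off >= 0) and np.all(v + off < mask.shape)
                      and mask[tuple(v + off)]]
                in_cluster = sum(node_mask[w] for w in nb)
                if in_cluster >= 2:
                    node_mask[tuple(v)] = True
                    labels[tuple(v)] = labs.pop()
                    changed = True

    labels, n_clusters = ndimage.label(node_mask, structure=np.ones((3, 3, 3)))

    g = nx.MultiGraph()
    edt = getattr(skel, "edt_um", None)
    cluster_voxels: dict[int, np.ndarray] = {}
    for lab in range(1, n_clusters + 1):
        vox = np.argwhere(labels == lab)
        cluster_voxels[lab] = vox
        if edt is not None and len(vox) > 1:
            # junction clusters anchor at the maximal-inscribed-sphere center
            best = vox[np.argmax(edt[vox[:, 0], vox[:, 1], vox[:, 2]])]
            pos = best * spacing + origin
        else:
            pos = (vox * spacing + origin).mean(axis=0)
        g.add_node(lab, pos=pos, voxels=vox)

    shape = np.asarray(mask.shape)

    def neighbors(v):
        out = []
        for off in _OFFSETS:
            w = v + off
            if np.all(w >= 0) and np.all(w < shape) and mask[tuple(w)]:
                out.append(tuple(w))
        return out

    visited = np.zeros(mask.shape, dtype=bool)

    def add_edge(na, nb, voxel_path):
        pts = np.asarray(voxel_path) * spacing + origin
        pts = _smooth_polyline(pts)
        poly = np.vstack([g.nodes[na]["pos"], pts, g.nodes[nb]["pos"]])
        keep = np.ones(len(poly), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(poly, axis=0), axis=1) > 1e-12
        poly = poly[keep]
        g.add_edge(na, nb, nodes=(na, nb), polyline=poly,
                   length_um=_polyline_length(poly),
                   voxels=np.asarray(voxel_path, dtype=int))

    direct_pairs: set[tuple[int, int]] = set()
    for lab, vox in cluster_voxels.items():
        for v in vox:
            for w in neighbors(v):
                if node_mask[w]:
                    other = labels[w]
                    if other != lab:
                        pair = (min(lab, other), max(lab, other))
                        if pair not in direct_pairs:
                            direct_pairs.add(pair)
                            add_edge(lab, other, [tuple(v), w])
                    continue
                if visited[w]:
                    continue
                # walk the slab run
                path = [tuple(v), w]
                visited[w] = True
                prev, cur = tuple(v), w
                while True:
                    nbrs = [u for u in neighbors(np.asarray(cur)) if u != prev]
                    nxt = None
                    for u in nbrs:
                        if node_mask[u]:
                            nxt = u
                            break
                    if nxt is None:
                        slab_next = [u for u in nbrs if not visited[u]]
                        if not slab_next:
                            break
                        nxt = slab_next[0]
                    path.append(nxt)
                    if node_mask[nxt]:
                        break
                    visited[nxt] = True
                    prev, cur = cur, nxt
                end = path[-1]
                if node_mask[end]:
                    add_edge(lab, labels[end], path)
                else:  # dead-ends into visited slab: degenerate, treat as endpoint
                    add_edge(lab, lab, path)

    # pure rings with no junction/endpoint voxels
    remaining = np.argwhere(mask & ~node_mask & ~visited)
    while len(remaining):
        start = tuple(remaining[np.lexsort((remaining[:, 0], remaining[:, 1],
                                            remaining[:, 2]))][0])
        lab = g.number_of_nodes() + 1
        node_mask[start] = True
        labels[start] = lab
        pos = np.asarray(start) * spacing + origin
        g.add_node(lab, pos=pos, voxels=np.asarray([start]))
        nbrs = neighbors(np.asarray(start))
        path = [start]
        prev, cur = start, nbrs[0]
        while cur != start:
            visited[cur] = True
            path.append(cur)
            nxt = [u for u in neighbors(np.asarray(cur)) if u != prev]
            prev, cur = cur, nxt[0]
        path.append(start)
        add_edge(lab, lab, path)
        remaining = np.argwhere(mask & ~node_mask & ~visited)

    root_ids = sorted({int(labels[r]) for r in skel.roots})
    # staircase voxels (3 neighbors on a simple 26-path) produce spurious
    # degree-2 nodes that would fragment terminal branches; dissolve them
    _dissolve_degree2(g, set(root_ids))
    n_comp = nx.number_connected_components(g)
    has_cycles = g.number_of_edges() - g.number_of_nodes() + n_comp > 0
    sg = SkeletonGraph(g, root_ids, tuple(skel.spacing), tuple(skel.origin),
                       has_cycles)
    sg.refresh_kinds()
    return sg


def _dissolve_degree2(g: nx.MultiGraph, protected: set) -> None:
    """Merge the two edges of every non-protected degree-2 node, in place."""
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if n in protected or g.degree(n) != 2:
                continue
            edges = list(g.edges(n, keys=True, data=True))
            if len(edges) != 2:       # self-loop at n
                continue
            (u1, v1, k1, d1), (u2, v2, k2, d2) = edges
            o1 = v1 if u1 == n else u1
            o2 = v2 if u2 == n else u2
            p1 = d1["polyline"] if d1["nodes"][1] == n else d1["polyline"][::-1]
            p2 = d2["polyline"] if d2["nodes"][0] == n else d2["polyline"][::-1]
            r1 = d1.get("point_radii")
            r2 = d2.get("point_radii")
            radii = None
            if r1 is not None and r2 is not None:
                r1 = r1 if d1["nodes"][1] == n else r1[::-1]
                r2 = r2 if d2["nodes"][0] == n else r2[::-1]
                radii = np.concatenate([r1, r2[1:]])
            g.remove_edge(u1, v1, k1)
            g.remove_edge(u2, v2, k2)
            g.remove_node(n)
            g.add_edge(o1, o2, nodes=(o1, o2), polyline=np.vstack([p1, p2[1:]]),
                       length_um=d1["length_um"] + d2["length_um"],
                       voxels=None, point_radii=radii)
            changed = True


# ---------------------------------------------------------------------------
# Pruning and morphometry


def prune_spurs(graph: SkeletonGraph, min_length_um: float,
                local_radius_factor: float | None = None) -> SkeletonGraph:
    """Iteratively drop terminal edges shorter than the threshold.

    Terminal edges not containing a root are removed until a fixpoint;
    non-root nodes whose degree drops to 2 are dissolved and their edges
    merged with arc lengths added.  Never increases the branch count.

    With ``local_radius_factor`` the threshold for each terminal edge is
    ``factor``·(EDT radius of its attachment node) where node radii are
    available — thinning spurs scale with the local tube caliber, and a
    global threshold sized for the largest junction would swallow genuine
    short arms of small distal junctions.  ``min_length_um`` then acts as
    the fallback where no radius is attached.
    """
    if min_length_um < 0:
        raise ValueError("min_length_um must be >= 0")
    g = graph.g.copy()
    roots = set(graph.root_ids)

    def threshold(attach_node) -> float:
        if local_radius_factor is not None:
            r = g.nodes[attach_node].get("radius")
            if r:
                return local_radius_factor * float(r)
        return min_length_um

    changed = True
    while changed:
        changed = False
        for u, v, k, d in list(g.edges(keys=True, data=True)):
            if u == v:
                continue
            leaf = attach = None
            if g.degree(u) == 1 and u not in roots:
                leaf, attach = u, v
            elif g.degree(v) == 1 and v not in roots:
                leaf, attach = v, u
            if leaf is not None and d["length_um"] < threshold(attach):
                g.remove_edge(u, v, k)
                g.remove_node(leaf)
                changed = True
        if changed:
            _dissolve_degree2(g, roots)
    _dissolve_degree2(g, roots)

    n_comp = nx.number_connected_components(g) if g.number_of_nodes() else 0
    has_cycles = g.number_of_edges() - g.number_of_nodes() + n_comp > 0
    out = SkeletonGraph(g, [r for r in graph.root_ids if g.has_node(r)],
                        graph.spacing, graph.origin, has_cycles)
    out.refresh_kinds()
    return out


def merge_junction_complexes(graph: SkeletonGraph) -> SkeletonGraph:
    """Fuse branch nodes whose separation is below the sum of their radii.

    A single anatomical bifurcation can fragment into a chain of digital
    forks inside the junction merge zone (the skeleton splits in stages while
    the lumens of the arms still overlap).  Branch nodes joined by an edge
    shorter than the sum of their inscribed-sphere radii belong to one
    junction; they are contracted onto the node with the larger radius.
    Genuine neighboring junctions sit several radii apart and are untouched.
    Requires node ``radius`` attributes; nodes without radii are skipped.
    """
    g = graph.g.copy()
    roots = set(graph.root_ids)
    changed = True
    while changed:
        changed = False
        for u, v, k, d in list(g.edges(keys=True, data=True)):
            if u == v or g.degree(u) < 3 or g.degree(v) < 3:
                continue
            ru = g.nodes[u].get("radius")
            rv = g.nodes[v].get("radius")
            if not ru or not rv:
                continue
            if d["length_um"] >= ru + rv:
                continue
            keep, drop = (u, v) if (ru, u not in roots) >= (rv, v not in roots) else (v, u)
            if drop in roots:
                keep, drop = drop, keep
            g.remove_edge(u, v, k)
            for a, b, kk, dd in list(g.edges(drop, keys=True, data=True)):
                other = b if a == drop else a
                if other == drop:
                    continue
                poly = dd["polyline"] if dd["nodes"][0] == other else dd["polyline"][::-1]
                poly = np.vstack([poly[:-1], np.asarray(g.nodes[keep]["pos"])[None, :]])
                radii = dd.get("point_radii")
                if radii is not None:
                    radii = radii if dd["nodes"][0] == other else radii[::-1]
                g.add_edge(other, keep, nodes=(other, keep), polyline=poly,
                           length_um=_polyline_length(poly), voxels=None,
                           point_radii=radii)
            g.remove_node(drop)
            changed = True
            break
    n_comp = nx.number_connected_components(g) if g.number_of_nodes() else 0
    out = SkeletonGraph(g, [r for r in graph.root_ids if g.has_node(r)],
                        graph.spacing, graph.origin,
                        g.number_of_edges() - g.number_of_nodes() + n_comp > 0)
    out.refresh_kinds()
    return out


def refine_junctions(graph: SkeletonGraph, fit_length_um: float = 25.0,
                     trim_factor: float = 2.0) -> None:
    """Relocate branch nodes to the intersection of extrapolated arms, in place.

    The medial axis of merging tubes forks up to ~r/sin(θ/2) distal to the
    geometric junction (the arms stay merged while their lumens overlap), so
    raw skeleton branch nodes are biased away from the root.  For each
    branch node the incident centerlines are line-fit over a window beyond
    the merge zone (arc length between ``trim_factor``·radius and
    +``fit_length_um`` from the node) and the node is moved to the
    least-squares intersection point of those lines; incident polylines are
    trimmed back accordingly and arc lengths recomputed.  Nodes whose arms
    are too short to fit, or whose correction exceeds 3 radii, are left
    untouched.
    """
    g = graph.g
    for n in list(g.nodes):
        if g.degree(n) < 3:
            continue
        r = float(g.nodes[n].get("radius") or 0.0)
        if r <= 0:
            r = float(np.mean(graph.spacing)) * 2.0
        trim = trim_factor * r
        old = np.asarray(g.nodes[n]["pos"], dtype=float)
        fits, edits = [], []
        ok = True
        for u, v, k, d in g.edges(n, keys=True, data=True):
            if u == v:
                ok = False
                break
            poly = d["polyline"] if d["nodes"][0] == n else d["polyline"][::-1]
            s = np.concatenate([[0.0], np.cumsum(
                np.linalg.norm(np.diff(poly, axis=0), axis=1))])
            win = (s >= trim) & (s <= trim + fit_length_um)
            if win.sum() >= 2:
                pts = poly[win]
                mean = pts.mean(axis=0)
                _, _, vt = np.linalg.svd(pts - mean)
                direction = vt[0]
                if np.dot(direction, mean - old) < 0:
                    direction = -direction
                fits.append((mean, direction))
            elif s[-1] > trim:
                direction = poly[-1] - old
                nrm = np.linalg.norm(direction)
                if nrm == 0:
                    ok = False
                    break
                fits.append((poly[-1], direction / nrm))
            else:
                ok = False
                break
            edits.append((u, v, k, d, s))
        if not ok or len(fits) < 3:
            continue
        # least-squares point closest to all fitted lines
        A = np.zeros((3, 3))
        b = np.zeros(3)
        for mean, direction in fits:
            P = np.eye(3) - np.outer(direction, direction)
            A += P
            b += P @ mean
        try:
            p_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue
        if np.linalg.norm(p_new - old) > 3.0 * r:
            continue
        g.nodes[n]["pos"] = p_new
        for u, v, k, d, s in edits:
            from_n = d["nodes"][0] == n
            poly = d["polyline"] if from_n else d["polyline"][::-1]
            keep = s >= trim
            if keep.sum() == 0:
                keep[-1] = True
            new_poly = np.vstack([p_new[None, :], poly[keep]])
            radii = d.get("point_radii")
            if radii is not None:
                rr = radii if from_n else radii[::-1]
                new_r = np.concatenate([[rr[0]], rr[keep]])
                d["point_radii"] = new_r if from_n else new_r[::-1]
            d["polyline"] = new_poly if from_n else new_poly[::-1]
            d["length_um"] = _polyline_length(new_poly)


def collapse_small_cycles(graph: SkeletonGraph,
                          max_length_um: float) -> SkeletonGraph:
    """Contract graph cycles shorter than ``max_length_um`` into one node.

    Where two tubes diverge after a junction, the rasterized surfaces can
    stay intermittently 26-adjacent, leaving junction-scale digital handles
    that the topology-preserving thinning faithfully keeps.  Such cycles
    (parallel edges, short self-loops, short cycle-basis loops) are junction
    artifacts, not anatomy; their nodes merge into a single branch node at
    the mean position.  Genuine long cycles are left in place and stay
    flagged on the graph.
    """
    g = graph.g.copy()
    roots = set(graph.root_ids)

    def contract(keep: int, drop: int) -> None:
        if drop in roots:
            roots.discard(drop)
            roots.add(keep)
        # anchor at the node with the larger inscribed sphere — averaging
        # positions drifts junctions away from the medial axis
        rk = g.nodes[keep].get("radius") or 0.0
        rd = g.nodes[drop].get("radius") or 0.0
        pos = np.asarray(g.nodes[keep if rk >= rd else drop]["pos"])
        if rd > rk:
            g.nodes[keep]["radius"] = rd
        for u, v, d in list(g.edges(drop, data=True)):
            other = v if u == drop else u
            if other == keep or other == drop:
                continue
            poly = d["polyline"] if d["nodes"][0] == other else d["polyline"][::-1]
            g.add_edge(other, keep, nodes=(other, keep), polyline=poly,
                       length_um=d["length_um"], voxels=d.get("voxels"),
                       point_radii=d.get("point_radii"))
        g.remove_node(drop)
        g.nodes[keep]["pos"] = pos

    changed = True
    while changed:
        changed = False
        # short self-loops
        for u, v, k, d in list(g.edges(keys=True, data=True)):
            if u == v and d["length_um"] < max_length_um:
                g.remove_edge(u, v, k)
                changed = True
        # parallel-edge pairs forming short cycles
        seen: dict[tuple[int, int], list] = {}
        for u, v, k, d in g.edges(keys=True, data=True):
            if u != v:
                seen.setdefault((min(u, v), max(u, v)), []).append((k, d["length_um"]))
        for (u, v), lst in seen.items():
            if len(lst) >= 2:
                lens = sorted(L for _, L in lst)
                if lens[0] + lens[1] < max_length_um:
                    for k, _ in sorted(lst)[::-1]:
                        g.remove_edge(u, v, k)
                    contract(u, v)
                    changed = True
                    break
        if changed:
            continue
        # short simple-graph cycles
        simple = nx.Graph()
        simple.add_nodes_from(g.nodes)
        best: dict[tuple[int, int], float] = {}
        for u, v, d in g.edges(data=True):
            if u != v:
                key = (min(u, v), max(u, v))
                best[key] = min(best.get(key, np.inf), d["length_um"])
                simple.add_edge(*key)
        for cyc in nx.cycle_basis(simple):
            # junction artifacts are spatially compact: all cycle nodes sit
            # within the merge zone (which scales with the local radius),
            # unlike genuine anastomoses
            pos = np.asarray([g.nodes[n]["pos"] for n in cyc])
            extent = float(np.max(np.linalg.norm(pos[:, None] - pos[None, :],
                                                 axis=2)))
            # merge zones extend to ~r/sin(θ/2) ≈ 2.9 r for forks down to
            # 40° separation; 3.5 r covers that with smoothing slack
            radii = [g.nodes[n].get("radius") or 0.0 for n in cyc]
            limit = max(max_length_um, 3.5 * max(radii))
            if extent < limit:
                keep = min(cyc)
                for drop in sorted(set(cyc) - {keep}):
                    # drop edges inside the cycle, reattach the rest
                    for u, v, k in list(g.edges(drop, keys=True)):
                        other = v if u == drop else u
                        if other in cyc or other == keep:
                            g.remove_edge(u, v, k)
                    contract(keep, drop)
                changed = True
                break

    n_comp = nx.number_connected_components(g) if g.number_of_nodes() else 0
    out = SkeletonGraph(g, sorted(roots & set(g.nodes)), graph.spacing,
                        graph.origin,
                        g.number_of_edges() - g.number_of_nodes() + n_comp > 0)
    out.refresh_kinds()
    return out


def _require_root(graph: SkeletonGraph, root_id: int) -> None:
    if not graph.g.has_node(root_id):
        raise KeyError(f"unknown root node {root_id}")


def count_branch_points(graph: SkeletonGraph, root_id: int) -> int:
    """Branch nodes (degree >= 3) in the root's connected component.

    A k-furcation is one junction node and counts once regardless of k.
    """
    _require_root(graph, root_id)
    comp = graph.component_of(root_id)
    return len(graph.branch_nodes(comp))


def _geodesic_distances(graph: SkeletonGraph, root_id: int) -> dict[int, float]:
    comp = graph.component_of(root_id)
    sub = graph.g.subgraph(comp)
    if sub.number_of_edges() - sub.number_of_nodes() + 1 > 0:
        raise CycleError(
            "component contains cycles; prune or inspect the skeleton before "
            "measuring root-to-branch distances")
    dist = {root_id: 0.0}
    stack = [root_id]
    seen = {root_id}
    while stack:
        u = stack.pop()
        for _, v, d in sub.edges(u, data=True):
            if v not in seen:
                seen.add(v)
                dist[v] = dist[u] + d["length_um"]
                stack.append(v)
    return dist


def distances_to_branch_points(graph: SkeletonGraph,
                               root_id: int) -> list[tuple[int, float]]:
    """Geodesic (arc-length) distance from the root to every branch node.

    Returns ``(branch_node_id, distance_um)`` sorted ascending by distance.
    Raises :class:`CycleError` if the component has cycles.
    """
    _require_root(graph, root_id)
    dist = _geodesic_distances(graph, root_id)
    comp = graph.component_of(root_id)
    out = [(n, dist[n]) for n in graph.branch_nodes(comp)]
    return sorted(out, key=lambda t: (t[1], t[0]))


def landmark_segment_length(graph: SkeletonGraph, root_id: int,
                            landmark="first") -> float:
    """Arc-length distance from the root to a landmark branch point.

    ``landmark="first"`` selects the branch node of minimal geodesic
    distance (the ostium-to-circumflex analog); an explicit branch node id
    selects that junction.
    """
    d = distances_to_branch_points(graph, root_id)
    if not d:
        raise ValueError("no landmark available: component has no branch points")
    if landmark == "first":
        return d[0][1]
    for n, dd in d:
        if n == landmark:
            return dd
    raise KeyError(f"landmark {landmark} is not a branch node in the root's component")


# ---------------------------------------------------------------------------
# SWC interchange


def write_swc(graph: SkeletonGraph, path: str | Path, default_radius: float = 1.0) -> None:
    """Write the graph as SWC (id, type, x, y, z, radius, parent; root parent −1).

    Polyline interior points become chained samples, so topology, positions,
    radii and total arc length survive a round trip.
    """
    lines = ["# SWC export: id type x y z radius parent"]
    sample_of_node: dict[int, int] = {}
    next_id = 1

    def node_radius(n):
        return float(graph.g.nodes[n].get("radius") or default_radius)

    def emit(pos, radius, parent, kind=0):
        nonlocal next_id
        sid = next_id
        next_id += 1
        lines.append(f"{sid} {kind} {pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f} "
                     f"{radius:.6f} {parent}")
        return sid

    for comp in nx.connected_components(graph.g):
        start = next((r for r in graph.root_ids if r in comp), min(comp))
        if graph.g.subgraph(comp).number_of_edges() - len(comp) + 1 > 0:
            raise CycleError("SWC cannot represent cyclic components")
        sample_of_node[start] = emit(graph.g.nodes[start]["pos"],
                                     node_radius(start), -1,
                                     1 if start in graph.root_ids else 0)
        stack = [start]
        seen_edges = set()
        while stack:
            u = stack.pop()
            for _, v, k, d in graph.g.edges(u, keys=True, data=True):
                ek = (min(u, v), max(u, v), k)
                if ek in seen_edges:
                    continue
                seen_edges.add(ek)
                poly = d["polyline"] if d["nodes"][0] == u else d["polyline"][::-1]
                radii = d.get("point_radii")
                if radii is not None and d["nodes"][0] != u:
                    radii = radii[::-1]
                parent = sample_of_node[u]
                for t in range(1, len(poly) - 1):
                    r = float(radii[t]) if radii is not None else default_radius
                    parent = emit(poly[t], r, parent)
                sample_of_node[v] = emit(poly[-1], node_radius(v), parent)
                stack.append(v)
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path: str | Path,
             spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> SkeletonGraph:
    """Parse an SWC file into a :class:`SkeletonGraph` (two-pass; forward
    parent references allowed).  Malformed lines raise with their line number."""
    samples: dict[int, tuple[np.ndarray, float, int, int]] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        s = raw.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        if len(parts) != 7:
            raise ValueError(f"{path}: malformed SWC line {ln}: {raw!r}")
        try:
            sid = int(parts[0]); kind = int(parts[1])
            x, y, z, r = (float(p) for p in parts[2:6])
            parent = int(parts[6])
        except ValueError as e:
            raise ValueError(f"{path}: malformed SWC line {ln}: {raw!r}") from e
        samples[sid] = (np.array([x, y, z]), r, parent, kind)

    sg = nx.Graph()
    for sid, (pos, r, parent, kind) in samples.items():
        sg.add_node(sid, pos=pos, radius=r, kind=kind)
    for sid, (pos, r, parent, kind) in samples.items():
        if parent != -1:
            if parent not in samples:
                raise ValueError(f"{path}: sample {sid} references missing parent {parent}")
            sg.add_edge(sid, parent)

    g = nx.MultiGraph()
    roots = [sid for sid, (_, _, p, k) in samples.items() if p == -1]
    node_samples = {sid for sid in sg.nodes if sg.degree(sid) != 2} | set(roots)
    for sid in node_samples:
        g.add_node(sid, pos=sg.nodes[sid]["pos"], radius=sg.nodes[sid]["radius"])

    visited = set()
    for a in node_samples:
        for b in sg.neighbors(a):
            if b in node_samples:
                key = frozenset((a, b))
                if key not in visited:
                    visited.add(key)
                    poly = np.vstack([sg.nodes[a]["pos"], sg.nodes[b]["pos"]])
                    g.add_edge(a, b, nodes=(a, b), polyline=poly,
                               length_um=_polyline_length(poly),
                               point_radii=np.array([sg.nodes[a]["radius"],
                                                     sg.nodes[b]["radius"]]))
                continue
            if b in visited:
                continue
            path = [a, b]
            visited.add(b)
            prev, cur = a, b
            while cur not in node_samples:
                nxt = [u for u in sg.neighbors(cur) if u != prev]
                if not nxt:
                    break
                prev, cur = cur, nxt[0]
                path.append(cur)
                if cur not in node_samples:
                    visited.add(cur)
            poly = np.vstack([sg.nodes[s]["pos"] for s in path])
            radii = np.array([sg.nodes[s]["radius"] for s in path])
            g.add_edge(path[0], path[-1], nodes=(path[0], path[-1]),
                       polyline=poly, length_um=_polyline_length(poly),
                       point_radii=radii)

    root_clusters = [r for r in roots if g.has_node(r)]
    n_comp = nx.number_connected_components(g) if g.number_of_nodes() else 0
    out = SkeletonGraph(g, root_clusters, spacing, (0.0, 0.0, 0.0),
                        g.number_of_edges() - g.number_of_nodes() + n_comp > 0)
    out.refresh_kinds()
    return out
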