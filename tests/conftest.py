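"""Shared fixtures: phantom suites and canonical small geometries.

The phantom suites (20 seeded trees, clean and degraded) are expensive, so
they are built once per session and shared between the morphometry property
tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from coromorph import analyze_grid
from coromorph import vesselgen as vg
from coromorph.grid import VoxelGrid

SUITE_KWARGS = dict(radius_root=9.0, radius_decay=0.9)
N_SUITE = 20


def suite_case(seed: int, noisy: bool):
    """Analyze one seeded phantom; returns (ground truth, metrics, spec)."""
    n = int(3 + seed % 8)
    spec = vg.generate_tree_spec(n, seed=seed, **SUITE_KWARGS)
    gt = vg.ground_truth_from_spec(spec)
    noise = vg.NoiseSpec(hole_rate=0.02, seed=seed) if noisy else None
    grid, _ = vg.voxelize(spec, noise=noise)
    try:
        metrics = analyze_grid(grid, [spec.root_point],
                               close_radius=2 if noisy else 0)[0]
    except Exception as e:                      # degraded masks may defeat repair
        metrics = e
    return gt, metrics, spec


@pytest.fixture(scope="session")
def phantom_suite_clean():
    return [suite_case(s, noisy=False) for s in range(N_SUITE)]


@pytest.fixture(scope="session")
def phantom_suite_noisy():
    return [suite_case(s, noisy=True) for s in range(N_SUITE)]


@pytest.fixture(scope="session")
def coronary_tube_profiles():
    """Station-diameter recovery on tubes at the two observed group calibers.

    Three phantoms at light-sheet spacing: wild-type-like 66.377 µm and
    mutant-like 58.492 µm diameters axis-aligned, plus the wild-type caliber
    tilted 30° off-grid; 800 µm long so all five default stations (200–600
    µm from the root) are defined.
    """
    cases = {}
    for label, diameter, tilt in (("wt", 66.377, 0.0),
                                  ("ko", 58.492, 0.0),
                                  ("wt_tilt30", 66.377, 30.0)):
        a = np.deg2rad(tilt)
        spec = vg.straight_tube_spec(800, diameter / 2,
                                     direction=(np.cos(a), 0.1, np.sin(a)))
        grid, _ = vg.voxelize(spec)
        m = analyze_grid(grid, [spec.root_point], close_radius=0)[0]
        cases[label] = (diameter, m, max(grid.spacing))
    return cases


@pytest.fixture()
def straight_tube():
    """Isotropic straight tube: radius 4 µm, 60 µm long, oblique direction."""
    spec = vg.straight_tube_spec(60, 4.0, direction=(1.0, 0.3, 0.2))
    grid, gt = vg.voxelize(spec, spacing=(1, 1, 1))
    return spec, grid, gt


def make_y_grid(stem=100.0, arm=60.0, r=6.0, half_deg=30.0, tilt_deg=0.0,
                spacing=(1.0, 1.0, 1.0)):
    """Symmetric Y phantom with stem along a tilted axis; analytic layout."""
    a = np.deg2rad(tilt_deg)
    d0 = np.array([np.cos(a), 0.0, np.sin(a)])
    e1 = np.array([-d0[2], 0.0, d0[0]])
    b = np.deg2rad(half_deg)
    d1 = np.cos(b) * d0 + np.sin(b) * e1
    d2 = np.cos(b) * d0 - np.sin(b) * e1
    p0 = np.zeros(3)
    pj = stem * d0
    segs = [
        vg.Segment(0, None, np.array([p0, pj]), np.full(2, r)),
        vg.Segment(1, 0, np.array([pj, pj + arm * d1]), np.full(2, r)),
        vg.Segment(2, 0, np.array([pj, pj + arm * d2]), np.full(2, r)),
    ]
    spec = vg.TreeSpec(segs, p0)
    grid, gt = vg.voxelize(spec, spacing=spacing)
    return spec, grid, gt


@pytest.fixture()
def y_phantom():
    return make_y_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_blob_grid(rng, shape=(24, 24, 24), p=0.35) -> VoxelGrid:
    occ = rng.random(shape) < p
    occ[0, :, :] = occ[-1, :, :] = False
    occ[:, 0, :] = occ[:, -1, :] = False
    occ[:, :, 0] = occ[:, :, -1] = False
    return VoxelGrid(occ, (1.0, 1.0, 1.0))
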