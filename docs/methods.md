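# Methods

`coromorph` quantifies the 3D architecture of vascular trees from binary
segmentation masks — the kind produced by light-sheet imaging of
immunolabeled, cleared embryonic hearts — and the kinetics of
mechanosensitive currents and calcium signals recorded from endothelial
cells. Because no imaging data ships with the package, every quantitative
claim is exercised on synthetic phantoms with analytically known ground
truth.

## Vessel phantoms (`vesselgen`)

A phantom is a rooted tree of straight tubular segments. Growth starts from
a root segment and repeatedly converts a randomly chosen open tip into a
junction with two (optionally three) children. Child directions are drawn
uniformly in a cone of half-angle 50° around the parent direction, with
siblings at least 40° apart; child radii are the parent radius times a fixed
decay (default 0.8 per generation, a Murray-like taper that keeps ground
truth analytic). Candidate segments are rejection-sampled so that no new
tube surface comes within 4 µm of unrelated existing surfaces: without this
clearance, rasterized tubes that pass near each other stay intermittently
26-adjacent and create *digital handles* — spurious tunnels that a
topology-preserving skeletonizer faithfully keeps and that would falsify
topology recovery. The overlap of a child with its own parent near the
junction is legitimate and exempted.

Rasterization sets every voxel whose center lies within the local
(linearly interpolated) radius of the swept capsule. The default spacing is
(0.97, 0.97, 2.00) µm, the acquisition voxel of the imaging the package
targets. Ground truth (branch-point count, root-to-branch arc distances,
station diameters) is computed from the polylines, never the raster.
Degradation is applied after rasterization: boundary-voxel flips driven by
Gaussian draws (surface roughness) and seeded deletion of interior voxel
blocks (holes), which is what the morphological closing stage exists to
repair. The recovery test suites use 3–10 bifurcations per tree,
`radius_root=9 µm` and `radius_decay=0.9` so that every segment stays at or
above ~4.7 µm radius — at least three voxels on the fine axes; thinner tubes
(under ~1.5 voxels on the 2 µm axis) lose forks to discretization, and the
generator flags sub-voxel radii accordingly.

What the phantoms do **not** emulate: curved or tortuous centerlines,
anastomoses, caliber noise along a segment, intensity-level segmentation
errors, or touching non-vessel structures. Passing recovery tests therefore
demonstrates correctness of the measurement chain on clean tree geometry at
the stated resolution, not robustness to every real-world segmentation
artifact.

## Mask preparation (`maskprep`)

Closing = dilation then erosion with a discrete ball (default radius 2
voxels, isotropic in voxel units; a µm-calibrated ellipsoid is available).
The volume is zero-padded by the element radius, so dimensions are unchanged
and vessels touching the border (which do not occur in phantoms) would need
pre-padding by the caller. Component hygiene keeps 26-connected components
that contain a labeled root point or exceed a voxel-count floor.

## Skeletonization (`skeletonize`)

Topology-preserving sequential thinning. A voxel is deleted only if it is
*simple* — deletion leaves both the foreground 26-connectivity and the
background 6-connectivity unchanged — tested by the standard local
criterion: exactly one 26-component of foreground in the punctured 3×3×3
neighborhood, and exactly one 6-component of background in the
18-neighborhood touching a face. Endpoints (exactly one foreground
neighbor) and the supplied root voxels are never deleted. Candidates are
processed in ascending order of the anisotropic Euclidean distance
transform, ties broken by raster (z, y, x) index, so the deepest voxels
survive and the skeleton is centered; the whole procedure is deterministic.
The per-voxel tests are numba-compiled; a 128³ tube volume thins in a few
seconds.

Two documented consequences of the endpoint rule: (i) thinning convex blobs
can freeze a one-voxel-wide spur between the protected root and the last
surviving endpoint (a ball collapses to a short root-anchored path rather
than a point) — spur control is deliberately deferred to graph-level
pruning; (ii) surface noise seeds short terminal spurs that scale with the
local tube radius.

## Graph construction and morphometry (`treegraph`)

Skeleton voxels with ≠2 neighbors (and all roots) become node voxels;
26-adjacent node-voxel clusters collapse to one node, so a k-furcation is a
single branch point however many arms it has. Junction nodes anchor at the
cluster voxel of maximal EDT (the maximal-inscribed-sphere center). Runs of
degree-2 voxels become edge polylines; staircase voxels that acquire a third
neighbor through diagonal adjacency are dissolved back into their edges.
Cycles never raise during construction; they set a flag (and
`distances_to_branch_points` refuses cyclic components with an instruction
to prune or inspect).

**Arc lengths.** Raw voxel-center paths overestimate oblique curve lengths
by up to ~8% (stair-stepping). Edge polylines are therefore smoothed with a
5-point moving average (endpoints anchored) before lengths are summed; on
oblique straight tubes this brings length errors to ~1–2%.

**Junction-scale artifact repair**, applied in this order by the pipeline's
auto mode:

1. *Small-cycle collapse.* Where two arms diverge, rasterized surfaces can
   stay intermittently adjacent and leave junction-scale handles. Cycles
   whose nodes all lie within one merge zone (spatial extent below the
   pruning threshold) are contracted to a single node; long cycles —
   genuine anastomoses — are left flagged.
2. *Spur pruning.* Terminal edges shorter than a threshold are removed
   iteratively, and degree-2 nodes dissolved. The auto threshold is
   2× the *local* junction radius (EDT at the attachment node): thinning
   spurs scale with local caliber, and a global threshold sized for the
   largest trunk would swallow the genuinely short arms of small distal
   junctions. Edges containing a root are never pruned.
3. *Junction-complex merging.* A single anatomical bifurcation can split
   into a chain of digital forks; branch nodes joined by an edge shorter
   than the sum of their radii are fused onto the larger-radius node.
4. *Junction refinement.* The medial axis forks up to ~r/sin(θ/2) distal
   to the geometric junction (arms stay merged while their lumens overlap).
   Each branch node is relocated to the least-squares intersection of lines
   fitted to its incident centerlines over an arc window starting 2 radii
   from the node and extending 25 µm; incident polylines are trimmed
   accordingly. Corrections larger than 3 radii are rejected as unreliable.
   The window (2 r, 25 µm) was chosen on a development suite of seeded
   phantoms as the setting that minimizes first-branch distance error;
   longer windows reach past neighboring junctions and degrade.

With these steps, on 20 seeded noise-free phantoms the branch-point count
matches ground truth exactly and root-to-first-branch distances are
recovered to ≤2.4 µm (mean ~1 µm).

Geodesic root-to-branch distances are sums of edge arc lengths along the
unique tree path; `landmark_segment_length(..., "first")` returns the
nearest-branch distance — the ostium-to-circumflex analog. SWC export
writes every polyline point as a sample (root parent −1), so write→read
preserves topology, positions, radii, and total arc length to float
precision; the parser is two-pass and accepts forward parent references.

## Caliber (`caliber`)

The anisotropic EDT gives each foreground voxel its µm distance to
background; its value on the centerline is the maximal-inscribed-sphere
radius. Diameter at an off-lattice centerline point uses the tight local
bound min over the 3×3×3 neighborhood of EDT(v) + |p − v| (every voxel
carries an inscribed sphere, so this bounds the radius at p from above and
is tight when v lies toward the nearest wall). Stations are fixed arc-length
positions from the root — default 200, 300, 400, 500, 600 µm, the
measurement scheme used for embryonic coronary arteries — interpolated
linearly between bracketing centerline points; stations beyond the main
path are NaN and excluded from the mean. At junctions the main path follows
the child of maximal downstream arc length, a deterministic surrogate for
following the named trunk. The estimator carries a small systematic
underestimate (≲ one coarse voxel on the diameter) because centerline
voxels sit slightly off the true axis; recovered means on 66.4 µm and
58.5 µm tubes are within ~1.6 µm of truth, and a 30° off-grid tilt moves
stations by well under two coarse voxels.

`two_point_mean_diameter` is the two-measurement averaging used for the
pulmonary artery and aorta.

## Hemodynamics (`hemo`)

Single-pipe Poiseuille idealization: ΔP = R·Q, R = 8µL/(πr⁴). Percent
changes are computed directly from diameters — the radius conversion
cancels in the ratio, so `resistance_change_from_diameters(d0, d1) =
100·((d0/d1)⁴ − 1)` is independent of viscosity and length. For the
observed narrowing 66.377 → 58.492 µm this gives an 11.879% diameter
reduction and a 65.8% resistance increase. No network flow solve and no
non-Newtonian or pulsatile corrections are attempted.

## Electrophysiology traces (`ephys`)

Currents are sampled at 10 kHz (0.1 ms). The inactivation constant is fit
as I(t) = A·exp(−(t−t_peak)/τ) + C on the window from the peak to 95%
recovery toward baseline (or trace end). Peak and recovery points are
located on a lightly smoothed copy (5-sample moving average) because the
raw argmax is noise-inflated; the peak is then refined to the raw extremum
within the smoothing window so the most informative early samples are kept.
The offset C is pinned to the pre-stimulus baseline by default — the
baseline is estimated from many samples and fixing it roughly halves the
variance of τ for fast currents (a 1 ms τ at 10 kHz and 10:1 signal-to-noise
is otherwise at the edge of identifiability); `free_offset=True` releases it
for drifting recordings. A trace whose peak deviation stays below 3× the
pre-stimulus noise SD is reported as having no mechanosensitive current —
a result, not an error. An optional latency filter (<5 ms) rejects
responses that are too slow to be deflection-gated; it is off by default.

Classification: RA for τ < 5 ms, IA for 5–50 ms, SA for τ > 50 ms, with the
τ = 50 ms boundary assigned to IA (the bin statement "5–50 ms" is taken as
inclusive; a variant phrasing ">51 ms" for SA exists but is not used).
Deflection–response series are restricted to stimuli ≤1,000 nm and binned
into 1–10, 11–50, 51–100, 101–250, 251–500 and 501–1,000 nm (per-cell bin
means; non-integer deflections falling between printed bin edges, e.g.
10.4 nm, are not assigned to any bin). ΔF/F0 = (F − F0)/F0 with F0 the mean
of the first 10 acquisition cycles (3 s per cycle); an ionomycin-saturated
maximum optionally rescales the series. Class proportions between two
groups are compared with a two-sided Pearson chi-squared test without
continuity correction.

## Problem sizes and determinism

The test suites and the acceptance script use 20 phantoms of 3–10
bifurcations (volumes up to roughly 200³ voxels) and 800 µm tubes for the
caliber checks; a full run takes a few minutes on one core. All randomness
flows through explicit integer seeds: identical parameters and seeds give
bit-identical voxel grids, skeletons and metric files.

## Known limitations

- Junction localization degrades when sibling branches diverge at shallow
  angles (<~40°) or when two junctions sit within one merge zone of each
  other; the refinement guard then leaves the raw (distally biased) node.
- Sub-voxel tubes (radius below ~1.5 voxels on the coarse axis) lose forks;
  the rasterizer flags this.
- Caliber from the EDT slightly underestimates at bends and near junctions
  (inscribed spheres shrink there); station positions inherit the ~1–2%
  arc-length uncertainty of the centerline.
- No automated reconnection of broken vessel fragments: a mask whose trunk
  is severed yields two components, and only the rooted one is measured.
- SWC cannot represent cyclic components; writing a flagged-cyclic graph
  raises.
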