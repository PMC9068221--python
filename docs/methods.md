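# Methods

## Scene model

A planning scene is a 3D integer label volume with four roles: air, surgical
space, non-surgical space, and target. The feasibility rule is binary and
voxel-based: a corridor is admissible iff it contains no non-surgical voxel;
air and surgical space are equally traversable, and target voxels are the
intended terminal contact, so they are counted as allowed. Every voxel is
classified by its **center** (a voxel "is in" a region iff its center is),
which makes the rule equivalent to an exact point-to-segment distance test
and gives every operation a brute-force oracle.

All geometry is computed in world millimetres on canonical RAS axes
(x = left→right, y = posterior→anterior, z = inferior→superior). File headers
(NIfTI affine, NRRD direction matrix) are honored on read by reorienting
axis-aligned volumes into this canonical frame; oblique acquisitions are
rejected rather than silently resampled. Anisotropic volumes (CT stacks
commonly have coarser slice spacing than in-plane resolution, e.g. 0.65 mm
vs 1 mm slices across scanners) are resampled to an isotropic grid before
searching — nearest-neighbor only, since labels are categorical — with the
target spacing defaulting to the smallest input spacing. Resampling preserves
each label's physical volume to within a few percent for structures at least
a few voxels thick; whether to resample or work on the native grid is this
package's choice, and isotropic grids keep the metric geometry
rotation-invariant.

## Corridor geometry and pose grid

The corridor is a capsule: all points within radius `r = head_diameter/2` of
the axis segment. The hemispherical tip cap matches a diamond burr head and
makes capsule membership an exact point-to-segment distance test. The shaft
is modeled at the head radius and extends from the tip to the volume
bounding-box exit — the whole instrument shaft must be collision-free, not
just the drill head. Space beyond the volume is treated as air (the exterior
of the scanned region is not non-surgical tissue); a pose whose *tip* leaves
the volume's physical box, however, is counted infeasible, since a drill tip
outside the scanned anatomy is not a usable placement.

Pose parameterization:

* rotations `rx, ry, rz` are extrinsic, about the fixed world axes, composed
  `Rz·Ry·Rx`, on the centered grid `step·(k − n//2)` — for the default
  5°/180° this is −90°, −85°, …, +85° (36 values, half-open so the count is
  exactly `range/step`), and a degenerate range equal to its step yields the
  single zero angle;
* `spin` lies on `[0°, 360°)`; it is geometrically inert for a circular
  cross-section but is a real degree of freedom of the instrument and is
  enumerated (it would matter for non-circular burrs, an extension point);
* `depth` withdraws the tip along the +axis on `[0, 15) mm`; depth 0 is
  target contact ("head meets the target").

Enumeration is lexicographic in `(rx, ry, rz, spin, depth)` and the closed
form `n_rot³·n_spin·n_travel` is verified by materialization in the tests;
the default grid counts 50,388,480 poses.

## Collision checking

Two routes share one boundary convention (collision iff a forbidden voxel
center is at distance `≤ r` from the axis segment):

1. **Brute force** — rasterize the capsule over its index bounding box and
   inspect labels. This is the reference oracle.
2. **Fast path** — exact minimum distance from forbidden voxel centers to the
   axis segment. The segment is sampled at half the minimal voxel spacing
   `h`; a 1-Lipschitz lower bound from the Euclidean distance transform
   (clearance map) accepts most feasible corridors without touching the
   KD-tree; otherwise the nearest-neighbor distance at the samples brackets
   the true minimum within `h/2`, and the ambiguous band is resolved exactly
   on the KD-tree candidates. The fast path is exact, not approximate, and
   the suite enforces 100% agreement with the oracle across all phantom
   families.

Spin does not change the capsule, so the search evaluates one collision test
per `(rx, ry, rz, depth)` and replicates the verdict across spin values; this
caching provably changes no count and no pose verdict (tested against
pose-by-pose brute force).

Drill-size adaptation repeats the full search with the head diameter reduced
by `decrement` (default 0.5 mm) until a feasible pose exists or the diameter
would fall below `min_diameter` (default 1 mm), in which case the result is
flagged infeasible-at-floor. Feasible poses are ranked by decreasing
clearance (minimal forbidden distance minus radius); ties break by smaller
angular deviation from the canonical outward axis, then lexicographic pose
order, so reports are reproducible byte-for-byte. The ranking criterion is
this package's addition — the screening rule itself defines only
feasibility, not a preference among feasible paths.

## Synthetic phantoms

The generator builds segmented-skull stand-ins analytically: a non-surgical
block fills the posterior portion of the volume (flush with the posterior box
face, so no fictitious posterior air pocket offers escape routes), pierced by
a circular channel of parametric width along the anterior axis; the first
2 mm of the channel are the target slab, behind a 2 mm posterior wall; the
anterior remainder of the volume is an air vestibule. Obstacle bodies (boxes
/ ellipsoids) may be added: paired "orbits" flanking the corridor exit and an
anterior slab emulating a frontal-cortex blockade. Optional seeded jitter
perturbs the classification coordinates by up to the jitter amplitude,
roughening boundaries without ever relabeling interior voxels.

The default family widths encode the species contrast that motivates
drill-size screening: a 13 mm corridor at 0.65 mm voxels (goat-like — wide
sphenoid body, drillable with a conventional 2.9 mm burr) and a 2.5 mm
corridor at 1 mm voxels (macaque-like — narrower than the burr, forcing
adaptation to 2.4 mm). `measure_channel_width` recovers the analytic width as
the inscribed-disc diameter at mid-channel via the distance transform, within
about one voxel.

What the phantoms do **not** emulate: curved or branching anatomy, partial
volume effects and segmentation error, CT intensities (labels only), and
real per-species feasibility percentages — those depend on actual skull
anatomy, so passing tests demonstrate correctness of the search machinery,
not anatomical realism.

## Numerical choices and problem sizes

* Distances in mm as float64; the collision boundary uses exact comparisons
  (`≤ r`), with the discrete voxel-center geometry making exact ties
  well-defined (tested at a forbidden center exactly at radius).
* Clearance-map sentinel for obstacle-free volumes is +inf.
* The test suite and the acceptance script run on coarse grids (45°/90°/5 mm
  → 768 poses; 30°/30°/5 mm → 7,776 poses) and volumes of 48³–96³ voxels;
  the full 50M-pose grid is enumerated lazily and counted in closed form.
  The end-to-end check plans on a 96³ scene with a 15° grid (622,080 poses,
  25,920 distinct collision tests per diameter), which completes in well
  under a minute per search on one CPU.
* Reports contain no timestamps and use sorted JSON keys; identical inputs
  give byte-identical reports.

## Known limitations

Straight corridors only (no articulated or curved trajectories); circular
cross-sections only; single target component (the anchor is the target
centroid — a disconnected target would need per-component anchoring); the
exhaustive search is embarrassingly parallel but implemented single-threaded.
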