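# Methods

This note documents the models, conventions, and numerical choices behind
`arctraj`, in the spirit of a planning-study methods section.

## Coordinate and angle conventions

Patient coordinates are (x, ap, si) in mm: lateral x with the right
hemisphere negative, anterior–posterior increasing anterior → posterior
(frontal pole ≈ −80 mm, occipital pole ≈ +100 mm on the default phantom),
and superior–inferior. Files exported from RAS-convention tools must flip
the AP sign on ingestion; the NIfTI loader logs a reminder. Voxel masks use
a center-inclusion rule throughout: a voxel belongs to a structure iff its
center lies inside the defining primitive. This is deterministic, fast, and
converges to the analytic volume as spacing shrinks (verified at 2, 1, and
0.5 mm in the tests); it ignores partial-volume effects, which is consistent
with the voxel-counting volumes used by the metrics.

Beam angles follow an IEC-61217-like convention for a head-first supine
patient: gantry 0° sends the beam anterior → posterior, the gantry rotates
about the SI axis at couch 0, and couch rotation turns the patient about
the room-vertical (patient AP) axis. Couch spans [−90°, +90°), gantry
[0°, 360°), both half-open, default resolution 1°.

## Cranial segmentation

The brain is split into six classes: laterality at x = 0 (x < 0 right,
x ≥ 0 left) and region by AP coordinate — frontal [brain min, 20 mm),
medial [20, 60), posterior [60, brain max]. Boundaries are half-open so
every interior point gets exactly one class, and mirrored points map to the
paired class (1↔2, 3↔4, 5↔6). Targets spanning multiple segments are
classified by centroid; this is a package convention for an inherently
ambiguous edge case, chosen for determinism over partial-target clipping.

## Phantom

The synthetic cranial phantom stands in for a population-averaged brain
atlas. Defaults: brain ellipsoid with semi-axes (70, 90, 65) mm centered at
(0, +10, 0) so the AP extent is −80…+100 mm; eight OAR primitives —
brainstem capsule, chiasm ellipsoid, paired optic-nerve capsules, eye
spheres (24 mm), lens spheres (8 mm) — at anatomically plausible positions,
mirror-symmetric across x = 0; 2 mm isotropic grid. The phantom reproduces
the *geometry class* of the problem (OARs clustered anterior-inferior and
central, large posterior OAR-free region); it does not reproduce real
cortical anatomy, inter-patient variability, or the lateral asymmetries of
a real brain. Tests passing on the phantom therefore validate the
machinery and its invariants, not anatomical fidelity.

The 18-case suite places one spherical target per (class, diameter) for
diameters 5, 10, 20 mm. Placement is seeded sampling over brain voxels
that can host the full sphere (interior distance transform ≥ radius),
restricted to the class region and weighted toward the region centroid
(weight e^{−d/25 mm}) so targets land at representative depths. The three
planning techniques per case give the 54-plan bookkeeping used by the
statistics module.

## Overlap maps

Per couch–gantry bin, target and avoidance voxel centers are projected
onto the plane orthogonal to the beam axis (parallel-ray approximation)
and rasterized at 1 mm pixels; the map value is
|target shadow ∩ avoidance shadow| / |target shadow|. Choices worth noting:

* **Parallel rays, not a divergent source.** For cranial geometry
  (structures within ~10 cm of isocenter, source at ~1 m) the divergence
  error is small, and parallel projection buys an exact antipodal symmetry
  O(c, g) = O(c, g+180°): the implementation canonicalizes the beam-axis
  line so antipodal bins share one projection basis and the symmetry holds
  bit-for-bit (and halves the computation). Published overlap maps from
  source-side shadowing need not satisfy it.
* **Depth is ignored.** An OAR distal to the target still counts as
  overlap, matching the exit-dose rationale of BEV avoidance.
* **Normalization by the target shadow.** The fraction's denominator is
  the target's shadow pixel count; an avoidance structure that fully
  shadows the target gives 1 regardless of the OAR's size.
* **No per-OAR weighting.** The avoidance structure is the unweighted
  union of all OARs; the union's shadow dominates every member's shadow,
  so the merged map bounds each per-OAR map from above (tested). Per-OAR
  maps remain available for analyses that need them.
* Collision zones are supplied as couch×gantry rectangles (possibly
  wrapping in gantry) or a boolean grid; flagged bins keep their values
  but are infeasible to the solver. Real collision zones are
  machine-specific and must be measured; any shipped mask is a
  configuration, not a fact about a particular linac.

An independent slow oracle (per-voxel line-of-sight binning) cross-checks
the projection path to within 0.05 absolute on ≥ 95% of bins in the tests.

## Class templates

The brain is tiled with an axis-aligned lattice of sphere centers
(default 20 mm diameter, 20 mm spacing) anchored at the brain centroid —
the anchor is a package convention chosen for symmetry and determinism. A
center is kept iff the whole sphere fits inside the contour, assessed via
the interior Euclidean distance transform (distance from the center's
voxel to the nearest outside voxel center must reach the sphere radius);
the discretization error of this test is below one voxel and shrinks with
the grid spacing.
Templates aggregate member maps by bin-wise **maximum**, not mean: the
template must upper-bound every member so that low-cost template regions
are low-cost for every target in the class. Because the centroid-anchored
lattice places a column of targets exactly on the midline and the
half-open laterality rule assigns x = 0 to the left classes, left
templates dominate (rather than exactly equal) the mirrored right
templates; the tests assert this dominance and the equality away from
midline-driven bins.

## OFIXED solver

Formalization: partition the gantry circle into k ≤ max_arcs contiguous
sectors (half-open [start, start+span), wrap at 360°), each spanning at
least min_span (defaults 4 and 30°), assign each sector one couch angle
(repeats allowed), and minimize the sum of map values over covered control
points — each gantry angle delivered exactly once, i.e. a total budget of
360 control points at 1°. The partition reading (rather than four
independent, possibly re-covering arcs) follows from that fixed
control-point budget. Collision-flagged bins cost +∞ (hard infeasibility,
not a penalty); if no finite partition exists the solver raises an error
listing fully blocked couch angles.

The solver is exact: per-sector best-couch costs from per-couch prefix
sums over the doubled circle, then dynamic programming over sector
breakpoints with the first breakpoint enumerated. Costs are sums, not
means — equivalent ranking at fixed total span. Tie-breaks are
deterministic: fewest arcs after merging adjacent same-couch sectors, then
the lexicographically smallest (couch, gantry start) sequence with arcs
ordered by gantry start; a full-circle arc canonically starts at gantry 0,
and couch ties resolve to the lowest couch index. A brute-force
enumeration oracle (≤ 36 gantry bins) with the same tie-break verifies
global optimality on 200 random maps in the acceptance tests.

## Objectives

The distance rule is applied verbatim: Rx·(1 − 0.10·d) for d < 10 mm,
150 cGy at and beyond 10 mm (the floor applies at exactly 10 mm because
proximity constrained is defined as *strictly less than* 10 mm). In the
narrow band d ∈ (8.5, 10) mm the formula yields less than the floor; no
blending is invented — the rule is applied as stated and a warning is
logged. Results are rounded to the nearest cGy. Serial OARs (brainstem,
chiasm, optic nerves) are measured through 2 mm PRV expansions; spheres
and capsules dilate exactly (their Euclidean dilation is again a
sphere/capsule), other representations use a distance-transform threshold.
Minimum distances are full-3D Euclidean distances between voxel centers —
conservative (≤ any per-slice 2D measurement) and rotation invariant. The
ring objective is round(Rx/3), which reproduces the conventional 800 cGy
at Rx = 2400 (the "33%" is treated as one third). The tuning ring is a
1–3 cm diameter shell centered on a spherical target with the target
subtracted; non-spherical targets fall back to a distance shell from the
target surface. Objectives are emitted as data; no optimizer is called.

## Metrics

Volumes are voxel counts × voxel volume, no sub-voxel interpolation;
commercial-system interpolation schemes vary and are not modeled. CI
reference dose defaults to the prescription. Dmax is the voxel maximum
without a small-volume surrogate (no D0.03cc), matching a plain
"maximum dose" definition. Analytic dose fixtures (uniform, linear
falloff, inverse-cube) provide closed-form oracle values: the inverse-cube
field has GI exactly 2, and shell constructions give exact CI and V12Gy
targets. Metric values on these fixtures stabilize within 5% from 2 mm to
1 mm grids.

## Statistics

Wilcoxon signed-rank, two-tailed, per metric and technique pair. Zero
differences are dropped (the original convention; the choice is not
dictated by the comparison design) and ties get average ranks. For
effective n ≤ 25 the p-value is exact: the null distribution of the rank
sum over all 2^n sign assignments is built by convolution (ranks doubled
to integers), which is equivalent to full enumeration and verified against
it for n ≤ 12. Above n = 25 a normal approximation with tie correction and
continuity correction is used. The per-comparison significance level is
0.05/12 (the number of metrics), a deliberate middle ground at n = 18
cases between no correction and the fully conservative 0.05/36 over all
metric×pair tests. Monitor units are accepted as an input column (they are
optimizer output and never computed here).

## Pipeline and problem sizes

The default end-to-end run uses 5° angular resolution, the 2 mm phantom,
a 20 mm / 20 mm target lattice (≈ 135 targets on the default phantom), and
completes in a few minutes on one CPU; 1° maps are supported and scale
linearly in bin count. Acceptance-level tests run the full 5° workflow
twice and require byte-identical outputs under a fixed seed; all
randomness flows through explicitly seeded generators, and every run
writes a MANIFEST.json with per-file SHA-256 checksums, the seed, and a
config hash. The standard four-arc baseline geometry (full coplanar arc,
vertex arc, two ±45° couch partial arcs) ships as editable defaults
because the exact partial-arc spans are an institutional convention, not a
universal constant.

## Known limitations

* No VMAT optimization or dose calculation: dosimetric conclusions about
  real plans cannot be drawn from this package alone; it selects and
  scores geometry.
* The phantom's anatomy is idealized and mirror-symmetric; real-anatomy
  class templates are not simple mirror images, and template quality on
  real patients is untested here.
* Parallel-ray shadows slightly misplace overlap boundaries relative to a
  divergent source; a divergent mode is a config stub, not implemented.
* Collision masks reproduce the concept, not measured values for any
  specific machine.
* Multiple simultaneous metastases are out of scope; the max-aggregation
  template logic would need a different conservative construction.
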