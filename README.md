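# arctraj

Anatomically informed class-solution arc trajectories for cranial
stereotactic radiosurgery / radiotherapy (SRS/SRT).

When a single brain metastasis is treated with VMAT, the choice of
noncoplanar arc geometry — which couch angles, which gantry sectors —
largely determines how much dose sprays through the organs at risk (OARs:
brainstem, optic chiasm, optic nerves, eyes, lenses). `arctraj` implements
a 4π beam-orientation workflow for selecting that geometry before any dose
optimization happens:

1. **BEV overlap maps.** For every couch–gantry combination on a 1°-resolution
   grid (couch ∈ [−90°, 90°), gantry ∈ [0°, 360°)), project the target and a
   merged avoidance structure (the union of all OARs) onto the plane orthogonal
   to the beam axis and score the fractional overlap of their shadows,
   O(θ, φ) ∈ [0, 1]. Mechanically infeasible couch/gantry regions are flagged
   with a configurable collision mask.
2. **Six-class cranial templates.** The brain contour is tiled with equally
   sized, equally spaced spherical targets and segmented into six classes —
   {right, left} × {frontal, medial, posterior}, split at x = 0 laterally and
   at 20 mm / 60 mm along the anterior→posterior axis. Each class template map
   is the bin-wise **maximum** of its member maps: a conservative overestimate
   of the overlap any target in that region could see.
3. **OFIXED arc selection.** An exact solver partitions the gantry circle into
   at most four contiguous fixed-couch sub-arcs, each ≥ 30°, jointly spending
   exactly 360° of control points, minimizing the summed map value
   Σ O(θ_k, φ) over covered control points. Per-sector best-couch costs come
   from prefix sums and the circular partition is solved by dynamic
   programming — provably globally optimal (a brute-force enumeration oracle
   verifies this in the test suite).
4. **Distance-based objectives.** VMAT optimization objectives are generated
   from geometry alone: an OAR at minimum distance d mm from the PTV gets an
   upper objective Rx·(1 − 0.10·d) for d < 10 mm ("proximity constrained"),
   a 150 cGy floor beyond; plus PTV coverage (≥ 99% at Rx), a 15% hotspot
   cap, and a tuning-ring objective at Rx/3 on a 1–3 cm shell.
5. **Plan-quality metrics and statistics.** Paddick conformity index
   CI = (V_T,ref/V_T)·(V_T,ref/V_ref), gradient index GI = V_{Rx/2}/V_Rx,
   V12Gy (normal brain ≥ 12 Gy, target excluded), per-OAR Dmax; paired
   two-tailed Wilcoxon signed-rank tests across planning techniques
   (standard four-arc template vs class solution vs patient-specific) with
   Bonferroni-corrected significance (0.05/12 = 0.00417).

Everything runs on a built-in parameterized cranial phantom (ellipsoidal
brain + 8 OAR primitives) and analytic dose fields, so no external atlas,
planning system, or patient data is required. Dose *calculation* is out of
scope by design: dose grids are inputs to the metrics, not products of the
package.

Intended users: medical-physics researchers studying beam-angle/trajectory
optimization and class-solution planning, and developers who need a
reproducible, fully synthetic testbed for 4π arc-selection algorithms.

## Worked example

```python
from arctraj import (ArcConstraints, PhantomConfig, build_objective_set,
                     build_phantom, case_structure_set, case_target,
                     compute_overlap_map, make_case_suite, merge_oars, solve)

phantom = build_phantom(PhantomConfig())          # brain + 8 OARs, 2 mm grid
suite = make_case_suite(phantom, seed=1)          # 18 cases: 6 classes x 3 sizes
case = next(c for c in suite if c.case_id == "c3_d20mm")   # right-medial, 2 cm

avoid = merge_oars(phantom, phantom.names("oar"))
omap = compute_overlap_map(case_target(phantom, case), avoid, resolution_deg=5)
sol = solve(omap, ArcConstraints())               # <= 4 arcs, >= 30 deg each
print(f"cost {sol.total_cost:.3f} with {len(sol.arcs)} arcs")
for a in sol.arcs:
    print(f"  couch {a.couch_deg:6.1f}  gantry {a.gantry_start_deg:5.1f}"
          f"  span {a.span_deg:5.1f}")

oset = build_objective_set(case_structure_set(phantom, case), 2400)
for p in oset.proximity:
    if p.proximity_constrained:
        print(p.oar, f"d = {p.min_distance_mm:.2f} mm ->",
              oset.record_for(p.oar + "_prv").dose_cgy, "cGy")
```

prints (seed 1):

```
cost 0.000 with 4 arcs
  couch  -90.0  gantry  30.0  span 130.0
  couch  -10.0  gantry 160.0  span  45.0
  couch  -85.0  gantry 205.0  span 135.0
  couch  -10.0  gantry 340.0  span  50.0
brainstem d = 8.49 mm -> 364.0 cGy
```

The solver found four fixed-couch arcs whose control points accumulate zero
BEV overlap with the merged avoidance structure — the beam never "sees" the
target and an OAR stacked along the same axis. The brainstem sits 8.49 mm
from this medial target, so it is proximity constrained and its 2 mm
planning-risk volume receives a distance-derived upper objective of
2400·(1 − 0.10·8.49) ≈ 364 cGy; all other OARs are beyond 10 mm and get the
150 cGy floor.

The same workflow end to end, from a shell:

```bash
arctraj run --out run_dir --seed 1       # templates + 18-case trajectories
arctraj template build --res 5 --out run_dir
arctraj ofixed solve --map run_dir/class1_right_frontal.csv --out plan.json
```

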