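# Methods

`vmatgeo` computes treatment-plan *geometry* for multi-lesion cranial SRS
VMAT: which lesions share an isocenter, where each isocenter goes, and which
collimator angle each arc should use. It calculates no dose; its output is
the geometric scaffold a planner (or a treatment planning system's dose
optimizer) builds on.

## Coordinate and machine conventions

All patient-frame coordinates are DICOM LPS millimetres (+x patient left,
+y posterior, +z superior), head-first supine. Machine angles:

* gantry 0 places the source anterior (beam travels anterior→posterior,
  +y); gantry 90 places it at the patient's left; rotation is about the
  patient's superior–inferior axis at couch 0.
* the couch rotates about the room-vertical (patient anterior–posterior)
  axis and is applied before the gantry rotation.
* collimator angles are reduced modulo 180°: opposed leaf banks make every
  aperture 180°-periodic.

The beam's-eye view (BEV) is what a viewer looking along the beam sees:
x to the viewer's right, y up (patient superior at couch 0). With this
orientation `(x_bev, y_bev, −beam_dir)` is a right-handed orthonormal
triple.

Projection into the BEV is **parallel (orthographic) by default**. A
divergent (central projection, SAD 1000 mm) mode exists for sensitivity
checks; for cranial targets within ±5 cm of the isocenter the difference at
SAD 1000 mm is below half a millimetre, so the simpler and exactly
symmetrizable parallel model is the default.

The projected outer boundary (POB) of a lesion group is one 2-D convex
hull per lesion. Quasi-ellipsoidal PTVs are convex, so the hull is the
outer boundary; it is also order-free and duplication-free, which the
property tests rely on.

## Isocenter placement

For a group of lesions the isocenter starts at the centroid of the
*equally weighted* lesion centroids (each lesion one point, regardless of
volume). It is then symmetrized: the POB is measured at gantry 0°
(balancing left/right and superior/inferior) and gantry 270° (balancing
anterior/posterior), and the isocenter is shifted by half the imbalance
along the BEV axes. Under parallel projection one pass is exact and the
result equals the 3-D bounding-box center of the grouped surface points —
a closed form the test suite uses as an independent oracle. The loop
(capped at 20 iterations, balance tolerance 0.01 mm) exists so the
divergent mode converges too.

## Feasibility: the projection distance check

A candidate group is feasible when its POB stays inside per-direction
distance limits in the BEV at gantry 0°, 45°, 270° and 315° (couch and
collimator 0°). Defaults per machine:

| machine | X limit per side | Y limit per side | rationale |
|---|---|---|---|
| HD120 | 50 mm | 40 mm | Y cap keeps the field on the 2.5 mm central leaves |
| Millennium 120 | 50 mm | 50 mm | recommended single-isocenter reach |

Comparisons use ≤ with a 1e-6 mm slack, so a boundary exactly at the limit
passes. Limits and check angles are config-overridable. Feasibility is
always evaluated at couch 0, independent of the treatment arcs' couch
angles.

## Lesion grouping

The objective is the sum of squared Euclidean distances (SSED) from each
isocenter to its member lesion *centroids* (one point per lesion; SSED over
surface points would weight large lesions by their point count).

* **Exhaustive route** (≤7 lesions): for k = 1, 2, 3 every set partition
  into k blocks is enumerated (restricted-growth placement; S(7,3) = 301 at
  the largest). Each block gets a symmetrized isocenter and a feasibility
  check; at the first k with any fully feasible partition, the feasible
  partition with minimum total SSED wins. Equal-SSED ties (1e-6 relative)
  break to the lexicographically smallest canonical partition, making the
  result deterministic.
* **k-means route** (>7 lesions, or exhaustive exhausted): k-means++ on the
  lesion centroids, best of `repeats` runs (default = lesion count) by
  within-cluster SSED, escalating k from 1 — or from 4 after an exhaustive
  failure, since k ≤ 3 is then proven infeasible — until every cluster's
  symmetrized isocenter passes the check. The k-means backend is
  scikit-learn's `KMeans` (`init="k-means++"`, `n_init=repeats`), seeded
  from the configured seed.

Both routes minimize the same objective, so on well-separated
configurations they return the same partition (asserted in the tests). A
single lesion that violates the criteria on its own raises a hard error
naming the lesion — no number of isocenters can repair that.

The returned k is minimal by construction on the exhaustive route (complete
enumeration at every smaller k found nothing). On the k-means route
minimality is heuristic, as k-means at k−1 may miss a feasible partition a
complete search would find; the escalation-from-k=1 policy mirrors the
clinical behaviour.

## MLC aperture model

Two machines are modeled from vendor geometry (`src/vmatgeo/data/machines.json`):
HD120 (32 × 2.5 mm central pairs spanning y ∈ [−40, 40] mm, 14 × 5 mm
outer pairs per side) and Millennium 120 (40 × 5 mm central, 10 × 10 mm
outer per side); 60 pairs each.

`fit_leaves` opens, for every leaf pair whose band intersects the POB, a
single X interval from the smallest to the largest clipped X across all
polygons. One pair cannot close between two targets it must span, so the
gap between islands counts toward the opening area — the island-blocking
cost the collimator optimization minimizes. Band clipping is analytic: the
X extrema of a polygon∩band region occur at vertices inside the band or at
edge/boundary crossings, so they are computed edge-parametrically (numpy,
vectorized over bands) without constructing clip polygons. Bands are
half-open `[e_i, e_{i+1})` — a polygon merely touching a leaf boundary does
not open the band above it (positive-height overlap required), avoiding
double counting.

Leaf over-travel and interdigitation limits are deliberately not modeled;
with them the optimal collimator angle can differ by up to ~15° without a
practically relevant change in aperture quality. Jaws are fitted as the
bounding extents of all gantry-sample POBs over an arc plus a configurable
margin (default 0 mm), with the Y edges clamped to ±40 mm on HD120.

## Collimator-angle optimization

For each (cluster, arc) pair the POB is sampled along the gantry rotation;
at each candidate collimator angle the POB is rotated into the MLC frame
(rotation by −angle, MLC held fixed) and the fitted opening areas are
summed over the arc. The angle with the smallest summed area wins; totals
within 1e-9 relative of the minimum count as ties and break to the smallest
angle (pure floating-point argmin would be unstable for rotationally
symmetric targets). The scan covers 0–165° in line with machine rotation
limits; 180°-periodicity makes a wider scan pointless.

Sampling defaults follow the clinically released settings — gantry every
2°, collimator every 5° — with the finer 4°/1° research setting selectable
through `scan.gantry_step_deg` / `scan.coll_step_deg`.

The default arc set is one full arc at couch 0° (gantry 181°→179° CW) and
three 180°-range partial arcs at couch 90°, 45° and 315°, routed on the
side away from the table. Exact partial-arc start/stop values are
site-specific and fully configurable per arc.

## Synthetic cases

`vmatgeo.synthetic` generates multi-metastasis test cases at desk scale:
cluster centers drawn uniformly in a box (rejection-sampled into a cranial
sphere, optionally with a minimum pairwise spacing for planted-structure
experiments), lesion centers scattered isotropically about them
(Gaussian), and lesion surfaces as Fibonacci-lattice sphere point sets.
Defaults — 3 groups × 2 lesions, radii 2–10 mm, 8 mm spread, 80 mm skull
radius — mirror a typical multi-metastasis presentation (a handful of
small, spatially grouped targets). The lattice is deterministic, so a spec
plus seed reproduces bit-identical geometry, hulls and aperture areas.

What the generator does *not* emulate: real contour slice structure,
non-spherical lesion shapes, organs at risk, and dose. Passing tests
therefore demonstrate the geometric algorithms (grouping, placement,
feasibility, aperture fitting) — not dosimetric plan quality, which
requires a dose engine and clinical contours.

## Numerical choices

* Boundary feasibility slack 1e-6 mm; symmetrization balance 0.01 mm,
  ≤20 iterations; SSED tie tolerance 1e-6 relative; collimator tie
  tolerance 1e-9 relative.
* Angle normalization: gantry/couch mod 360, collimator mod 180.
* Degenerate inputs rejected with specific errors: lesions with <4 points,
  collinear projections (named lesion), k larger than the distinct-centroid
  count, POBs beyond the MLC span, X field spans beyond the jaw limit.
* Problem sizes in tests and the acceptance script (16–32 surface points
  per lesion, 50–200 random cases, coarse gantry sampling for end-to-end
  runs) were chosen to exercise every code path at interactive run times;
  all tolerances above are independent of these sizes.

## Known limitations

* Plan *geometry* only: no fluence, MU, or dose metrics.
* Parallel projection is the default; the divergent mode is a sensitivity
  tool, not a validated beam model.
* No couch-angle optimization (the summed-area objective discriminates
  couch angles poorly), no leaf-motion constraints, no dosimetric leaf gap
  or transmission modeling.
* Head-first-supine only; other orientations are rejected rather than
  transformed.
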