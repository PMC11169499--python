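# Methods

This note records the model, its assumptions, the numerical choices and
their rationale, and what the synthetic test conditions do and do not
establish about real applications.

## Model overview

The package estimates demographic connectivity for a generic
broadcast-spawning hermaphroditic coral by Lagrangian particle
tracking: virtual larvae are released inside reef-site polygons, moved
passively through gridded velocity fields, thinned by daily mortality,
and allowed to settle on site polygons during a competency window.  The
per-night result is a transfer-probability matrix between sites;
repeated over spawning nights it yields the consistency classification
of sources and sinks.

The larvae are purely passive: no swimming, no buoyancy ontogeny, no
substrate exploration or metamorphosis delay, and no explicit diffusion.
Vertical motion is advection by the resolved vertical velocity only,
with reflection at the surface and the seabed.  These simplifications
match the modelling tradition the package implements; their main
consequence is that fine-scale retention is driven entirely by the
resolved flow.

## Regionalization

Hexagonal habitat cells carry one of four geomorphic zones (Reef Slope,
Reef Crest, Sheltered Slope, Outer Reef Flat) and a depth.  Zones are
processed independently, so site polygons never mix zones.  Within a
zone:

1. **Adjacency.** Delaunay triangulation of hexagon centroids.  Because
   zoning splits reefs, a zone's hexagons are often spatially
   non-contiguous; triangulation bridges the gaps and guarantees one
   connected graph where nearest-neighbour rules would not.  Degenerate
   inputs (fewer than three hexagons, collinear centroids) fall back to
   a path graph along the principal axis.
2. **Weights.** `w_ij = sqrt(v_ij² + (d_i − d_j)²)`.  The centroid
   distance `v_ij` is normalized by the largest Delaunay edge length in
   the zone graph; the depth difference stays in metres.  This
   interpretation — normalize length, not depth — keeps relative
   geometry dimensionless while preserving the formula's form; it is a
   deliberate reading of an ambiguous convention and is isolated in one
   function should a different normalization be wanted.
3. **MST.** Kruskal's algorithm with ties broken lexicographically by
   (weight, smaller-id pair), making the tree deterministic.  Its
   optimality is pinned against exhaustive spanning-tree enumeration on
   small random graphs.
4. **Partition.** Iterative best-edge removal on the tree: at each step
   the edge whose deletion most reduces summed within-cluster depth
   variance is removed, provided both resulting components keep at
   least `min_size` hexagons (default 200); splitting stops when no
   deletable edge remains or the mean cluster area has reached the
   target site area (default 62,500 m²).  A connected component smaller
   than `min_size` becomes a single site.  Depth variance alone is the
   homogeneity objective; spatial compactness is already enforced by
   tree contiguity.  The number of sites is an outcome, not an input.

## Synthetic environment

The generators produce the statistical structure the analysis assumes,
not a hydrodynamic simulation:

* **Drift–tide–shear fields.**
  `u(t, k) = shear[k]·(mean_u + A·sin(2πt/T))`, likewise for v (the
  cross-drift tidal amplitude can be set independently to model an
  anisotropic tidal ellipse); w = 0.  The time average over whole tidal
  periods is the sheared mean drift — the analytic analogue of a mean
  offshore-to-onshore flow with tidal oscillation.  Default tidal
  period is the M2 constituent (12.42 h).
* **Bathymetry.** Reef platforms: constant crest depth inside a radius,
  half-cosine ramp to the shelf depth outside; overlaps take the
  minimum.  Land is bathymetry ≤ 0; velocities are zeroed on land.
* **Hexagon maps.** Pointy-top lattices of `1 + 3n(n+1)` equal-area
  hexagons; a ring-based zone rule (cycling the four zones by default,
  which deliberately produces non-contiguous zone patches) and a
  monotone depth-versus-distance rule with a small seeded jitter.
* **Scenario transect.** Seven 19-hexagon reef patches, 3 km apart on
  an east–west line, each with a distinct characteristic depth so the
  partition recovers one site per patch.  Hexagons are 200 m across
  (patches ≈ 1 km), sized so a drifting larva spends many 15-min record
  points over each site it crosses.

What the synthetic fields do **not** contain: mesoscale eddies, wind
events, baroclinic instability, curvilinear or unstructured grids,
wetting/drying, or realistic coastlines.  Tests passing on these fields
therefore establish the correctness of the pipeline's mechanics
(integration, nesting, bookkeeping, matrix contracts) and the
qualitative emergent behaviours (drift direction recovery, dimensional
sensitivity), not predictive skill on any real reef.

## Particle tracking

* **Grids and sampling.** Rectilinear grids, hourly snapshots.
  Interpolation is linear in time, bilinear in the horizontal, and
  linear in depth between layer midpoints, clamped at the top/bottom
  midpoints.  Nodal values are reproduced exactly.
* **Nesting.** A query inside the fine rectangle samples the fine
  field; elsewhere the coarse field; outside the coarse rectangle (or
  the shared time coverage) the particle is removed as `exited`.
  Leaving the fine domain alone is not removal — re-entry is allowed.
  A 10⁻⁶-hour tolerance at the coverage edge absorbs floating-point
  accumulation of the step clock.
* **Integrator.** Classical RK4, 5-minute step, positions recorded
  every 15 minutes.  Fourth-order convergence is verified on the
  analytic solid-body-rotation orbit (error ratio ≈ 16 per step
  halving), where multilinear sampling of the linear velocity field is
  exact and the measured error is purely the integrator's.
* **Vertical motion.** z changes only by w; reflection at z = 0 and at
  the bilinear local seabed depth.  In 2-D modes z is carried but
  ignored.
* **Land.** A step whose endpoint falls in a land cell is rejected and
  the particle keeps its position for that step: no permanent beaching,
  matching the no-diffusion assumption.
* **Performance.** The inner loop (chunks of three RK4 steps between
  record points) is compiled with numba; the numpy reference step is
  retained and an equivalence test pins the two to 10⁻¹² relative
  agreement, so the compiled path is an optimization, not a second
  model.

## Larval biology

* **Release.** 61 slots per site per night (every 3 minutes, 20:00 to
  23:00 inclusive), one larva per slot, uniform rejection sampling
  inside the site polygon, depth 2.25 m.  334 sites give 20,374 larvae
  per night.
* **Age.** Measured from each larva's own release event, not from a
  night-level reference; releases span three hours and the competency
  window is defined relative to spawning.
* **Mortality.** Exactly `round(0.40·n)` of the remaining cohort is
  removed at each whole-day age boundary (which is a shared step index
  for a night's cohort, since all larvae use the same step size),
  before that record point's settlement check.  The "remaining-cohort"
  reading is the only self-consistent one: removing 40 % of the
  *original* cohort daily would extinguish it by day 3, before the
  competency window opens.  Exact-fraction thinning (rather than
  per-larva Bernoulli draws) makes the survivor curve deterministic to
  within cumulative rounding: |survivors − N·0.6^d| ≤ d.
* **Settlement.** Checked only at 15-minute record points (the tracking
  cadence), boundary-inclusive point-in-polygon against an STR-tree of
  site polygons, first hit wins, natal site included (self-recruitment
  is a diagonal matrix entry and a cyclic network link).  Tracking
  ceases at settlement.

## Connectivity analysis

`M[i, j]` = settled(i→j)/released(i).  Invariants asserted in code and
tests: entries in [0, 1]; row sums ≤ 1; `M·released` reconstructs
integer settled counts exactly.  A *sink site* is any site with a
positive column sum; a *link* is any positive entry, diagonal included.
Percentages are reported to two decimals in output tables.  Consistency
requires strict positivity on every analysed night; the night set is a
configuration choice.  2-D/3-D comparisons report
`100·(links_3D − links_2D)/links_2D` and the same for sink-site counts;
a zero reference is reported as not comparable rather than infinite.

## Pipeline and reproducibility

Per-stage seeds are derived as `blake2b(master_seed | stage | night)`
mod 2³¹, so stages are reproducible independently and two runs with the
same configuration and master seed produce byte-identical CSV outputs.
Each night×mode produces schedule, trajectory, settlement and matrix
files; the manifest records configuration, status accounting (released
= active + settled + dead + exited, asserted) and output checksums.
Timestamps are scenario-clock hours; a night's releases run 20:00–23:00
of that night's local clock, and any offset to UTC is fixed by the
caller's choice of scenario origin.

## Study-scale defaults versus desk-scale experiments

Biological and numerical defaults are the study protocol: 61 releases
per site per night, 2.25 m release depth, 4–28 d competency, 0.40 d⁻¹
mortality, 5-min step, 15-min records, 30-day tracking, 200-hexagon
minimum site size, 62,500 m² target area.  The bundled experiments use
a 7-site transect, 3 spawning nights and 10-day (directional) or 6-day
(sensitivity) horizons — sizes chosen so that the emergent effects
(competency-delayed downstream settlement; surface export versus
sub-surface retention) are expressed well inside the simulated window
while multi-seed replication stays cheap.  Flow magnitudes (2.5 cm/s
drift, 15 cm/s tidal amplitude, 25 cm/s surface export) are ordinary
shelf values.

## Known limitations

* Rectilinear grids only; curvilinear/unstructured hydrodynamic output
  must be regridded first.
* No diffusion kernel: unresolved sub-grid variability is absent, so
  synthetic connectivity is sharper (more deterministic) than a real
  system's.
* The depth-heterogeneity objective of the tree partition is one
  defensible choice among several; alternatives (adding positional
  variance) would change site shapes in depth-homogeneous areas.
* Settlement has no habitat-quality weighting within a zone and no
  behavioural component.
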