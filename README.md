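# reefconnect

Biophysical modelling of coral-larval dispersal and connectivity within
reef clusters, for marine ecologists and reef managers who need to know
which reef sites consistently act as **sources** of larval recruitment
and which as **sinks** — the information that drives the placement of
protected areas and of active interventions such as out-planting
heat-adapted corals.

The package simulates the full chain for a generic broadcast-spawning
*Acropora*-type coral:

1. **Regionalization** — habitat hexagons with geomorphic-zone labels
   (Reef Slope, Reef Crest, Sheltered Slope, Outer Reef Flat) are merged
   into reef-site polygons: per zone, a Delaunay triangulation of
   hexagon centroids yields a connected adjacency graph even across
   spatially separate patches; each edge gets the weight
   `w_ij = sqrt(v_ij² + (d_i − d_j)²)` (normalized centroid distance
   `v_ij`, hexagon depths `d_i`, `d_j`); a minimum spanning tree of the
   graph is split into depth-homogeneous clusters of at least 200
   hexagons with a target site area of 62,500 m².
2. **Release** — on each spawning night, one virtual larva per site
   every 3 minutes from 20:00 to 23:00 inclusive (61 per site), at a
   uniformly random point inside the site polygon, 2.25 m deep.
3. **Dispersal** — passive RK4 advection at a 5-minute step with
   positions recorded every 15 minutes, through hourly velocity fields
   on a fine grid nested inside a coarse outer grid; runs can be forced
   with surface-2D, depth-averaged-2D or full-3D velocities.  Particles
   leaving the outer domain are removed; leaving the fine domain is not
   removal (re-entry is allowed).
4. **Biology** — daily removal of 40 % of the remaining cohort
   (0.40 d⁻¹ mortality); settlement allowed between 4 and 28 days after
   release (the competency window), instantly on the first site polygon
   a larva is recorded over, the natal site included.
5. **Connectivity** — per night, the matrix `M[i, j]` = proportion of
   larvae released at site *i* that settled at site *j* (row sums ≤ 1;
   column sums may exceed 1), from which the analysis derives settled
   and sink-site percentages, link counts (self-loops included), and the
   classification of *consistent* sources/sinks: sites whose source
   (sink) strength is positive on **every** analysed spawning night.

Real hydrodynamic archives are not required: the
`synthetic_environment` and `scenarios` modules generate analytic
drift–tide–shear fields, reef-platform bathymetry and hexagon habitat
maps with the structure the analysis assumes, so the entire pipeline
runs and is tested at desk scale.

## Worked example

`examples/` contains one narrative script per capability.  The
end-to-end run (`python examples/06_full_pipeline.py` — three spawning
nights, all three velocity modes, 10-day tracking, seven sites on an
east–west transect under a westward drift with tide) prints, among
other output:

```
    full3d  night-0         7.96           71.43        9
    full3d  night-1         8.43           71.43        9
    full3d  night-2         9.37           71.43        8
 surface2d  night-0         5.62           57.14        4
...
consistent sources: ['ReefCrest-000', 'ReefCrest-001', 'ReefCrest-002', 'ReefCrest-003']
consistent sinks:   ['ReefCrest-002', 'ReefCrest-003', 'ReefCrest-004', 'ReefCrest-005', 'ReefCrest-006']
```

Columns are the percentage of released larvae that settled, the
percentage of sites that received settlers, and the number of network
links per night.  Full-3D forcing resolves more links and sink sites
than surface-2D forcing, and the consistent sinks (high site numbers =
west) sit downstream of the consistent sources (low numbers = east) —
the directional source→sink structure a mean drift imposes on a reef
network.

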