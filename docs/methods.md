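# Methods

## Model overview

The pipeline measures geographic accessibility to children's hospitals
in five stages, each a pure function of the previous stage's artifact:

1. **Region** — counties with demographic counts, hospital points with
   bed counts, and an undirected road graph whose edges carry a length
   and a speed (travel time in minutes = length_km / speed_kmh × 60).
2. **Service areas** — per hospital, single-source Dijkstra travel times
   from the hospital's network node; an edge is reached for the fraction
   of its length coverable with the budget remaining at either endpoint
   (partial reach from both ends merged, capped at 1). The service-area
   polygon is the union of all reached (partial) edge segments buffered
   by `buffer_m`, plus the buffered hospital point. One polygon per
   hospital; overlaps are never dissolved.
3. **Planarization** — the union of all service-area boundaries is
   polygonized into disjoint faces; each face is labeled with the set of
   input polygons containing a guaranteed-interior representative point.
   The face set tiles the union of the inputs, and its labels are
   validated in the tests by a Monte-Carlo point-in-polygon oracle.
4. **Demography** — areal-weighted interpolation: a target polygon
   receives from each county `count × area(county ∩ target) / area(county)`.
   The estimator assumes uniform density within counties; it is
   mass-preserving (a partition of the region reproduces the totals),
   additive and monotone. Counties are classified inside / partial /
   outside the service-area union with a 1e-9 relative-area tolerance;
   "covered" means inside or partial.
5. **Capacity and report** — a face's bed supply is the summed beds of
   its covering hospitals; beds per 1000 children = beds / children ×
   1000, computed per face (per overlapping service area, not for the
   dissolved union). The coverage report tabulates totals, inside,
   outside and percentage shares for total population, children,
   households and carless households.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `threshold_min` | 60 | travel-time budget (minutes); the one-hour accessibility standard |
| `buffer_m` | 500 | half-width of the buffered street union forming the polygon (m) |
| `min_face_area_km2` | 1e-6 | faces below this (1 m²) are merged into the neighbor sharing the longest boundary, absorbing float slivers |
| `min_pop` | 1 | child population below which a face's beds-per-1000 is reported undefined instead of dividing by ~0 |
| `snap_tolerance_m` | 1 | maximum hospital-to-node snapping distance |

Rounding: interpolated counts stay real-valued internally; percentages
round half-up — 1 decimal for population and county shares, whole
percent for household rows. Beds per 1000 is reported to 1 decimal.

## The synthetic region

The generator emulates the statistical structure of a large state
analyzed at county level, scaled down so the full pipeline runs in
seconds: an 8×8 grid of 20 km square counties (counties as grid cells
make intersection areas exact in tests); 3 metro counties with mean
population 800,000 against a rural mean of 20,000; a child share drawn
around 25% per county; households at a fixed mean size of 2.8 persons;
carless households at 4% of metro and 8% of rural households (≈5%
overall, concentrated in rural counties); 6 hospitals placed at road
nodes inside metro counties with beds drawn around a mean of 150
(minimum 1).

The road network is a 1 km square lattice at 40 km/h with the lattice
edges along the L-shaped paths between consecutive metro centers
upgraded to 90 km/h highways. With 1 km spacing, the 500 m street buffer
exactly fills the lattice cells, so service areas are solid regions, as
they would be over a real street network whose local-road spacing is
well below the buffer width. Generation is fully deterministic for a
fixed spec and seed (same inputs give byte-identical files).

What the generator does *not* emulate: real county shapes, heterogeneous
within-county density (the interpolation's uniformity assumption is
exactly true here, so interpolation error on real data is not measured),
one-way streets, turn penalties, traffic, and helicopter/EMS transport.
Passing tests therefore demonstrate the correctness of the pipeline's
operators and their invariants, not the realism of any particular
coverage percentage.

## Numerical choices

- Shortest paths via Dijkstra (networkx); correctness cross-checked in
  tests against an independent brute-force Bellman–Ford relaxation on
  graphs of ≤ 50 nodes (tolerance 1e-9 min). Shortest-path ties are
  irrelevant: only distances enter the reachability computation.
- Edges in components disconnected from the origin get fraction 0.
- Buffers use 8 quadrant segments, keeping disc areas within ~0.7% of
  πr²; reached segments are buffered individually and unioned once,
  which is markedly faster than buffering the merged multiline on
  lattice-sized networks and identical up to float noise.
- Face labeling uses representative interior points; points on face
  boundaries are deliberately unclassified (either adjacent label is
  acceptable). No exact-arithmetic geometry kernel is used; robustness
  is tolerance-based.
- At full coverage the interpolated inside value is clamped to the total
  to absorb float overshoot, keeping inside + outside = total.

## Design choices

- The per-face supply attribution (every hospital whose service area
  covers the face) keeps the hospital-density and beds-per-capita layers
  mutually consistent; an alternative — counting only hospitals located
  inside the face — would decouple them.
- Beds per capita is defined as beds / children × 1000 (the "beds per
  1000 children" reading); with `min_pop` guarding near-empty faces.
- The household inside/outside split uses areal interpolation by
  default; a `whole`-county assignment (a county's households count as
  inside if the county intersects the union at all) is available via
  `--county-assignment whole` and gives an upper bound.
- At a zero travel budget the service area degenerates to the 500 m disc
  around the hospital, so counties containing a hospital are still
  "partially covered" — a consequence of the buffered-streets polygon
  definition, asserted as such in the tests.

## Problem sizes

Tests run on 3×3 to 5×4 county grids and ≤ 50-node random graphs; the
end-to-end determinism check uses a 4×4-county region with 3 hospitals.
The analysis scripts and the acceptance run use the default 8×8 region
(25,921 road nodes, 51,520 edges, 6 hospitals), chosen as the smallest
region exhibiting the metro/rural contrast with several distinct metro
clusters.

## Known limitations

- The service-area polygon is a buffered street union, not the
  generalized hull a commercial network-analyst tool draws; polygon
  shapes (and hence face counts) are method-dependent even when the
  underlying reachable street set is identical.
- Undirected travel at free-flow speeds; no time-of-day variation.
- Areal interpolation inherits the uniform-density assumption; with
  strongly clustered within-county populations it can misallocate
  population near service-area edges (dasymetric refinement is out of
  scope).
- Counts are independent across attributes: the interpolation does not
  enforce child_pop ≤ total_pop within an arbitrary target, though both
  are interpolated with the same weights so the inequality is preserved.
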