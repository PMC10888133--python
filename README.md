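# pedaccess

Spatial accessibility of children's hospitals: travel-time service areas
over a road network, overlap planarization, areal-weighted population
interpolation, and hospital-bed supply per capita.

## The problem

Children needing emergency or specialty pediatric care can only use a
hospital they can physically reach in time; an hour's drive is the
conventional accessibility threshold. In large states with vast rural
areas, most children's hospitals cluster in a few metro areas, so
accessibility is driven by three things this package measures together:

1. **Reach** — which locations are within a 60-minute drive of a
   children's hospital, computed over the road network (not straight-line
   distance): each hospital's *service area* is the region encompassing
   all street segments reachable within the travel-time budget.
2. **Supply density** — service areas of nearby hospitals overlap.
   Keeping one polygon per hospital (overlap, not dissolve) and
   *planarizing* the set into disjoint faces labeled with their covering
   hospitals gives, per face, the number of reachable hospitals and the
   summed bed supply. Beds per 1000 children for a face is

   `beds_per_1000 = (Σ beds of covering hospitals) / (children in face) × 1000`

   where the face's child population comes from areal-weighted
   interpolation of county counts:

   `children(face) = Σ_county child_pop_county × area(county ∩ face) / area(county)`

3. **Who is left out** — county coverage, and the population, household
   and carless-household counts inside vs outside the union of all
   service areas (a household without a vehicle outside the union faces
   the steepest access barrier).

Everything runs on a synthetic region with the metro/rural structure the
analysis assumes (dense metro clusters holding the hospitals, a sparse
rural periphery, ~25% children per county, carless households
concentrated in rural counties), so no proprietary GIS data is needed.
Coordinates are planar meters throughout.

## Worked example

The numbered scripts under `analysis/` run the pipeline stage by stage
(each writes its artifact under `results/`):

```bash
python analysis/01_generate_region.py
python analysis/02_service_areas.py
python analysis/03_planarize_overlaps.py
python analysis/04_interpolate_population.py
python analysis/05_bed_capacity.py
python analysis/06_coverage_report.py
```

With the default region (64 counties, 6 hospitals in 3 metro clusters,
seed 0) this prints, among other lines:

```
6 overlapping service areas -> 173 disjoint faces
children inside the service-area union: 667,372 of 891,460 (74.9%)
counties completely or partially covered: 32 of 64 (50.0%)
beds per 1000 children: min 1.2, median 65,280.9, max 345,575.9
carless households inside: 45,677 (64%); outside: 25,523
```

Reading: half the counties touch a 60-minute service area, and they hold
three quarters of the children (children concentrate in metros, which
the hospitals cover). The per-face bed supply spans five orders of
magnitude: the densest metro-core face has 1.2 beds per 1000 children,
while sparsely populated fringe faces reachable from several hospitals
show huge per-capita supply — bed availability is lowest exactly where
demand is concentrated. Carless households are covered at a *lower* rate
(64%) than households overall (76%) because they are disproportionately
rural.

The same pipeline is scriptable via the CLI (`pedaccess generate`,
`service-areas`, `overlay`, `interpolate`, `capacity`, `report`, `run`,
`validate`) or the library API (`pedaccess.generate_region`,
`service_areas_for_all`, `planarize`, `areal_interpolate`,
`capacity_table`, `build_report`).

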