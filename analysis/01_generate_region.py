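#!/usr/bin/env python
"""Generate the synthetic study region.

An 8x8 grid of 20 km counties with three metro clusters holding the six
children's hospitals, county demographics (about 25% children; carless
households 4% of metro and 8% of rural households), and a 1 km road
lattice with a 90 km/h highway overlay linking the metro centers.
Writes counties.geojson, hospitals.geojson, nodes.csv/edges.csv and the
region manifest under results/region/.
"""

from pathlib import Path

import pedaccess as pa

OUT = Path(__file__).resolve().parent.parent / "results" / "region"

spec = pa.RegionSpec(seed=0)
region = pa.generate_region(spec)
pa.write_region(region, OUT, spec)

children = sum(c.child_pop for c in region.counties)
total = sum(c.total_pop for c in region.counties)
print(f"region: {len(region.counties)} counties, {len(region.hospitals)} hospitals, "
      f"{len(region.network.nodes)} road nodes")
print(f"population {total:,.0f}, children {children:,.0f} "
      f"({pa.percentage(children, total, 1)}%)")
print(f"written to {OUT}")
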