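#!/usr/bin/env python
"""Compute each hospital's sixty-minute service area.

One polygon per hospital (overlap retained, never dissolved): the union
of all street segments reachable within 60 minutes of driving, buffered
by 500 m. Writes results/pipeline/service_areas.geojson.
"""

from pathlib import Path

import pedaccess as pa
from pedaccess import io as pio

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "pipeline"
OUT.mkdir(parents=True, exist_ok=True)

region = pa.read_region(ROOT / "region")
areas = pa.service_areas_for_all(region, threshold_min=60.0, buffer_m=500.0)
pio.write_service_areas(OUT / "service_areas.geojson", areas)

for sa in areas:
    reached = sum(1 for f in sa.reached_edge_fractions.values() if f > 0)
    print(f"{sa.hospital_id}: area {sa.polygon.area / 1e6:,.0f} km^2, "
          f"{reached} street segments reached")
print(f"wrote {len(areas)} service areas to {OUT / 'service_areas.geojson'}")
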