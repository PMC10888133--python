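#!/usr/bin/env python
"""Planarize the overlapping service areas into disjoint labeled faces.

Decomposes the service areas into interior-disjoint faces, each labeled
with the set of hospitals whose service area covers it; the overlap
count per face is the hospital-density layer. Writes
results/pipeline/faces.geojson.
"""

from collections import Counter
from pathlib import Path

import pedaccess as pa
from pedaccess import io as pio

OUT = Path(__file__).resolve().parent.parent / "results" / "pipeline"

areas = pio.read_service_areas(OUT / "service_areas.geojson")
arrangement = pa.planarize(areas)
pio.write_faces(OUT / "faces.geojson", arrangement)

counts = Counter(f.overlap_count for f in arrangement.faces)
print(f"{len(areas)} overlapping service areas -> {len(arrangement.faces)} disjoint faces")
for k in sorted(counts):
    area_km2 = sum(f.polygon.area for f in arrangement.faces if f.overlap_count == k) / 1e6
    print(f"  reachable from {k} hospital(s): {counts[k]} faces, {area_km2:,.0f} km^2")
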