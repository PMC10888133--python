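#!/usr/bin/env python
"""Areal-weighted child population of every planarized face.

Each face's child population is the sum over counties of the county's
children times the fraction of the county's area intersecting the face
(uniform within-county density). Writes results/pipeline/interpolation.csv
and the county coverage classification.
"""

from pathlib import Path

import pandas as pd
from shapely.ops import unary_union

import pedaccess as pa
from pedaccess import io as pio

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "pipeline"

region = pa.read_region(ROOT / "region")
arrangement = pio.read_faces(OUT / "faces.geojson")
areas = pio.read_service_areas(OUT / "service_areas.geojson")

rows = []
for face in arrangement.faces:
    r = pa.areal_interpolate(region.counties, face.polygon, "child_pop", face.face_id)
    rows.append({"target_id": r.target_id, "attribute": r.attribute,
                 "value": r.value, "n_contributing_counties": len(r.contributions)})
df = pd.DataFrame(rows)
df.to_csv(OUT / "interpolation.csv", index=False)

union = unary_union([sa.polygon for sa in areas])
classes = pa.classify_counties(region.counties, union)
pd.DataFrame(sorted(classes.items()), columns=["county_id", "class"]).to_csv(
    OUT / "county_coverage.csv", index=False)

children_total = sum(c.child_pop for c in region.counties)
children_inside = pa.areal_interpolate(region.counties, union, "child_pop").value
print(f"children inside the service-area union: {children_inside:,.0f} of "
      f"{children_total:,.0f} ({pa.percentage(children_inside, children_total, 1)}%)")
print(f"face child populations written for {len(df)} faces; "
      f"largest face holds {df.value.max():,.0f} children")
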