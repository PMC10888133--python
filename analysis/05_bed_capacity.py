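#!/usr/bin/env python
"""Hospital beds per 1000 children for every planarized face.

A face's supply is the summed beds of every hospital whose service area
covers it; demand is its interpolated child population. Writes
results/pipeline/capacity.csv.
"""

from pathlib import Path

import pedaccess as pa
from pedaccess import io as pio
from pedaccess.capacity import capacity_frame

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "pipeline"

region = pa.read_region(ROOT / "region")
arrangement = pio.read_faces(OUT / "faces.geojson")
rows = pa.capacity_table(arrangement, region.hospitals, region.counties)
frame = capacity_frame(rows)
frame.to_csv(OUT / "capacity.csv", index=False)

defined = frame.dropna(subset=["beds_per_1000"])
print(f"{len(frame)} faces, {len(defined)} with a defined beds-per-1000 value")
print(f"beds per 1000 children: min {defined.beds_per_1000.min():,.1f}, "
      f"median {defined.beds_per_1000.median():,.1f}, "
      f"max {defined.beds_per_1000.max():,.1f}")
dense = defined.nlargest(3, "child_pop")
print("most populous faces (metro cores) have the scarcest beds:")
for r in dense.itertuples():
    print(f"  {r.face_id}: {r.child_pop:,.0f} children, {r.total_beds} beds "
          f"-> {r.beds_per_1000} per 1000")
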