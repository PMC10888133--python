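#!/usr/bin/env python
"""Coverage statistics: population, counties, and vehicle availability.

Summarizes who lives inside and outside the union of the sixty-minute
service areas: total and child population, households, and households
without a vehicle. Writes results/pipeline/report.json and report.md.
"""

from pathlib import Path

import pedaccess as pa
from pedaccess import io as pio
from pedaccess.report import report_markdown

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "pipeline"

region = pa.read_region(ROOT / "region")
areas = pio.read_service_areas(OUT / "service_areas.geojson")
rep = pa.build_report(region.counties, areas)

pio.write_json(OUT / "report.json", rep.to_dict())
(OUT / "report.md").write_text(report_markdown(rep))

print(f"counties completely or partially covered: {rep.counties_covered} of "
      f"{rep.counties_total} ({rep.county_share_pct}%)")
print(f"children inside: {rep.inside['child_pop']:,.0f} of "
      f"{rep.totals['child_pop']:,.0f} ({rep.shares['child_pop']}%)")
print(f"children outside: {rep.outside['child_pop']:,.0f}")
print(f"households inside: {rep.inside['households']:,.0f} "
      f"({rep.shares['households']:.0f}%)")
print(f"carless households inside: {rep.inside['no_vehicle_households']:,.0f} "
      f"({rep.shares['no_vehicle_households']:.0f}%); "
      f"outside: {rep.outside['no_vehicle_households']:,.0f}")
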