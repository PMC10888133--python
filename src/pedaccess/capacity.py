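"""Hospital-bed supply per 1000 children for each planarized face.

A face's bed supply is the sum of beds of every hospital whose service
area covers it (exactly the face's covering set from the planarization),
and its demand is the child population interpolated into the face
polygon. Beds per 1000 children = beds / children x 1000; faces with
fewer than ``min_pop`` interpolated children are flagged undefined rather
than reported as a near-division-by-zero.

Because supply is attributed to every face a hospital's service area
covers, low-population faces reachable from several hospitals show high
per-capita supply while dense metro cores show low supply — the
demand/supply contrast the metric is designed to expose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .demography import areal_interpolate
from .overlay import Arrangement
from .types import County, Hospital, hospitals_by_id

DEFAULT_MIN_POP = 1.0


@dataclass
class FaceCapacity:
    face_id: str
    child_pop: float
    total_beds: int
    beds_per_1000: float | None  # None = undefined (child_pop below min_pop)
    overlap_count: int


def face_bed_supply(arrangement: Arrangement, hospitals: list[Hospital]) -> dict[str, int]:
    """Total beds available to each face from its covering hospitals."""
    by_id = hospitals_by_id(hospitals)
    supply: dict[str, int] = {}
    for face in arrangement.faces:
        missing = face.hospital_ids - by_id.keys()
        if missing:
            raise KeyError(
                f"face {face.face_id} references unknown hospital(s): {sorted(missing)}"
            )
        supply[face.face_id] = sum(by_id[h].beds for h in face.hospital_ids)
    return supply


def beds_per_1000(
    total_beds: float, child_pop: float, min_pop: float = DEFAULT_MIN_POP
) -> float | None:
    """Beds per 1000 resident children; None when the population is below min_pop."""
    if total_beds < 0 or child_pop < 0:
        raise ValueError("total_beds and child_pop must be >= 0")
    if child_pop < min_pop:
        return None
    return total_beds / child_pop * 1000.0


def capacity_table(
    arrangement: Arrangement,
    hospitals: list[Hospital],
    counties: list[County],
    min_pop: float = DEFAULT_MIN_POP,
) -> list[FaceCapacity]:
    """Per-face child population, bed supply, and beds per 1000 children."""
    supply = face_bed_supply(arrangement, hospitals)
    rows = []
    for face in arrangement.faces:
        children = areal_interpolate(
            counties, face.polygon, "child_pop", target_id=face.face_id
        ).value
        rows.append(
            FaceCapacity(
                face_id=face.face_id,
                child_pop=children,
                total_beds=supply[face.face_id],
                beds_per_1000=beds_per_1000(supply[face.face_id], children, min_pop),
                overlap_count=face.overlap_count,
            )
        )
    return rows


def capacity_frame(rows: list[FaceCapacity]) -> pd.DataFrame:
    """Tabular view, beds_per_1000 rounded to 1 decimal (NaN where undefined)."""
    return pd.DataFrame(
        {
            "face_id": [r.face_id for r in rows],
            "child_pop": [r.child_pop for r in rows],
            "total_beds": [r.total_beds for r in rows],
            "beds_per_1000": [
                math.nan if r.beds_per_1000 is None else round(r.beds_per_1000, 1)
                for r in rows
            ],
            "overlap_count": [r.overlap_count for r in rows],
        }
    )
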