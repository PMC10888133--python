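"""Planarize overlapping service areas into disjoint labeled faces.

The open equivalent of a count-overlapping-features step: the union of all
service-area boundaries is polygonized into disjoint faces, and each face
is labeled with the set of hospitals whose service area covers it. The
face is the unit at which hospital density (the overlap count) and beds
per capita are reported.

Labeling uses a guaranteed-interior representative point per face; its
correctness is enforced by a Monte-Carlo point-in-polygon oracle in the
test suite. Faces smaller than ``min_face_area_km2`` (floating-point
slivers) are merged into the neighbor sharing the longest boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry
from shapely.ops import polygonize, unary_union
from shapely.prepared import prep

from .network_isochrone import ServiceArea
from .types import ValidationError

DEFAULT_MIN_FACE_AREA_KM2 = 1e-6

_M2_PER_KM2 = 1e6


@dataclass
class PlanarFace:
    """A disjoint face of the arrangement, labeled with its covering hospitals."""

    face_id: str
    polygon: BaseGeometry
    hospital_ids: frozenset[str]

    @property
    def overlap_count(self) -> int:
        return len(self.hospital_ids)


@dataclass
class Arrangement:
    faces: list[PlanarFace] = field(default_factory=list)
    source_count: int = 0

    @property
    def union_area(self) -> float:
        return sum(f.polygon.area for f in self.faces)


def planarize(
    service_areas: list[ServiceArea],
    min_face_area_km2: float = DEFAULT_MIN_FACE_AREA_KM2,
) -> Arrangement:
    """Decompose overlapping service areas into interior-disjoint labeled faces.

    The face set is independent of input order up to face_id relabeling;
    the faces tile the union of the inputs exactly (up to float tolerance).
    """
    if not service_areas:
        raise ValidationError("planarize requires at least one service area")
    for sa in service_areas:
        if not sa.polygon.is_valid:
            raise ValidationError(f"invalid service-area geometry for hospital {sa.hospital_id}")

    boundaries = unary_union([sa.polygon.boundary for sa in service_areas])
    raw_faces = list(polygonize(boundaries))

    prepared = [(sa.hospital_id, prep(sa.polygon)) for sa in service_areas]
    labeled: list[tuple[BaseGeometry, frozenset[str]]] = []
    for geom in raw_faces:
        rp = geom.representative_point()
        ids = frozenset(hid for hid, p in prepared if p.contains(rp))
        if ids:  # faces inside holes of the union carry no hospital and are dropped
            labeled.append((geom, ids))

    labeled = _merge_slivers(labeled, min_face_area_km2 * _M2_PER_KM2)

    # deterministic ordering regardless of input order
    labeled.sort(key=lambda t: (t[0].representative_point().x, t[0].representative_point().y))
    faces = [
        PlanarFace(face_id=f"f{i:04d}", polygon=geom, hospital_ids=ids)
        for i, (geom, ids) in enumerate(labeled)
    ]
    return Arrangement(faces=faces, source_count=len(service_areas))


def _merge_slivers(
    labeled: list[tuple[BaseGeometry, frozenset[str]]], min_area_m2: float
) -> list[tuple[BaseGeometry, frozenset[str]]]:
    """Absorb sub-tolerance faces into the neighbor sharing the longest boundary."""
    big = [(g, ids) for g, ids in labeled if g.area >= min_area_m2]
    small = [(g, ids) for g, ids in labeled if g.area < min_area_m2]
    if not small or not big:
        return labeled
    merged = [list(t) for t in big]
    for g, _ in small:
        shared = [g.boundary.intersection(h.boundary).length for h, _ in merged]
        j = max(range(len(merged)), key=lambda k: shared[k])
        merged[j][0] = unary_union([merged[j][0], g])
    return [(g, ids) for g, ids in merged]


def overlap_count_at(service_areas: list[ServiceArea], point) -> int:
    """Number of service-area polygons strictly containing *point*.

    For a point interior to a face this equals the face's overlap count;
    points on boundaries may return either adjacent count.
    """
    pt = point if isinstance(point, Point) else Point(point)
    return sum(1 for sa in service_areas if sa.polygon.contains(pt))
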