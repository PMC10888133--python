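"""Travel-time service areas over the road network.

A service area is the region encompassing every street segment reachable
from a hospital within a travel-time budget (60 minutes by default),
computed with single-source shortest paths over the undirected road graph
and realized geometrically as the buffered union of the reached (possibly
partial) edge segments. One polygon is produced per hospital; overlapping
areas are never dissolved together, so downstream planarization can count
how many hospitals cover each location.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import shapely
from shapely.geometry import LineString
from shapely.geometry.base import BaseGeometry
from shapely.ops import substring

from .types import Hospital, Region, RoadNetwork, ValidationError

DEFAULT_THRESHOLD_MIN = 60.0
DEFAULT_BUFFER_M = 500.0
#: segments per quarter circle in buffer offsets; 8 keeps disc areas within ~0.7%
BUFFER_QUAD_SEGS = 8


@dataclass
class ServiceArea:
    """One hospital's reachable region at a travel-time threshold."""

    hospital_id: str
    threshold_min: float
    polygon: BaseGeometry
    reached_edge_fractions: dict[str, float] = field(default_factory=dict)


def edge_travel_time(length_m: float, speed_kmh: float) -> float:
    """Traversal time of an edge, in minutes."""
    if length_m <= 0:
        raise ValidationError(f"length_m must be > 0 (got {length_m})")
    if speed_kmh <= 0:
        raise ValidationError(f"speed_kmh must be > 0 (got {speed_kmh})")
    return (length_m / 1000.0) / speed_kmh * 60.0


def node_travel_times(network: RoadNetwork, origin: str) -> dict[str, float]:
    """Shortest-path travel time (minutes) from *origin* to every reachable node."""
    g = network.graph
    if origin not in g:
        raise KeyError(f"origin node {origin!r} not in network")
    return nx.single_source_dijkstra_path_length(g, origin, weight="time_min")


def _directional_fractions(
    network: RoadNetwork, times: dict[str, float], threshold_min: float
) -> dict[str, tuple[float, float]]:
    """Per edge: fraction reachable entering from each endpoint, clipped to [0, 1]."""
    out = {}
    for e in network.edges:
        w = e.travel_time_min
        tu = times.get(e.from_node, float("inf"))
        tv = times.get(e.to_node, float("inf"))
        fu = min(1.0, max(0.0, (threshold_min - tu) / w))
        fv = min(1.0, max(0.0, (threshold_min - tv) / w))
        out[e.edge_id] = (fu, fv)
    return out


def reachable_subnetwork(
    network: RoadNetwork, origin: str, threshold_min: float
) -> dict[str, float]:
    """Fraction of each edge reachable within *threshold_min* from *origin*.

    An edge is covered from either endpoint with the budget remaining
    there; partial reach from both ends is merged and capped at 1.
    Edges in components unreachable from the origin get fraction 0.
    """
    if threshold_min < 0:
        raise ValidationError(f"threshold_min must be >= 0 (got {threshold_min})")
    times = node_travel_times(network, origin)
    return {
        eid: min(1.0, fu + fv)
        for eid, (fu, fv) in _directional_fractions(network, times, threshold_min).items()
    }


def build_service_area(
    network: RoadNetwork,
    hospital: Hospital,
    threshold_min: float = DEFAULT_THRESHOLD_MIN,
    buffer_m: float = DEFAULT_BUFFER_M,
    snap_tolerance_m: float | None = None,
) -> ServiceArea:
    """Polygon enclosing all streets reachable from *hospital* within the budget.

    The hospital is snapped to the nearest network node (an error if it is
    farther than ``snap_tolerance_m``, when given); each reached edge
    portion is buffered by ``buffer_m`` and unioned with the buffered
    hospital point.
    """
    if buffer_m <= 0:
        raise ValidationError(f"buffer_m must be > 0 (got {buffer_m})")
    origin, snap_d = network.nearest_node(hospital.point)
    if snap_tolerance_m is not None and snap_d > snap_tolerance_m:
        raise ValidationError(
            f"hospital {hospital.hospital_id} is {snap_d:.1f} m from the nearest "
            f"network node (snap tolerance {snap_tolerance_m} m)"
        )
    times = node_travel_times(network, origin)
    directional = _directional_fractions(network, times, threshold_min)

    pieces = []
    fractions: dict[str, float] = {}
    for e in network.edges:
        fu, fv = directional[e.edge_id]
        fractions[e.edge_id] = min(1.0, fu + fv)
        if fu <= 0.0 and fv <= 0.0:
            continue
        seg = LineString([network.nodes[e.from_node], network.nodes[e.to_node]])
        if fu + fv >= 1.0:
            pieces.append(seg)
        else:
            if fu > 0.0:
                pieces.append(substring(seg, 0.0, fu, normalized=True))
            if fv > 0.0:
                pieces.append(substring(seg, 1.0 - fv, 1.0, normalized=True))

    # buffering pieces individually and unioning once is much faster than
    # buffering the merged multiline on lattice-sized networks
    geoms = np.array(pieces + [hospital.point], dtype=object)
    polygon = shapely.union_all(shapely.buffer(geoms, buffer_m, quad_segs=BUFFER_QUAD_SEGS))
    return ServiceArea(
        hospital_id=hospital.hospital_id,
        threshold_min=threshold_min,
        polygon=polygon,
        reached_edge_fractions=fractions,
    )


def service_areas_for_all(
    region: Region,
    threshold_min: float = DEFAULT_THRESHOLD_MIN,
    buffer_m: float = DEFAULT_BUFFER_M,
    snap_tolerance_m: float | None = None,
) -> list[ServiceArea]:
    """One (never-dissolved) service area per hospital, sorted by hospital id."""
    areas = [
        build_service_area(region.network, h, threshold_min, buffer_m, snap_tolerance_m)
        for h in region.hospitals
    ]
    areas.sort(key=lambda sa: sa.hospital_id)
    return areas
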