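"""Core domain objects shared across the pipeline.

All coordinates are planar meters (no geographic CRS); geometries are
shapely objects. Counties are the areal-interpolation source zones,
hospitals the supply points and isochrone origins, and the road network
the medium over which travel-time service areas are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable

import networkx as nx
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry


class ValidationError(ValueError):
    """An input object violates a documented invariant."""


@dataclass(frozen=True)
class County:
    """A source zone: polygon plus the demographic counts interpolated from it."""

    county_id: str
    polygon: BaseGeometry
    total_pop: float
    child_pop: float
    households: float
    no_vehicle_households: float

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValidationError(f"county {self.county_id}: invalid or empty polygon")
        if not 0 <= self.child_pop <= self.total_pop:
            raise ValidationError(
                f"county {self.county_id}: child_pop {self.child_pop} "
                f"outside [0, total_pop={self.total_pop}]"
            )
        if not 0 <= self.no_vehicle_households <= self.households:
            raise ValidationError(
                f"county {self.county_id}: no_vehicle_households "
                f"{self.no_vehicle_households} outside [0, households={self.households}]"
            )


@dataclass(frozen=True)
class Hospital:
    """A supply facility: point location and licensed pediatric bed count."""

    hospital_id: str
    point: Point
    beds: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.beds < 1:
            raise ValidationError(f"hospital {self.hospital_id}: beds must be >= 1")


@dataclass(frozen=True)
class RoadEdge:
    edge_id: str
    from_node: str
    to_node: str
    length_m: float
    speed_kmh: float

    def __post_init__(self) -> None:
        if self.length_m <= 0:
            raise ValidationError(f"edge {self.edge_id}: length_m must be > 0")
        if self.speed_kmh <= 0:
            raise ValidationError(f"edge {self.edge_id}: speed_kmh must be > 0")

    @property
    def travel_time_min(self) -> float:
        return (self.length_m / 1000.0) / self.speed_kmh * 60.0


@dataclass
class RoadNetwork:
    """Undirected road graph: nodes with planar coordinates, edges with travel times.

    Traversal is allowed both ways at equal cost; there are no turn
    penalties or one-way restrictions.
    """

    nodes: dict[str, tuple[float, float]]
    edges: list[RoadEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.from_node not in self.nodes or e.to_node not in self.nodes:
                raise ValidationError(
                    f"edge {e.edge_id}: endpoint missing from node table"
                )

    @cached_property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for nid, (x, y) in self.nodes.items():
            g.add_node(nid, x=x, y=y)
        for e in self.edges:
            # parallel edges collapse to the fastest one; lattice generators
            # never emit them, but imported networks might
            w = e.travel_time_min
            if g.has_edge(e.from_node, e.to_node):
                if g[e.from_node][e.to_node]["time_min"] <= w:
                    continue
            g.add_edge(
                e.from_node,
                e.to_node,
                edge_id=e.edge_id,
                time_min=w,
                length_m=e.length_m,
            )
        return g

    def nearest_node(self, point: Point) -> tuple[str, float]:
        """Return (node_id, distance_m) of the node closest to *point*."""
        best_id, best_d = None, float("inf")
        for nid, (x, y) in self.nodes.items():
            d = ((x - point.x) ** 2 + (y - point.y) ** 2) ** 0.5
            if d < best_d:
                best_id, best_d = nid, d
        if best_id is None:
            raise ValidationError("network has no nodes")
        return best_id, best_d


@dataclass
class Region:
    """A complete study region: counties, hospitals and the road network."""

    counties: list[County]
    hospitals: list[Hospital]
    network: RoadNetwork
    crs_note: str = "planar meters, non-geographic"

    def county_by_id(self, county_id: str) -> County:
        for c in self.counties:
            if c.county_id == county_id:
                return c
        raise KeyError(county_id)


def hospitals_by_id(hospitals: Iterable[Hospital]) -> dict[str, Hospital]:
    return {h.hospital_id: h for h in hospitals}
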