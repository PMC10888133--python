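"""GeoJSON / CSV readers and writers for every pipeline artifact.

Geometries are exchanged as RFC 7946 GeoJSON geometry objects via
``shapely.geometry.shape``/``mapping``; the coordinates are planar meters,
documented as non-geographic in each FeatureCollection's ``crs_note``.
CSV tables go through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .types import County, Hospital, RoadEdge, RoadNetwork

CRS_NOTE = "planar meters, non-geographic"


def _feature(geom: BaseGeometry, props: dict[str, Any]) -> dict[str, Any]:
    return {"type": "Feature", "geometry": mapping(geom), "properties": props}


def _collection(features: list[dict[str, Any]]) -> dict[str, Any]:
    return {"type": "FeatureCollection", "crs_note": CRS_NOTE, "features": features}


def write_geojson(path: str | Path, features: list[dict[str, Any]]) -> None:
    Path(path).write_text(json.dumps(_collection(features), sort_keys=True))


def read_geojson(path: str | Path) -> list[dict[str, Any]]:
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    return data["features"]


# ---------------------------------------------------------------- counties

def write_counties(path: str | Path, counties: Iterable[County]) -> None:
    feats = [
        _feature(
            c.polygon,
            {
                "county_id": c.county_id,
                "total_pop": c.total_pop,
                "child_pop": c.child_pop,
                "households": c.households,
                "no_vehicle_households": c.no_vehicle_households,
            },
        )
        for c in counties
    ]
    write_geojson(path, feats)


def read_counties(path: str | Path) -> list[County]:
    out = []
    for f in read_geojson(path):
        p = f["properties"]
        out.append(
            County(
                county_id=str(p["county_id"]),
                polygon=shape(f["geometry"]),
                total_pop=p["total_pop"],
                child_pop=p["child_pop"],
                households=p["households"],
                no_vehicle_households=p["no_vehicle_households"],
            )
        )
    return out


# ---------------------------------------------------------------- hospitals

def write_hospitals(path: str | Path, hospitals: Iterable[Hospital]) -> None:
    feats = [
        _feature(
            h.point,
            {"hospital_id": h.hospital_id, "beds": h.beds, "name": h.name},
        )
        for h in hospitals
    ]
    write_geojson(path, feats)


def read_hospitals(path: str | Path) -> list[Hospital]:
    out = []
    for f in read_geojson(path):
        p = f["properties"]
        out.append(
            Hospital(
                hospital_id=str(p["hospital_id"]),
                point=shape(f["geometry"]),
                beds=int(p["beds"]),
                name=str(p.get("name", "")),
            )
        )
    return out


# ---------------------------------------------------------------- network

def write_network(nodes_path: str | Path, edges_path: str | Path, net: RoadNetwork) -> None:
    nodes = pd.DataFrame(
        [{"node_id": nid, "x": x, "y": y} for nid, (x, y) in net.nodes.items()]
    )
    edges = pd.DataFrame(
        [
            {
                "edge_id": e.edge_id,
                "from_node": e.from_node,
                "to_node": e.to_node,
                "length_m": e.length_m,
                "speed_kmh": e.speed_kmh,
            }
            for e in net.edges
        ]
    )
    nodes.to_csv(nodes_path, index=False)
    edges.to_csv(edges_path, index=False)


def read_network(nodes_path: str | Path, edges_path: str | Path) -> RoadNetwork:
    nodes_df = pd.read_csv(nodes_path, dtype={"node_id": str})
    edges_df = pd.read_csv(edges_path, dtype={"edge_id": str, "from_node": str, "to_node": str})
    nodes = {r.node_id: (float(r.x), float(r.y)) for r in nodes_df.itertuples()}
    edges = [
        RoadEdge(
            edge_id=r.edge_id,
            from_node=r.from_node,
            to_node=r.to_node,
            length_m=float(r.length_m),
            speed_kmh=float(r.speed_kmh),
        )
        for r in edges_df.itertuples()
    ]
    return RoadNetwork(nodes=nodes, edges=edges)


# ---------------------------------------------------------------- service areas / faces

def write_service_areas(path: str | Path, service_areas) -> None:
    feats = [
        _feature(
            sa.polygon,
            {"hospital_id": sa.hospital_id, "threshold_min": sa.threshold_min},
        )
        for sa in service_areas
    ]
    write_geojson(path, feats)


def read_service_areas(path: str | Path):
    from .network_isochrone import ServiceArea

    out = []
    for f in read_geojson(path):
        p = f["properties"]
        out.append(
            ServiceArea(
                hospital_id=str(p["hospital_id"]),
                threshold_min=float(p["threshold_min"]),
                polygon=shape(f["geometry"]),
                reached_edge_fractions={},
            )
        )
    return out


def write_faces(path: str | Path, arrangement) -> None:
    feats = [
        _feature(
            face.polygon,
            {
                "face_id": face.face_id,
                "hospital_ids": ",".join(sorted(face.hospital_ids)),
                "overlap_count": face.overlap_count,
            },
        )
        for face in arrangement.faces
    ]
    write_geojson(path, feats)


def read_faces(path: str | Path):
    from .overlay import Arrangement, PlanarFace

    faces = []
    for f in read_geojson(path):
        p = f["properties"]
        faces.append(
            PlanarFace(
                face_id=str(p["face_id"]),
                polygon=shape(f["geometry"]),
                hospital_ids=frozenset(p["hospital_ids"].split(",")),
            )
        )
    max_overlap = max((fc.overlap_count for fc in faces), default=0)
    return Arrangement(faces=faces, source_count=max_overlap)


def write_json(path: str | Path, obj: Any) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())
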