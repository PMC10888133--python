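"""Synthetic study regions with metro/rural structure.

Generates a rectangular grid of counties (a few dense metro clusters with
hospitals, a low-density rural periphery), county demographics (total and
child population, households, carless households), and a lattice road
network with a faster highway overlay connecting the metro centers. The
construction mirrors the statistical shape of a large state whose
children's hospitals sit almost entirely in metropolitan counties: about a
quarter of each county's population are children, and roughly five percent
of households lack a vehicle, with the carless share higher in rural
counties.

Counties are rectangular cells so that area intersections used in tests
have closed-form expected values; population is treated as uniformly
distributed within each county, which is exactly the assumption of
areal-weighted interpolation downstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely.geometry import Point, box

from . import io as pio
from .types import County, Hospital, Region, RoadEdge, RoadNetwork, ValidationError

MEAN_HOUSEHOLD_SIZE = 2.8  # persons per household; fixed constant of the generator


@dataclass(frozen=True)
class RegionSpec:
    """Parameters of the synthetic region generator.

    Distances are kilometers, speeds km/h, populations persons. Counties
    are cells of an ``n_counties_x`` x ``n_counties_y`` grid with side
    ``county_size_km``; ``n_metros`` cells are designated metro counties
    and receive the hospitals.
    """

    seed: int = 0
    n_counties_x: int = 8
    n_counties_y: int = 8
    county_size_km: float = 20.0
    n_metros: int = 3
    metro_pop_mean: float = 800_000.0
    rural_pop_mean: float = 20_000.0
    child_share_mean: float = 0.25
    carless_share_metro: float = 0.04
    carless_share_rural: float = 0.08
    road_grid_spacing_km: float = 1.0
    speed_highway_kmh: float = 90.0
    speed_local_kmh: float = 40.0
    n_hospitals: int = 6
    beds_mean: float = 150.0
    snap_tolerance_m: float = 1.0

    def validate(self) -> None:
        counts = {
            "n_counties_x": self.n_counties_x,
            "n_counties_y": self.n_counties_y,
            "n_metros": self.n_metros,
            "n_hospitals": self.n_hospitals,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValidationError(f"{name} must be >= 1 (got {v})")
        shares = {
            "child_share_mean": self.child_share_mean,
            "carless_share_metro": self.carless_share_metro,
            "carless_share_rural": self.carless_share_rural,
        }
        for name, v in shares.items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1] (got {v})")
        positives = {
            "county_size_km": self.county_size_km,
            "metro_pop_mean": self.metro_pop_mean,
            "rural_pop_mean": self.rural_pop_mean,
            "road_grid_spacing_km": self.road_grid_spacing_km,
            "speed_highway_kmh": self.speed_highway_kmh,
            "speed_local_kmh": self.speed_local_kmh,
            "beds_mean": self.beds_mean,
            "snap_tolerance_m": self.snap_tolerance_m,
        }
        for name, v in positives.items():
            if v <= 0:
                raise ValidationError(f"{name} must be > 0 (got {v})")
        if self.n_metros > self.n_counties_x * self.n_counties_y:
            raise ValidationError("n_metros exceeds number of counties")
        if self.n_hospitals > self.n_metros * 4:
            raise ValidationError(
                f"n_hospitals must be <= 4 x n_metros "
                f"(got {self.n_hospitals} > {4 * self.n_metros})"
            )


def _lattice_network(spec: RegionSpec) -> tuple[RoadNetwork, dict[str, tuple[int, int]]]:
    """Square lattice of local roads covering the full region rectangle."""
    km = 1000.0
    w = spec.n_counties_x * spec.county_size_km
    h = spec.n_counties_y * spec.county_size_km
    nx_nodes = int(round(w / spec.road_grid_spacing_km)) + 1
    ny_nodes = int(round(h / spec.road_grid_spacing_km)) + 1
    spacing_m = spec.road_grid_spacing_km * km

    nodes: dict[str, tuple[float, float]] = {}
    grid_index: dict[str, tuple[int, int]] = {}
    for j in range(ny_nodes):
        for i in range(nx_nodes):
            nid = f"n{i}_{j}"
            nodes[nid] = (i * spacing_m, j * spacing_m)
            grid_index[nid] = (i, j)

    edges: list[RoadEdge] = []
    k = 0
    for j in range(ny_nodes):
        for i in range(nx_nodes):
            if i + 1 < nx_nodes:
                edges.append(
                    RoadEdge(f"e{k}", f"n{i}_{j}", f"n{i + 1}_{j}", spacing_m, spec.speed_local_kmh)
                )
                k += 1
            if j + 1 < ny_nodes:
                edges.append(
                    RoadEdge(f"e{k}", f"n{i}_{j}", f"n{i}_{j + 1}", spacing_m, spec.speed_local_kmh)
                )
                k += 1
    return RoadNetwork(nodes=nodes, edges=edges), grid_index


def _upgrade_highways(net: RoadNetwork, metro_nodes: list[str], speed_kmh: float) -> RoadNetwork:
    """Upgrade the L-shaped lattice path between consecutive metro centers to highway speed."""
    pos = net.nodes
    upgraded: set[frozenset[str]] = set()
    by_coord = {(round(x), round(y)): nid for nid, (x, y) in pos.items()}

    def node_at(x: float, y: float) -> str:
        return by_coord[(round(x), round(y))]

    spacing = None
    for e in net.edges:
        spacing = e.length_m
        break

    def walk(a: str, b: str) -> None:
        ax, ay = pos[a]
        bx, by = pos[b]
        # horizontal leg then vertical leg
        x = ax
        step = spacing if bx >= ax else -spacing
        while abs(x - bx) > 1e-6:
            upgraded.add(frozenset({node_at(x, ay), node_at(x + step, ay)}))
            x += step
        y = ay
        step = spacing if by >= ay else -spacing
        while abs(y - by) > 1e-6:
            upgraded.add(frozenset({node_at(bx, y), node_at(bx, y + step)}))
            y += step

    for a, b in zip(metro_nodes, metro_nodes[1:]):
        walk(a, b)

    new_edges = []
    for e in net.edges:
        if frozenset({e.from_node, e.to_node}) in upgraded:
            e = dataclasses.replace(e, speed_kmh=speed_kmh)
        new_edges.append(e)
    return RoadNetwork(nodes=net.nodes, edges=new_edges)


def generate_region(spec: RegionSpec) -> Region:
    """Generate a deterministic synthetic region for a fixed spec (incl. seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    km = 1000.0
    size_m = spec.county_size_km * km

    n_cells = spec.n_counties_x * spec.n_counties_y
    metro_cells = sorted(rng.choice(n_cells, size=spec.n_metros, replace=False).tolist())
    metro_set = set(metro_cells)

    counties: list[County] = []
    for cell in range(n_cells):
        cx, cy = cell % spec.n_counties_x, cell // spec.n_counties_x
        poly = box(cx * size_m, cy * size_m, (cx + 1) * size_m, (cy + 1) * size_m)
        is_metro = cell in metro_set
        mean = spec.metro_pop_mean if is_metro else spec.rural_pop_mean
        # lognormal-ish spread around the stratum mean, bounded away from 0
        total = max(100.0, rng.normal(mean, 0.15 * mean))
        child_share = float(np.clip(rng.normal(spec.child_share_mean, 0.02), 0.0, 1.0))
        child = round(total * child_share)
        households = round(total / MEAN_HOUSEHOLD_SIZE)
        carless_share = spec.carless_share_metro if is_metro else spec.carless_share_rural
        carless = round(households * carless_share)
        counties.append(
            County(
                county_id=f"c{cx}_{cy}",
                polygon=poly,
                total_pop=round(total),
                child_pop=child,
                households=households,
                no_vehicle_households=carless,
            )
        )

    net, grid_index = _lattice_network(spec)

    # metro center = lattice node nearest each metro county's centroid
    metro_center_nodes: list[str] = []
    for cell in metro_cells:
        cx, cy = cell % spec.n_counties_x, cell // spec.n_counties_x
        centroid = Point((cx + 0.5) * size_m, (cy + 0.5) * size_m)
        nid, _ = net.nearest_node(centroid)
        metro_center_nodes.append(nid)

    net = _upgrade_highways(net, metro_center_nodes, spec.speed_highway_kmh)

    # hospitals: at lattice nodes inside metro counties, near the metro center
    metro_polys = [counties[cell].polygon for cell in metro_cells]
    hospitals: list[Hospital] = []
    for k in range(spec.n_hospitals):
        metro_idx = k % spec.n_metros
        center = metro_center_nodes[metro_idx]
        ci, cj = grid_index[center]
        poly = metro_polys[metro_idx]
        # jitter around the center, rejected until inside the metro county
        for _ in range(100):
            di, dj = rng.integers(-2, 3, size=2)
            nid = f"n{ci + di}_{cj + dj}"
            if nid in net.nodes and poly.contains(Point(*net.nodes[nid]).buffer(1.0)):
                break
        else:
            nid = center
        beds = max(1, int(round(rng.normal(spec.beds_mean, 0.3 * spec.beds_mean))))
        hospitals.append(
            Hospital(
                hospital_id=f"h{k}",
                point=Point(*net.nodes[nid]),
                beds=beds,
                name=f"Children's Hospital {k}",
            )
        )

    return Region(counties=counties, hospitals=hospitals, network=net)


def write_region(region: Region, out_dir: str | Path, spec: RegionSpec | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pio.write_counties(out / "counties.geojson", region.counties)
    pio.write_hospitals(out / "hospitals.geojson", region.hospitals)
    pio.write_network(out / "nodes.csv", out / "edges.csv", region.network)
    manifest = {"crs_note": region.crs_note}
    if spec is not None:
        manifest["spec"] = dataclasses.asdict(spec)
        manifest["seed"] = spec.seed
    (out / "region_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_region(in_dir: str | Path) -> Region:
    d = Path(in_dir)
    return Region(
        counties=pio.read_counties(d / "counties.geojson"),
        hospitals=pio.read_hospitals(d / "hospitals.geojson"),
        network=pio.read_network(d / "nodes.csv", d / "edges.csv"),
    )
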