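"""Shared fixtures: tiny hand-checkable networks and a small synthetic region."""

from __future__ import annotations

import pytest
from shapely.geometry import box

import pedaccess as pa
from pedaccess.network_isochrone import ServiceArea


@pytest.fixture(scope="session")
def path_network() -> pa.RoadNetwork:
    """A-B-C path; both edges take 10 minutes (10 km at 60 km/h)."""
    return pa.RoadNetwork(
        nodes={"A": (0.0, 0.0), "B": (10_000.0, 0.0), "C": (20_000.0, 0.0)},
        edges=[
            pa.RoadEdge("AB", "A", "B", 10_000.0, 60.0),
            pa.RoadEdge("BC", "B", "C", 10_000.0, 60.0),
        ],
    )


@pytest.fixture(scope="session")
def small_spec() -> pa.RegionSpec:
    """A 4x4-county region small enough for repeated end-to-end runs."""
    return pa.RegionSpec(
        seed=3,
        n_counties_x=4,
        n_counties_y=4,
        county_size_km=10.0,
        n_metros=2,
        metro_pop_mean=120_000.0,
        rural_pop_mean=8_000.0,
        road_grid_spacing_km=1.0,
        speed_highway_kmh=90.0,
        speed_local_kmh=40.0,
        n_hospitals=3,
        beds_mean=120.0,
    )


@pytest.fixture(scope="session")
def small_region(small_spec) -> pa.Region:
    return pa.generate_region(small_spec)


@pytest.fixture(scope="session")
def small_service_areas(small_region) -> list[ServiceArea]:
    # 12-minute budget keeps areas well inside the 40 km region
    return pa.service_areas_for_all(small_region, threshold_min=12.0, buffer_m=500.0)


def make_service_area(hospital_id: str, polygon) -> ServiceArea:
    return ServiceArea(hospital_id=hospital_id, threshold_min=60.0, polygon=polygon)


@pytest.fixture()
def two_squares() -> list[ServiceArea]:
    """Two unit squares overlapping in a 0.5 x 1 strip."""
    return [
        make_service_area("h0", box(0.0, 0.0, 1.0, 1.0)),
        make_service_area("h1", box(0.5, 0.0, 1.5, 1.0)),
    ]


def grid_counties(
    nx: int,
    ny: int,
    size: float,
    child_pops: list[float] | None = None,
    total_pops: list[float] | None = None,
) -> list[pa.County]:
    """Rectangular county grid with prescribed (or default) counts."""
    counties = []
    for cell in range(nx * ny):
        i, j = cell % nx, cell // nx
        child = child_pops[cell] if child_pops else 250.0
        total = total_pops[cell] if total_pops else max(child * 4, child)
        counties.append(
            pa.County(
                county_id=f"c{i}_{j}",
                polygon=box(i * size, j * size, (i + 1) * size, (j + 1) * size),
                total_pop=total,
                child_pop=child,
                households=round(total / 2.8),
                no_vehicle_households=round(total / 2.8 * 0.05),
            )
        )
    return counties
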