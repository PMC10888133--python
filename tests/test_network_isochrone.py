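"""Service-area computation: travel times, reached fractions, polygons."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from shapely.geometry import LineString, Point
from shapely.ops import unary_union

import pedaccess as pa
from pedaccess.network_isochrone import node_travel_times
from pedaccess.types import ValidationError


@pytest.mark.parametrize(
    "length_m, speed_kmh, expected_min",
    [(1000.0, 60.0, 1.0), (30_000.0, 30.0, 60.0), (500.0, 100.0, 0.3)],
)
def test_edge_travel_time_unit_conversion(length_m, speed_kmh, expected_min):
    assert pa.edge_travel_time(length_m, speed_kmh) == pytest.approx(expected_min)


@pytest.mark.parametrize("length_m, speed_kmh", [(0, 60), (-5, 60), (100, 0), (100, -1)])
def test_edge_travel_time_rejects_nonpositive(length_m, speed_kmh):
    with pytest.raises(ValidationError):
        pa.edge_travel_time(length_m, speed_kmh)


def test_partial_reach_on_three_node_path(path_network):
    # hand Dijkstra: t(A)=0, t(B)=10, t(C)=20; budget 15 covers AB fully, half of BC
    fractions = pa.reachable_subnetwork(path_network, "A", 15.0)
    assert fractions == pytest.approx({"AB": 1.0, "BC": 0.5})


def test_zero_budget_reaches_nothing(path_network):
    assert pa.reachable_subnetwork(path_network, "A", 0.0) == pytest.approx(
        {"AB": 0.0, "BC": 0.0}
    )


def test_saturated_budget_reaches_everything(path_network):
    fractions = pa.reachable_subnetwork(path_network, "A", 1000.0)
    assert fractions == pytest.approx({"AB": 1.0, "BC": 1.0})


def test_missing_origin_raises(path_network):
    with pytest.raises(KeyError):
        pa.reachable_subnetwork(path_network, "Z", 10.0)


def _random_network(rng: np.random.Generator, n_nodes: int) -> pa.RoadNetwork:
    nodes = {f"n{i}": tuple(rng.uniform(0, 50_000, size=2)) for i in range(n_nodes)}
    ids = list(nodes)
    edges = []
    k = 0
    # random connected-ish graph: a random spanning chain plus extra chords
    order = rng.permutation(n_nodes)
    pairs = list(zip(order, order[1:]))
    n_extra = rng.integers(0, 2 * n_nodes)
    for _ in range(n_extra):
        i, j = rng.integers(0, n_nodes, size=2)
        if i != j:
            pairs.append((i, j))
    seen = set()
    for i, j in pairs:
        key = frozenset((int(i), int(j)))
        if key in seen:
            continue
        seen.add(key)
        (xa, ya), (xb, yb) = nodes[ids[int(i)]], nodes[ids[int(j)]]
        euclid = ((xa - xb) ** 2 + (ya - yb) ** 2) ** 0.5
        # roads are at least as long as the straight line between endpoints
        edges.append(
            pa.RoadEdge(
                f"e{k}", ids[int(i)], ids[int(j)],
                max(1.0, euclid * float(rng.uniform(1.0, 1.8))),
                float(rng.uniform(20, 110)),
            )
        )
        k += 1
    return pa.RoadNetwork(nodes=nodes, edges=edges)


def _bellman_ford(network: pa.RoadNetwork, origin: str) -> dict[str, float]:
    """Brute-force relaxation oracle, independent of the graph library."""
    dist = {nid: float("inf") for nid in network.nodes}
    dist[origin] = 0.0
    for _ in range(len(network.nodes)):
        changed = False
        for e in network.edges:
            w = e.travel_time_min
            for a, b in ((e.from_node, e.to_node), (e.to_node, e.from_node)):
                if dist[a] + w < dist[b]:
                    dist[b] = dist[a] + w
                    changed = True
        if not changed:
            break
    return dist


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_travel_times_match_bellman_ford_oracle(seed):
    rng = np.random.default_rng(seed)
    net = _random_network(rng, n_nodes=int(rng.integers(5, 51)))
    origin = list(net.nodes)[0]
    expected = _bellman_ford(net, origin)
    got = node_travel_times(net, origin)
    for nid, d in expected.items():
        if d == float("inf"):
            assert nid not in got
        else:
            assert got[nid] == pytest.approx(d, abs=1e-9)


def test_fractions_nondecreasing_in_threshold():
    rng = np.random.default_rng(11)
    net = _random_network(rng, 30)
    origin = list(net.nodes)[0]
    prev = None
    for t in [0.0, 2.0, 5.0, 10.0, 20.0, 50.0]:
        f = pa.reachable_subnetwork(net, origin, t)
        assert all(0.0 <= v <= 1.0 for v in f.values())
        if prev is not None:
            assert all(f[eid] >= prev[eid] - 1e-12 for eid in f)
        prev = f


def test_network_time_bounded_below_by_euclidean():
    rng = np.random.default_rng(5)
    net = _random_network(rng, 40)
    origin = list(net.nodes)[0]
    ox, oy = net.nodes[origin]
    max_speed = max(e.speed_kmh for e in net.edges)
    for nid, t in node_travel_times(net, origin).items():
        x, y = net.nodes[nid]
        euclid_km = ((x - ox) ** 2 + (y - oy) ** 2) ** 0.5 / 1000.0
        assert t >= euclid_km / max_speed * 60.0 - 1e-9


def test_zero_threshold_polygon_is_buffer_disc(path_network):
    h = pa.Hospital("h0", Point(0.0, 0.0), beds=10)
    sa = pa.build_service_area(path_network, h, threshold_min=0.0, buffer_m=500.0)
    assert sa.polygon.area == pytest.approx(np.pi * 500.0**2, rel=1e-2)


def test_partial_path_polygon_matches_buffered_union_oracle(path_network):
    # budget 15 reaches AB entirely and the half of BC nearest B
    h = pa.Hospital("h0", Point(0.0, 0.0), beds=10)
    sa = pa.build_service_area(path_network, h, threshold_min=15.0, buffer_m=100.0)
    expected = unary_union(
        [
            LineString([(0, 0), (10_000, 0)]).buffer(100.0),
            LineString([(10_000, 0), (15_000, 0)]).buffer(100.0),
            Point(0, 0).buffer(100.0),
        ]
    )
    assert sa.polygon.area == pytest.approx(expected.area, rel=1e-2)
    # oriented sanity: covers 15 km of street plus end caps
    assert sa.polygon.area > 15_000 * 200


def test_polygon_monotone_in_threshold(small_region):
    h = small_region.hospitals[0]
    prev = None
    for t in [0.0, 4.0, 8.0, 12.0]:
        sa = pa.build_service_area(small_region.network, h, t, 500.0)
        if prev is not None:
            uncovered = prev.difference(sa.polygon).area
            assert uncovered < 1e6 * 1e-6  # < 1e-6 km^2
        prev = sa.polygon


def test_same_origin_gives_identical_polygons(path_network):
    h1 = pa.Hospital("h1", Point(0.0, 0.0), beds=10)
    h2 = pa.Hospital("h2", Point(0.0, 0.0), beds=99)
    sa1 = pa.build_service_area(path_network, h1, 15.0, 100.0)
    sa2 = pa.build_service_area(path_network, h2, 15.0, 100.0)
    assert sa1.polygon.equals(sa2.polygon)


def test_snap_tolerance_enforced(path_network):
    far = pa.Hospital("hx", Point(5_000.0, 9_000.0), beds=5)
    with pytest.raises(ValidationError, match="hx"):
        pa.build_service_area(path_network, far, 15.0, 100.0, snap_tolerance_m=1.0)


def test_one_service_area_per_hospital_order_independent(small_region):
    areas = pa.service_areas_for_all(small_region, 10.0, 500.0)
    assert len(areas) == len(small_region.hospitals)
    shuffled = pa.Region(
        counties=small_region.counties,
        hospitals=list(reversed(small_region.hospitals)),
        network=small_region.network,
    )
    areas2 = pa.service_areas_for_all(shuffled, 10.0, 500.0)
    for a, b in zip(areas, areas2):
        assert a.hospital_id == b.hospital_id
        assert a.polygon.equals(b.polygon)


def test_disconnected_component_gets_zero_fraction():
    net = pa.RoadNetwork(
        nodes={"A": (0, 0), "B": (1000, 0), "C": (50_000, 0), "D": (51_000, 0)},
        edges=[
            pa.RoadEdge("AB", "A", "B", 1000, 60),
            pa.RoadEdge("CD", "C", "D", 1000, 60),
        ],
    )
    fractions = pa.reachable_subnetwork(net, "A", 100.0)
    assert fractions["AB"] == 1.0
    assert fractions["CD"] == 0.0
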