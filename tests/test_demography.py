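"""Areal-weighted interpolation: hand-checked values and conservation laws."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box
from shapely.ops import unary_union

import pedaccess as pa
from pedaccess.types import ValidationError
from conftest import grid_counties


def test_full_containment_returns_full_count():
    counties = grid_counties(2, 1, 10.0, child_pops=[1000.0, 700.0])
    target = box(-1, -1, 10, 11)  # contains the left county only
    r = pa.areal_interpolate(counties, target, "child_pop")
    assert r.value == pytest.approx(1000.0, rel=1e-12)
    assert set(r.contributions) == {"c0_0"}


def test_half_coverage_is_proportional():
    counties = grid_counties(1, 1, 10.0, child_pops=[1000.0])
    target = box(0, 0, 5, 10)
    r = pa.areal_interpolate(counties, target, "child_pop")
    assert r.value == pytest.approx(500.0, rel=1e-12)
    _, weight, contributed = r.contributions["c0_0"]
    assert weight == pytest.approx(0.5)
    assert contributed == pytest.approx(500.0)


def test_hand_evaluated_two_county_target():
    # left county entirely, plus the left half of the right county: 300 + 350
    counties = grid_counties(2, 1, 10.0, child_pops=[300.0, 700.0])
    target = box(0, 0, 15, 10)
    r = pa.areal_interpolate(counties, target, "child_pop")
    assert r.value == pytest.approx(650.0, rel=1e-12)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    frac=st.floats(min_value=0.0, max_value=1.0),
    child_pop=st.floats(min_value=0.0, max_value=1e7),
)
def test_interpolated_value_proportional_to_covered_fraction(frac, child_pop):
    counties = grid_counties(1, 1, 10.0, child_pops=[child_pop],
                             total_pops=[max(child_pop, 1.0)])
    target = box(0, 0, 10 * frac, 10) if frac > 0 else box(20, 20, 21, 21)
    value = pa.areal_interpolate(counties, target, "child_pop").value
    assert value == pytest.approx(frac * child_pop, rel=1e-9, abs=1e-6)
    assert 0.0 <= value <= child_pop + 1e-6


def test_unknown_attribute_rejected():
    counties = grid_counties(1, 1, 10.0)
    with pytest.raises(ValidationError, match="attribute"):
        pa.areal_interpolate(counties, box(0, 0, 1, 1), "median_income")


def test_mass_conservation_over_partition():
    rng = np.random.default_rng(2)
    counties = grid_counties(4, 3, 7.0, child_pops=list(rng.uniform(10, 5000, 12)))
    total = sum(c.child_pop for c in counties)
    # partition of the full region into three vertical slabs
    slabs = [box(0, 0, 9, 21), box(9, 0, 17.5, 21), box(17.5, 0, 28, 21)]
    interpolated = sum(
        pa.areal_interpolate(counties, s, "child_pop").value for s in slabs
    )
    assert interpolated == pytest.approx(total, rel=1e-9)


def test_additivity_over_disjoint_targets():
    counties = grid_counties(3, 3, 5.0, child_pops=list(range(100, 1000, 100)))
    a, b = box(1, 1, 6, 6), box(8, 2, 14, 13)
    va = pa.areal_interpolate(counties, a, "child_pop").value
    vb = pa.areal_interpolate(counties, b, "child_pop").value
    vu = pa.areal_interpolate(counties, unary_union([a, b]), "child_pop").value
    assert vu == pytest.approx(va + vb, rel=1e-9)


def test_monotone_and_nonnegative_under_inclusion():
    counties = grid_counties(3, 3, 5.0)
    inner, outer = box(2, 2, 8, 8), box(1, 1, 12, 12)
    vi = pa.areal_interpolate(counties, inner, "child_pop").value
    vo = pa.areal_interpolate(counties, outer, "child_pop").value
    assert 0.0 <= vi <= vo


def test_classify_counties_inside_partial_outside():
    counties = grid_counties(2, 2, 10.0)
    # full first county plus the left half of the second; top row untouched
    union = box(0, 0, 15, 10)
    classes = pa.classify_counties(counties, union)
    assert classes["c0_0"] == "inside"
    assert classes["c1_0"] == "partial"
    assert classes["c0_1"] == "outside"
    assert classes["c1_1"] == "outside"
    covered = sum(1 for v in classes.values() if v in ("inside", "partial"))
    assert covered == 2


def test_population_outside_complement():
    counties = grid_counties(2, 2, 10.0, child_pops=[100.0, 200.0, 300.0, 400.0])
    everything = box(-1, -1, 21, 21)
    nothing = box(100, 100, 101, 101)
    assert pa.population_outside(counties, everything, "child_pop") == pytest.approx(0.0, abs=1e-9)
    assert pa.population_outside(counties, nothing, "child_pop") == pytest.approx(1000.0)


def test_statewide_outside_count_from_published_totals():
    # one county holding the statewide child population; the service-area
    # union covers exactly the inside fraction reported for the state
    child_total, child_inside = 7_470_055.0, 1_852_573.0
    county = pa.County(
        county_id="state",
        polygon=box(0, 0, 1, 1),
        total_pop=child_total,
        child_pop=child_total,
        households=1,
        no_vehicle_households=0,
    )
    union = box(0, 0, child_inside / child_total, 1)
    outside = pa.population_outside([county], union, "child_pop")
    assert outside == pytest.approx(5_617_482.0, abs=1.0)
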