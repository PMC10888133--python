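"""Areal-weighted interpolation of county counts into arbitrary polygons.

The child (or household) population inside a target polygon is estimated
as the sum over counties of the county's count times the fraction of the
county's area intersecting the target:

    value(target) = sum_c  attr_c * area(county_c intersect target) / area(county_c)

This assumes population is uniformly distributed within each county. The
estimator is mass-preserving (interpolating onto a partition of the whole
region reproduces the state totals), additive over disjoint targets, and
monotone under target inclusion.

Also provides the inside/partial/outside classification of counties
against the union of all service areas, and the complement count of
population left outside the union.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from shapely.geometry.base import BaseGeometry

from .types import County, ValidationError

ATTRIBUTES = ("total_pop", "child_pop", "households", "no_vehicle_households")

_REL_AREA_TOL = 1e-9


@dataclass
class InterpolationResult:
    target_id: str
    attribute: str
    value: float
    #: county_id -> (intersect_area_km2, weight, contributed value)
    contributions: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def areal_interpolate(
    counties: list[County],
    target: BaseGeometry,
    attribute: str,
    target_id: str = "target",
) -> InterpolationResult:
    """Interpolate a county count into *target* by intersection-area weights."""
    if attribute not in ATTRIBUTES:
        raise ValidationError(
            f"unknown attribute {attribute!r}; expected one of {ATTRIBUTES}"
        )
    total = 0.0
    contributions: dict[str, tuple[float, float, float]] = {}
    for c in counties:
        inter = c.polygon.intersection(target)
        if inter.is_empty:
            continue
        a = inter.area
        if a <= 0.0:
            continue
        weight = a / c.polygon.area
        contributed = getattr(c, attribute) * weight
        total += contributed
        contributions[c.county_id] = (a / 1e6, weight, contributed)
    return InterpolationResult(
        target_id=target_id, attribute=attribute, value=total, contributions=contributions
    )


def classify_counties(
    counties: list[County], union_polygon: BaseGeometry
) -> dict[str, str]:
    """Classify each county as inside / partial / outside the service-area union.

    A county counts as covered ("completely or partially within") when it
    is inside or partial; the relative-area tolerance absorbs boundary
    float noise.
    """
    out: dict[str, str] = {}
    for c in counties:
        area = c.polygon.area
        inside_frac = c.polygon.intersection(union_polygon).area / area
        if 1.0 - inside_frac < _REL_AREA_TOL:
            out[c.county_id] = "inside"
        elif inside_frac < _REL_AREA_TOL:
            out[c.county_id] = "outside"
        else:
            out[c.county_id] = "partial"
    return out


def population_outside(
    counties: list[County], union_polygon: BaseGeometry, attribute: str
) -> float:
    """Count of *attribute* living outside the service-area union."""
    total = sum(getattr(c, attribute) for c in counties)
    inside = areal_interpolate(counties, union_polygon, attribute).value
    return max(0.0, total - inside)
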