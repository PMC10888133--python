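"""Coverage statistics: who lives inside the service-area union.

Summarizes, for each demographic attribute, the state-wide total, the
areal-interpolated count inside the union of all service areas, the
complement outside, and the inside share as a percentage; plus the number
of counties completely or partially covered. Population and county shares
are printed to 1 decimal, household rows to whole percent, all
round-half-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from shapely.ops import unary_union

from .demography import ATTRIBUTES, areal_interpolate, classify_counties
from .network_isochrone import ServiceArea
from .types import County, ValidationError

#: printed decimals per attribute share (population/county rows 1, household rows 0)
SHARE_DECIMALS = {
    "total_pop": 1,
    "child_pop": 1,
    "households": 0,
    "no_vehicle_households": 0,
}


def percentage(part: float, whole: float, decimals: int = 1) -> float:
    """part/whole as a percentage, rounded half-up to *decimals*."""
    if whole <= 0:
        raise ValidationError(f"whole must be > 0 (got {whole})")
    if part < 0:
        raise ValidationError(f"part must be >= 0 (got {part})")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(part) / Decimal(whole) * 100).quantize(q, rounding=ROUND_HALF_UP)
    )


def carless_inside_share(carless_inside: float, carless_total: float) -> float:
    """Share of carless households living inside the union, whole percent."""
    return percentage(carless_inside, carless_total, 0)


@dataclass
class AccessReport:
    totals: dict[str, float] = field(default_factory=dict)
    inside: dict[str, float] = field(default_factory=dict)
    outside: dict[str, float] = field(default_factory=dict)
    shares: dict[str, float] = field(default_factory=dict)
    counties_covered: int = 0
    counties_total: int = 0
    county_share_pct: float = 0.0
    county_classes: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "totals": self.totals,
            "inside": self.inside,
            "outside": self.outside,
            "shares_pct": self.shares,
            "counties_covered": self.counties_covered,
            "counties_total": self.counties_total,
            "county_share_pct": self.county_share_pct,
            "county_classes": self.county_classes,
        }


def build_report(
    counties: list[County],
    service_areas: list[ServiceArea],
    county_assignment: str = "areal",
) -> AccessReport:
    """Coverage report against the union of all service areas.

    ``county_assignment`` selects how inside counts are attributed:
    "areal" interpolates by intersection area (default); "whole" assigns
    each county entirely inside or outside by whether it intersects the
    union at all.
    """
    if not service_areas:
        raise ValidationError("build_report requires at least one service area")
    if county_assignment not in ("areal", "whole"):
        raise ValidationError(f"unknown county_assignment {county_assignment!r}")
    union = unary_union([sa.polygon for sa in service_areas])
    classes = classify_counties(counties, union)

    rep = AccessReport(counties_total=len(counties), county_classes=classes)
    rep.counties_covered = sum(1 for v in classes.values() if v in ("inside", "partial"))
    rep.county_share_pct = percentage(rep.counties_covered, len(counties), 1)

    for attr in ATTRIBUTES:
        total = float(sum(getattr(c, attr) for c in counties))
        if county_assignment == "areal":
            inside = areal_interpolate(counties, union, attr).value
        else:
            inside = float(
                sum(
                    getattr(c, attr)
                    for c in counties
                    if classes[c.county_id] in ("inside", "partial")
                )
            )
        inside = min(inside, total)  # guard against float overshoot at full coverage
        rep.totals[attr] = total
        rep.inside[attr] = inside
        rep.outside[attr] = total - inside
        rep.shares[attr] = percentage(inside, total, SHARE_DECIMALS[attr]) if total > 0 else 0.0
    return rep


def report_markdown(rep: AccessReport) -> str:
    """Human-readable tables mirroring the coverage/vehicle summary layout."""
    lines = [
        "# Access report",
        "",
        "## Population coverage",
        "",
        "| Characteristic | Value |",
        "|---|---|",
        f"| Total population | {rep.totals['total_pop']:,.0f} |",
        f"| Population of children | {rep.totals['child_pop']:,.0f} |",
        f"| Children within the service areas | {rep.inside['child_pop']:,.0f} "
        f"({rep.shares['child_pop']}%) |",
        f"| Counties total | {rep.counties_total} |",
        f"| Counties completely or partially within | {rep.counties_covered} "
        f"({rep.county_share_pct}%) |",
        "",
        "## Vehicle availability",
        "",
        "| Characteristic | Value |",
        "|---|---|",
        f"| Households | {rep.totals['households']:,.0f} |",
        f"| Households within the service areas | {rep.inside['households']:,.0f} "
        f"({rep.shares['households']:.0f}%) |",
        f"| Households outside the service areas | {rep.outside['households']:,.0f} |",
        f"| Households without a vehicle | {rep.totals['no_vehicle_households']:,.0f} |",
        f"| Carless households within the service areas | "
        f"{rep.inside['no_vehicle_households']:,.0f} "
        f"({rep.shares['no_vehicle_households']:.0f}%) |",
        f"| Carless households outside the service areas | "
        f"{rep.outside['no_vehicle_households']:,.0f} |",
        "",
    ]
    return "\n".join(lines)
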