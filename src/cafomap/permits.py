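"""Linking facilities to administrative permit records.

Permit registers carry two candidate locations per record — the registered
latitude/longitude and a geocoded street address — both noisy.  Two linkage
criteria are provided:

* **best matches**: a permit is unambiguously tied to one facility when
  *both* of its points are on the facility's parcel or within 200 m of its
  buildings, and the two points are not both within 200 m of any other
  facility.  Injective on permits.
* **expanded matches**: any permit with either point within 1,000 m of a
  facility's buildings; many-to-many.

Distances are planar meters to the union of the facility's building
footprints, not to its centroid.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from shapely.geometry import Point, Polygon

from .clustering import Facility, Parcel

__all__ = [
    "Permit",
    "MatchResult",
    "best_matches",
    "expanded_matches",
    "tabulate_permit_gaps",
    "permit_match_shares",
]


@dataclass(frozen=True)
class Permit:
    """An administrative permit record (state water-board style)."""

    wdid: str
    regulatory_program: str = ""
    activation_date: dt.date | None = None
    termination_date: dt.date | None = None
    facility_name: str = ""
    facility_address: str = ""
    agency_name: str = ""
    agency_address: str = ""
    npdes_no: str = ""
    cafo_population: int | None = None
    registered_point: Point | None = None
    address_point: Point | None = None

    def __post_init__(self) -> None:
        for pt in (self.registered_point, self.address_point):
            if pt is not None and not (abs(pt.x) < float("inf") and abs(pt.y) < float("inf")):
                raise ValueError(f"permit {self.wdid}: non-finite coordinates")

    @property
    def points(self) -> list[Point]:
        return [p for p in (self.registered_point, self.address_point) if p is not None]


@dataclass
class MatchResult:
    best: dict[str, str] = field(default_factory=dict)       # permit -> facility
    expanded: set[tuple[str, str]] = field(default_factory=set)

    def best_for_facility(self, facility_id: str) -> list[str]:
        return sorted(p for p, f in self.best.items() if f == facility_id)

    def expanded_for_facility(self, facility_id: str) -> list[str]:
        return sorted(p for p, f in self.expanded if f == facility_id)


def _point_parcel(
    point: Point, parcel_geoms: Mapping[str, Polygon] | None
) -> str | None:
    if parcel_geoms is None:
        return None
    for pid in sorted(parcel_geoms):
        if parcel_geoms[pid].covers(point):
            return pid
    return None


def _facility_parcel_ids(facility: Facility) -> set[str]:
    return {p.parcel_id for p in facility.parcels}


def best_matches(
    facilities: Sequence[Facility],
    permits: Sequence[Permit],
    parcel_geoms: Mapping[str, Polygon] | None = None,
    radius_m: float = 200.0,
) -> dict[str, str]:
    """Unambiguous permit -> facility assignments.

    Both permit points must individually be on one of the facility's
    parcels or within ``radius_m`` of its building-footprint union, and
    there must be no *other* facility with both points within ``radius_m``
    of it (the ambiguity veto uses the distance clause only).  Permits
    missing either point never best-match.  In the rare case that a permit
    qualifies for several facilities through the parcel clause and the veto
    does not fire, the nearest facility wins (ties to the smaller id).
    """
    for f in facilities:
        if f.geometry is None:
            raise ValueError(f"facility {f.facility_id}: derive attributes first")
    result: dict[str, str] = {}
    for permit in permits:
        if permit.registered_point is None or permit.address_point is None:
            continue
        pts = [permit.registered_point, permit.address_point]
        pt_parcels = [_point_parcel(p, parcel_geoms) for p in pts]
        qualified: list[tuple[float, str]] = []
        near_both: list[str] = []
        for fac in facilities:
            dists = [p.distance(fac.geometry) for p in pts]
            if all(d <= radius_m for d in dists):
                near_both.append(fac.facility_id)
            fac_parcels = _facility_parcel_ids(fac)
            ok = all(
                (pp is not None and pp in fac_parcels) or d <= radius_m
                for pp, d in zip(pt_parcels, dists)
            )
            if ok:
                qualified.append((min(dists), fac.facility_id))
        candidates = [
            (d, fid) for d, fid in qualified
            if all(other == fid for other in near_both)
        ]
        if candidates:
            candidates.sort()
            result[permit.wdid] = candidates[0][1]
    return result


def expanded_matches(
    facilities: Sequence[Facility],
    permits: Sequence[Permit],
    radius_m: float = 1000.0,
) -> set[tuple[str, str]]:
    """All (permit, facility) pairs with either permit point within radius."""
    pairs: set[tuple[str, str]] = set()
    for fac in facilities:
        if fac.geometry is None:
            raise ValueError(f"facility {fac.facility_id}: derive attributes first")
        for permit in permits:
            if any(p.distance(fac.geometry) <= radius_m for p in permit.points):
                pairs.add((permit.wdid, fac.facility_id))
    return pairs


def match_permits(
    facilities: Sequence[Facility],
    permits: Sequence[Permit],
    parcel_geoms: Mapping[str, Polygon] | None = None,
    best_radius_m: float = 200.0,
    expanded_radius_m: float = 1000.0,
) -> MatchResult:
    """Run both criteria and attach match lists to the facilities."""
    result = MatchResult(
        best=best_matches(facilities, permits, parcel_geoms, best_radius_m),
        expanded=expanded_matches(facilities, permits, expanded_radius_m),
    )
    for fac in facilities:
        fac.best_permit_ids = result.best_for_facility(fac.facility_id)
        fac.expanded_permit_ids = result.expanded_for_facility(fac.facility_id)
    return result


def tabulate_permit_gaps(
    facilities: Sequence[Facility],
    permits: Sequence[Permit],
    permit_counties: Mapping[str, str] | None = None,
    radius_m: float = 1000.0,
    population_threshold: int = 200,
) -> "pd.DataFrame":
    """Per-county reconciliation of facilities against the permit register.

    Columns: facilities (count), facilities_no_permit_within_radius,
    permits (count), permits_no_facility_within_radius,
    permits_population_gt_threshold, permits_no_animal_count (missing or
    zero ``cafo_population``).  Facilities are attributed to their derived
    county; permits to ``permit_counties`` when given, else to the county
    of the nearest facility within radius, else "unassigned".
    """
    import pandas as pd

    rows: dict[str, dict[str, int]] = {}

    def row(county: str) -> dict[str, int]:
        return rows.setdefault(
            county,
            {
                "facilities": 0,
                "facilities_no_permit_within_radius": 0,
                "permits": 0,
                "permits_no_facility_within_radius": 0,
                "permits_population_gt_threshold": 0,
                "permits_no_animal_count": 0,
            },
        )

    for fac in facilities:
        county = fac.county or "unassigned"
        r = row(county)
        r["facilities"] += 1
        has_permit = any(
            p.distance(fac.geometry) <= radius_m
            for permit in permits
            for p in permit.points
        )
        if not has_permit:
            r["facilities_no_permit_within_radius"] += 1

    for permit in permits:
        near = [
            fac
            for fac in facilities
            if any(p.distance(fac.geometry) <= radius_m for p in permit.points)
        ]
        if permit_counties is not None and permit.wdid in permit_counties:
            county = permit_counties[permit.wdid]
        elif near:
            nearest = min(
                near,
                key=lambda fac: min(
                    p.distance(fac.geometry) for p in permit.points
                ),
            )
            county = nearest.county or "unassigned"
        else:
            county = "unassigned"
        r = row(county)
        r["permits"] += 1
        if not near:
            r["permits_no_facility_within_radius"] += 1
        if permit.cafo_population is not None and permit.cafo_population > population_threshold:
            r["permits_population_gt_threshold"] += 1
        if not permit.cafo_population:  # None or 0
            r["permits_no_animal_count"] += 1

    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "county"
    return df


def permit_match_shares(
    n_facilities: int, n_best_matched: int, n_no_permit_within_1km: int
) -> dict[str, float]:
    """Facility shares by permit status, as percentages.

    Returns the share with at least one best permit match, the share with
    none, and the share with no permit of any kind within 1 km (candidate
    unpermitted operations), each rounded to one decimal.
    """
    if n_facilities <= 0:
        raise ValueError("need a positive facility count")
    if not 0 <= n_best_matched <= n_facilities:
        raise ValueError("best-matched count outside [0, n_facilities]")
    return {
        "best_matched_pct": round(100.0 * n_best_matched / n_facilities, 1),
        "not_best_matched_pct": round(
            100.0 * (n_facilities - n_best_matched) / n_facilities, 1
        ),
        "unpermitted_pct": round(100.0 * n_no_permit_within_1km / n_facilities, 1),
    }
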