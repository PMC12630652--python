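"""Aggregation of building annotations into facilities.

A facility is a group of one or more animal-housing buildings operated
together; physical proximity and common ownership are the grouping signals.
Two buildings are *related* when any of four rules holds:

1. they sit on the same land parcel;
2. they are within 400 m and their parcel owner names are similar;
3. they are within 200 m and at least one lacks parcel ownership data;
4. they are within 50 m and at least one is a "lone" building — one left
   unrelated to every other building by rules 1-3.

Facilities are the connected components of the relatedness graph.  All
distances are minimum planar distances between axis-aligned building
bounding boxes, in meters.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import networkx as nx
import numpy as np
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

__all__ = [
    "Building",
    "Parcel",
    "Facility",
    "ClusterThresholds",
    "building_distance",
    "normalize_owner_name",
    "owner_similarity",
    "related",
    "cluster_buildings",
    "derive_facility_attributes",
]


@dataclass(frozen=True)
class Building:
    building_id: str
    footprint: Polygon
    parcel_id: str | None = None
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.footprint.is_empty or not self.footprint.is_valid:
            raise ValueError(f"building {self.building_id}: invalid footprint")
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"building {self.building_id}: confidence outside [0,1]")

    @property
    def centroid(self) -> Point:
        return self.footprint.centroid

    @property
    def bbox(self) -> Polygon:
        return box(*self.footprint.bounds)


@dataclass(frozen=True)
class Parcel:
    parcel_id: str
    number: str
    county: str
    zip_code: str
    owner_name: str | None = None
    geometry: Polygon | None = None


@dataclass
class Facility:
    """A cluster of buildings plus derived facility-level attributes."""

    facility_id: str
    building_ids: list[str]
    centroid: Point | None = None
    bbox: tuple[float, float, float, float] | None = None  # minx,miny,maxx,maxy
    n_buildings: int = 0
    footprint_sq_m: float = 0.0
    county: str | None = None
    zip_code: str | None = None
    census_tract: str | None = None
    census_blockgroup: str | None = None
    incomplete_parcel_info: bool = False
    admin_unresolved: bool = False
    animal_type: object = None        # AnimalTypeLabel once resolved
    date_bounds: object = None        # DateBounds once annotated
    parcels: list[Parcel] = field(default_factory=list)
    best_permit_ids: list[str] = field(default_factory=list)
    expanded_permit_ids: list[str] = field(default_factory=list)
    geometry: object = None           # MultiPolygon union of footprints


@dataclass(frozen=True)
class ClusterThresholds:
    """Distance/similarity thresholds for the four relatedness rules."""

    same_parcel: bool = True
    owner_match_m: float = 400.0
    missing_parcel_m: float = 200.0
    lone_building_m: float = 50.0
    owner_similarity_min: float = 0.85


def building_distance(b1: Building, b2: Building) -> float:
    """Minimum planar distance between the two buildings' bounding boxes.

    Zero when the boxes touch or overlap.
    """
    return float(b1.bbox.distance(b2.bbox))


_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


def normalize_owner_name(name: str) -> str:
    """Casefold, strip punctuation, collapse whitespace."""
    return re.sub(r"\s+", " ", name.translate(_PUNCT_TABLE).casefold()).strip()


# Trailing legal-entity tokens carry no ownership signal ("Smith Dairy" and
# "Smith Dairy LLC" are the same operator); single letters cover initialisms
# left by punctuation stripping ("L.L.C." -> "l l c").
_LEGAL_SUFFIXES = frozenset(
    "llc llp lp ltd inc corp co company trust partnership l c p".split()
)


def _strip_legal_suffix(normalized: str) -> str:
    tokens = normalized.split()
    while len(tokens) > 1 and tokens[-1] in _LEGAL_SUFFIXES:
        tokens.pop()
    return " ".join(tokens)


def owner_similarity(name1: str, name2: str) -> float:
    """Normalized edit-distance similarity of owner names in [0, 1].

    Names are normalized (casefold, punctuation stripped, whitespace
    collapsed) and trailing legal-entity suffixes dropped before a
    length-normalized Levenshtein comparison.  1.0 for strings identical
    after normalization.  Symmetric.  Both names must be non-empty after
    normalization — missing ownership data is handled by the
    missing-parcel relatedness rule, not here.
    """
    a, b = normalize_owner_name(name1), normalize_owner_name(name2)
    if not a or not b:
        raise ValueError("owner names empty after normalization")
    if a == b:
        return 1.0
    a, b = _strip_legal_suffix(a), _strip_legal_suffix(b)
    if a == b:
        return 1.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def _rule123(
    b1: Building,
    b2: Building,
    parcels: Mapping[str, Parcel],
    t: ClusterThresholds,
) -> bool:
    """Relatedness under the first three rules (no lone-building logic)."""
    # Rule 1: same parcel, no distance limit.
    if (
        t.same_parcel
        and b1.parcel_id is not None
        and b1.parcel_id == b2.parcel_id
    ):
        return True
    d = building_distance(b1, b2)
    # Rule 3: near and at least one building lacks parcel ownership data.
    p1 = parcels.get(b1.parcel_id) if b1.parcel_id else None
    p2 = parcels.get(b2.parcel_id) if b2.parcel_id else None
    owner1 = p1.owner_name if p1 else None
    owner2 = p2.owner_name if p2 else None
    if d <= t.missing_parcel_m and (owner1 is None or owner2 is None):
        return True
    # Rule 2: near and similar owner names.
    if (
        d <= t.owner_match_m
        and owner1 is not None
        and owner2 is not None
        and owner_similarity(owner1, owner2) >= t.owner_similarity_min
    ):
        return True
    return False


def related(
    b1: Building,
    b2: Building,
    parcels: Mapping[str, Parcel],
    thresholds: ClusterThresholds = ClusterThresholds(),
    lone_ids: frozenset[str] | None = None,
) -> bool:
    """Whether two buildings belong to the same facility.

    ``lone_ids`` is the set of buildings unrelated to all others under
    rules 1-3; when provided, rule 4 (within 50 m of a lone building) is
    also evaluated.  Callers normally use :func:`cluster_buildings`, which
    computes lone status in its second pass.
    """
    if _rule123(b1, b2, parcels, thresholds):
        return True
    if lone_ids and (b1.building_id in lone_ids or b2.building_id in lone_ids):
        return building_distance(b1, b2) <= thresholds.lone_building_m
    return False


def cluster_buildings(
    buildings: Sequence[Building],
    parcels: Mapping[str, Parcel] | Iterable[Parcel],
    thresholds: ClusterThresholds = ClusterThresholds(),
) -> list[Facility]:
    """Partition buildings into facilities via the relatedness graph.

    Rules 1-3 build the initial graph; buildings isolated there are "lone"
    and a second pass adds rule-4 edges (lone building within 50 m of any
    other).  Facilities are connected components, with ids assigned in
    order of each component's minimum building id so output is independent
    of input order.
    """
    if not isinstance(parcels, Mapping):
        parcels = {p.parcel_id: p for p in parcels}
    ids = [b.building_id for b in buildings]
    if len(set(ids)) != len(ids):
        raise ValueError("building ids must be unique")

    bs = sorted(buildings, key=lambda b: b.building_id)
    g = nx.Graph()
    g.add_nodes_from(b.building_id for b in bs)
    for i, b1 in enumerate(bs):
        for b2 in bs[i + 1 :]:
            if _rule123(b1, b2, parcels, thresholds):
                g.add_edge(b1.building_id, b2.building_id, rule="1-3")
    lone = frozenset(n for n in g.nodes if g.degree[n] == 0)
    if lone:
        for i, b1 in enumerate(bs):
            for b2 in bs[i + 1 :]:
                if (b1.building_id in lone or b2.building_id in lone) and (
                    building_distance(b1, b2) <= thresholds.lone_building_m
                ):
                    g.add_edge(b1.building_id, b2.building_id, rule="4")

    by_id = {b.building_id: b for b in bs}
    components = sorted(
        (sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0]
    )
    facilities = []
    for k, comp in enumerate(components, start=1):
        missing = any(by_id[bid].parcel_id is None for bid in comp)
        facilities.append(
            Facility(
                facility_id=f"F{k:05d}",
                building_ids=comp,
                n_buildings=len(comp),
                incomplete_parcel_info=missing,
            )
        )
    return facilities


def _plurality(values: Sequence[str | None], rng: np.random.Generator) -> str | None:
    """Most frequent non-missing value; ties broken by seeded uniform choice."""
    counts: dict[str, int] = {}
    for v in values:
        if v is not None:
            counts[v] = counts.get(v, 0) + 1
    if not counts:
        return None
    best = max(counts.values())
    tied = sorted(v for v, c in counts.items() if c == best)
    if len(tied) == 1:
        return tied[0]
    return tied[int(rng.integers(len(tied)))]


def derive_facility_attributes(
    facility: Facility,
    buildings: Mapping[str, Building] | Sequence[Building],
    admin_polygons: Mapping[str, Mapping[str, Polygon]] | None = None,
    parcels: Mapping[str, Parcel] | None = None,
    seed: int = 0,
) -> Facility:
    """Fill in a facility's derived geography and administrative units.

    The centroid is that of the multipolygon union of footprints, the bbox
    the envelope of all footprints, and the total footprint the sum of
    building areas.  County, census tract and block group are assigned by
    plurality of building centroids among the supplied admin polygons, with
    ties broken by a seeded random choice among the tied units (stable
    across runs and input orderings).  A building centroid covered by no
    polygon of a level contributes a missing value; if every centroid is
    uncovered the facility attribute is None and the facility is flagged.
    """
    if not isinstance(buildings, Mapping):
        buildings = {b.building_id: b for b in buildings}
    blds = [buildings[bid] for bid in facility.building_ids]
    union = unary_union([b.footprint for b in blds])
    bounds = union.bounds
    facility.geometry = union
    facility.centroid = union.centroid
    facility.bbox = bounds
    facility.n_buildings = len(blds)
    facility.footprint_sq_m = float(sum(b.footprint.area for b in blds))

    rng = np.random.default_rng(seed)
    if admin_polygons:
        for level, attr in (
            ("county", "county"),
            ("zip_code", "zip_code"),
            ("census_tract", "census_tract"),
            ("census_blockgroup", "census_blockgroup"),
        ):
            polys = admin_polygons.get(level)
            if polys is None:
                continue
            hits: list[str | None] = []
            for b in blds:
                unit = next(
                    (name for name, geom in sorted(polys.items())
                     if geom.covers(b.centroid)),
                    None,
                )
                hits.append(unit)
            value = _plurality(hits, rng)
            setattr(facility, attr, value)
            if value is None:
                facility.admin_unresolved = True

    if parcels is not None:
        seen: dict[str, Parcel] = {}
        for b in blds:
            if b.parcel_id is not None and b.parcel_id in parcels:
                seen[b.parcel_id] = parcels[b.parcel_id]
        facility.parcels = [seen[k] for k in sorted(seen)]
    return facility
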