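"""Synthetic study-region generator with known ground truth.

Builds a planar landscape — parcels on a rectangular grid, facilities as
compact clusters of rectangular buildings with common owners, a permit
register with configurable real-world pathologies (missing coordinates,
duplicated addresses, absent animal counts), a tile frame with county
bands, and per-building detection confidences — so the full pipeline
(cluster → match → estimate) can be exercised against exact ground truth.

All randomness flows from a single master seed through named child
streams, one per generator component, so each component's output is
reproducible independently of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from shapely.geometry import Point, Polygon, box

from .clustering import Building, Parcel
from .permits import Permit
from .tiling import Detection, Tile, assign_detections, duplicate_boundary_tiles, make_tile_grid

__all__ = [
    "LandscapeConfig",
    "GroundTruth",
    "Landscape",
    "PackingError",
    "generate_landscape",
    "generate_strata_labels",
]

_FIRST = [
    "SMITH", "JONES", "GARCIA", "MILLER", "DAVIS", "LOPEZ", "WILSON",
    "ANDERSON", "TAYLOR", "THOMAS", "MOORE", "MARTIN", "JACKSON", "LEE",
    "PEREZ", "WHITE", "HARRIS", "CLARK", "LEWIS", "WALKER", "HALL",
    "YOUNG", "KING", "WRIGHT", "SCOTT", "TORRES", "NGUYEN", "HILL",
    "ADAMS", "BAKER", "NELSON", "CAMPBELL",
]
_KIND = ["DAIRY", "FARMS", "RANCH", "POULTRY", "LIVESTOCK", "CATTLE CO", "AG"]
_SUFFIX = ["LLC", "INC", "LP", "TRUST", ""]


class PackingError(RuntimeError):
    """Raised when facilities cannot be placed at the required separation."""


class LandscapeConfig(BaseModel):
    """Parameters of the synthetic study region.

    Distances are planar meters; rates are probabilities in [0, 1].  The
    permit pathology rates default to the magnitudes seen in real state
    CAFO registers (roughly one permit in nine missing its coordinates,
    one in five sharing an address, one in four reporting no animal
    count).
    """

    region_width_m: float = Field(default=20_000.0, gt=0)
    region_height_m: float = Field(default=20_000.0, gt=0)
    n_facilities: int = Field(default=25, ge=0)
    buildings_per_facility_range: tuple[int, int] = (2, 8)
    facility_separation_min_m: float = Field(default=2_500.0, gt=0)
    facility_cluster_radius_m: float = Field(default=80.0, gt=0)
    parcel_grid_m: float = Field(default=800.0, gt=0)
    n_counties: int = Field(default=4, ge=1)
    tile_size_m: float = Field(default=1_000.0, gt=0)
    owner_name_noise_rate: float = Field(default=0.0, ge=0, le=1)
    facility_permit_rate: float = Field(default=0.9, ge=0, le=1)
    orphan_permit_rate: float = Field(default=0.1, ge=0, le=1)
    permit_jitter_m: float = Field(default=50.0, ge=0)
    permit_missing_location_rate: float = Field(default=0.11, ge=0, le=1)
    permit_duplicate_address_rate: float = Field(default=0.18, ge=0, le=1)
    permit_zero_population_rate: float = Field(default=0.25, ge=0, le=1)
    detection_miss_rate: float = Field(default=0.01, ge=0, le=1)
    positivity_rate_by_stratum: dict[str, float] = Field(default_factory=dict)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "LandscapeConfig":
        lo, hi = self.buildings_per_facility_range
        if not 1 <= lo <= hi:
            raise ValueError("buildings_per_facility_range must satisfy 1 <= lo <= hi")
        for k, v in self.positivity_rate_by_stratum.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"positivity rate for {k} outside [0,1]")
        return self

    def zero_noise(self) -> "LandscapeConfig":
        """A copy with every noise channel switched off."""
        return self.model_copy(
            update=dict(
                owner_name_noise_rate=0.0,
                permit_missing_location_rate=0.0,
                permit_duplicate_address_rate=0.0,
                permit_zero_population_rate=0.0,
                orphan_permit_rate=0.0,
                detection_miss_rate=0.0,
                permit_jitter_m=0.0,
                facility_permit_rate=1.0,
            )
        )


@dataclass
class GroundTruth:
    facility_assignment: dict[str, str]          # building -> facility
    permit_assignment: dict[str, str | None]     # permit -> facility (None: orphan)
    true_positive_tiles: set[str]
    true_facility_count: int
    facility_centers: dict[str, Point] = field(default_factory=dict)
    missed_facilities: set[str] = field(default_factory=set)


@dataclass
class Landscape:
    """Generator output; unpacks as (buildings, parcels, permits, tiles, truth)."""

    buildings: list[Building]
    parcels: list[Parcel]
    permits: list[Permit]
    tiles: list[Tile]
    ground_truth: GroundTruth
    detections: list[Detection] = field(default_factory=list)
    county_polygons: dict[str, Polygon] = field(default_factory=dict)
    county_clusters: dict[str, int] = field(default_factory=dict)
    parcel_geoms: dict[str, Polygon] = field(default_factory=dict)
    config: LandscapeConfig | None = None

    def __iter__(self) -> Iterator:
        return iter(
            (self.buildings, self.parcels, self.permits, self.tiles, self.ground_truth)
        )


def _owner_pool(rng: np.random.Generator, n: int) -> list[str]:
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < n:
        name = " ".join(
            filter(
                None,
                (
                    _FIRST[int(rng.integers(len(_FIRST)))],
                    _KIND[int(rng.integers(len(_KIND)))],
                    _SUFFIX[int(rng.integers(len(_SUFFIX)))],
                ),
            )
        )
        if name not in seen:
            seen.add(name)
            names.append(name)
    return names


def _perturb_name(name: str, rng: np.random.Generator) -> str:
    """A spelling variant that stays recognizably the same owner."""
    choice = int(rng.integers(3))
    if choice == 0:
        return name.replace(" LLC", ", L.L.C.") if "LLC" in name else name + " CO"
    if choice == 1:
        return name.title()
    i = int(rng.integers(len(name)))
    return name[:i] + name[i] + name[i:]  # doubled character


def _place_centers(cfg: LandscapeConfig, rng: np.random.Generator) -> list[Point]:
    margin = cfg.facility_cluster_radius_m + 100.0
    lo_x, hi_x = margin, cfg.region_width_m - margin
    lo_y, hi_y = margin, cfg.region_height_m - margin
    if cfg.n_facilities and (hi_x <= lo_x or hi_y <= lo_y):
        raise PackingError("region too small for the cluster radius margin")
    centers: list[Point] = []
    attempts = 0
    max_attempts = 2000 * max(cfg.n_facilities, 1)
    while len(centers) < cfg.n_facilities:
        attempts += 1
        if attempts > max_attempts:
            raise PackingError(
                f"could not place {cfg.n_facilities} facilities at separation "
                f">= {cfg.facility_separation_min_m} m in a "
                f"{cfg.region_width_m:g} x {cfg.region_height_m:g} m region"
            )
        p = Point(rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y))
        if all(p.distance(q) >= cfg.facility_separation_min_m for q in centers):
            centers.append(p)
    return centers


def generate_landscape(config: LandscapeConfig) -> Landscape:
    """Generate the full synthetic landscape.

    Raises :class:`PackingError` when the requested facility count cannot
    be placed at the required separation (explicit failure, never silent
    truncation).
    """
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_place, rng_bld, rng_own, rng_perm, rng_det, _ = (
        np.random.default_rng(s) for s in streams
    )

    centers = _place_centers(config, rng_place)
    facility_ids = [f"GT{k:04d}" for k in range(len(centers))]

    # Parcels: rectangular grid covering the region.
    parcel_geoms: dict[str, Polygon] = {}
    g = config.parcel_grid_m
    ncols = int(np.ceil(config.region_width_m / g))
    nrows = int(np.ceil(config.region_height_m / g))
    for r in range(nrows):
        for c in range(ncols):
            pid = f"P{r:03d}_{c:03d}"
            parcel_geoms[pid] = box(
                c * g, r * g,
                min((c + 1) * g, config.region_width_m),
                min((r + 1) * g, config.region_height_m),
            )

    def parcel_at(pt: Point) -> str:
        c = min(int(pt.x // g), ncols - 1)
        r = min(int(pt.y // g), nrows - 1)
        return f"P{r:03d}_{c:03d}"

    # County bands: vertical strips with unaligned boundaries so some tiles
    # straddle two counties and get duplicated.
    county_polygons: dict[str, Polygon] = {}
    w = config.region_width_m / config.n_counties
    for k in range(config.n_counties):
        x0 = k * w
        x1 = config.region_width_m if k == config.n_counties - 1 else (k + 1) * w
        county_polygons[f"C{k:02d}"] = box(x0, 0, x1, config.region_height_m)
    county_clusters = {cid: i + 1 for i, cid in enumerate(sorted(county_polygons))}

    def county_at(pt: Point) -> str:
        k = min(int(pt.x // w), config.n_counties - 1)
        return f"C{k:02d}"

    # Buildings.
    owners = _owner_pool(rng_own, len(centers) + 8)
    lo, hi = config.buildings_per_facility_range
    buildings: list[Building] = []
    facility_assignment: dict[str, str] = {}
    facility_of_parcel: dict[str, str] = {}
    missed = {
        fid
        for fid in facility_ids
        if rng_det.random() < config.detection_miss_rate
    }
    detections: list[Detection] = []
    bid_counter = 0
    for fid, center in zip(facility_ids, centers):
        n_b = int(rng_bld.integers(lo, hi + 1))
        placed: list = []
        for _ in range(n_b):
            # rejection-place so footprints never touch (real buildings are
            # disjoint and a facility MultiPolygon must be valid); the disk
            # radius grows slowly if the cluster gets crowded
            foot = None
            for attempt in range(200):
                radius = config.facility_cluster_radius_m * (1 + attempt / 100)
                ang = rng_bld.uniform(0, 2 * np.pi)
                rad = radius * np.sqrt(rng_bld.uniform())
                cx, cy = center.x + rad * np.cos(ang), center.y + rad * np.sin(ang)
                bw = rng_bld.uniform(20, 60)
                bh = rng_bld.uniform(12, 30)
                cand = box(cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2)
                if not any(cand.intersects(other) for other in placed):
                    foot = cand
                    break
            if foot is None:
                raise PackingError(
                    f"could not place {n_b} disjoint buildings for facility {fid}"
                )
            placed.append(foot)
            if fid in missed:
                conf = float(rng_det.uniform(0.05, 0.45))
            else:
                conf = float(rng_det.uniform(0.55, 0.95))
            bid = f"B{bid_counter:05d}"
            bid_counter += 1
            pid = parcel_at(foot.centroid)
            buildings.append(
                Building(building_id=bid, footprint=foot, parcel_id=pid, confidence=conf)
            )
            facility_assignment[bid] = fid
            facility_of_parcel.setdefault(pid, fid)
            detections.append(Detection(x=foot.centroid.x, y=foot.centroid.y, confidence=conf))

    # Parcel records: facility parcels take the facility owner's name (with
    # optional spelling noise); other parcels get background owners.
    owner_of_facility = dict(zip(facility_ids, owners))
    parcels: list[Parcel] = []
    for pid in sorted(parcel_geoms):
        geom = parcel_geoms[pid]
        fid = facility_of_parcel.get(pid)
        if fid is not None:
            name = owner_of_facility[fid]
            if rng_own.random() < config.owner_name_noise_rate:
                name = _perturb_name(name, rng_own)
        else:
            name = owners[-1 - int(rng_own.integers(8))]
        cen = geom.centroid
        parcels.append(
            Parcel(
                parcel_id=pid,
                number=pid.replace("P", "APN-"),
                county=county_at(cen),
                zip_code=f"9{int(cen.x // 5000):02d}{int(cen.y // 5000):02d}",
                owner_name=name,
                geometry=geom,
            )
        )

    # Permits.
    permits: list[Permit] = []
    permit_assignment: dict[str, str | None] = {}
    widx = 0
    for fid, center in zip(facility_ids, centers):
        if rng_perm.random() >= config.facility_permit_rate:
            continue
        wdid = f"W{widx:05d}"
        widx += 1
        jit = lambda: rng_perm.normal(0.0, config.permit_jitter_m / 2) if config.permit_jitter_m else 0.0
        reg = Point(center.x + jit(), center.y + jit())
        addr_pt = Point(center.x + jit(), center.y + jit())
        address = f"{1000 + widx} COUNTY ROAD {int(center.x // 1000)}, {county_at(center)}"
        if rng_perm.random() < config.permit_missing_location_rate:
            reg = None
        if permits and rng_perm.random() < config.permit_duplicate_address_rate:
            donor = permits[int(rng_perm.integers(len(permits)))]
            address, addr_pt = donor.facility_address, donor.address_point
        if rng_perm.random() < config.permit_zero_population_rate:
            pop = 0 if rng_perm.random() < 0.5 else None
        else:
            pop = int(rng_perm.lognormal(6.5, 0.8)) + 200
        program = "Cattle CAFO" if rng_perm.random() < 0.7 else "Other Animal CAFO"
        permits.append(
            Permit(
                wdid=wdid,
                regulatory_program=program,
                facility_name=f"{owner_of_facility[fid]} FACILITY",
                facility_address=address,
                agency_name=owner_of_facility[fid],
                agency_address=address,
                cafo_population=pop,
                registered_point=reg,
                address_point=addr_pt,
            )
        )
        permit_assignment[wdid] = fid
    n_orphans = int(round(config.orphan_permit_rate * len(centers)))
    for _ in range(n_orphans):
        wdid = f"W{widx:05d}"
        widx += 1
        pt = Point(
            rng_perm.uniform(0, config.region_width_m),
            rng_perm.uniform(0, config.region_height_m),
        )
        permits.append(
            Permit(
                wdid=wdid,
                regulatory_program="Cattle CAFO",
                facility_name="TERMINATED OPERATION",
                facility_address=f"{2000 + widx} OLD ROUTE, {county_at(pt)}",
                cafo_population=None,
                registered_point=pt,
                address_point=Point(pt.x, pt.y),
            )
        )
        permit_assignment[wdid] = None

    # Tile frame with county duplication and detection assignment.
    region = box(0, 0, config.region_width_m, config.region_height_m)
    tiles = make_tile_grid(region, config.tile_size_m)
    tiles = duplicate_boundary_tiles(tiles, county_polygons)
    tiles = assign_detections(tiles, detections)

    true_positive: set[str] = set()
    for t in tiles:
        for b in buildings:
            c = b.footprint.centroid
            if t.contains_point(c.x, c.y) and t.geometry.buffer(1e-9).covers(c):
                true_positive.add(t.tile_id)
                break

    truth = GroundTruth(
        facility_assignment=facility_assignment,
        permit_assignment=permit_assignment,
        true_positive_tiles=true_positive,
        true_facility_count=len(centers),
        facility_centers=dict(zip(facility_ids, centers)),
        missed_facilities=missed,
    )
    return Landscape(
        buildings=buildings,
        parcels=parcels,
        permits=permits,
        tiles=tiles,
        ground_truth=truth,
        detections=detections,
        county_polygons=county_polygons,
        county_clusters=county_clusters,
        parcel_geoms=parcel_geoms,
        config=config,
    )


def generate_strata_labels(
    strata_totals: Mapping[str, int],
    positivity_rate_by_stratum: Mapping[str, float],
    sample_sizes: Mapping[str, int],
    seed: int,
) -> list[dict]:
    """Simulate stratified labeling: binomial positives per stratum.

    For each stratum, ``sample_sizes[s]`` tiles are labeled and each is
    positive independently with the stratum's positivity rate.  Returns
    one record per labeled tile with ``stratum_id``, ``tile_id`` and a
    binary ``label``.
    """
    rng = np.random.default_rng(seed)
    records: list[dict] = []
    for sid in sorted(strata_totals):
        total = strata_totals[sid]
        n = sample_sizes[sid]
        if n > total:
            raise ValueError(f"stratum {sid}: sample size {n} exceeds total {total}")
        p = positivity_rate_by_stratum[sid]
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"stratum {sid}: rate {p} outside [0,1]")
        labels = rng.random(n) < p
        for i, lab in enumerate(labels):
            records.append(
                {"stratum_id": sid, "tile_id": f"{sid}/t{i:06d}", "label": int(lab)}
            )
    return records
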