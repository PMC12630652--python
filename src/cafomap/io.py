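"""Interchange formats: flat facility CSV, rich GeoJSON, permits, strata.

Internally the pipeline works in a planar metric frame (all clustering and
matching thresholds are meter distances); conversion to WGS84 lon/lat
happens only here, at the I/O boundary, through a local equirectangular
projection anchored at a configurable origin.  GeoJSON output follows
RFC 7946: coordinates are [lon, lat] and geometries are WGS84.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from shapely.geometry import Point, Polygon, box, mapping, shape

from .annotation import DateBounds
from .clustering import Building, Facility, Parcel
from .completeness import Stratum
from .permits import Permit

__all__ = [
    "LocalProjection",
    "FACILITY_CSV_COLUMNS",
    "SchemaError",
    "write_facilities_csv",
    "read_facilities_csv",
    "write_facilities_geojson",
    "read_facilities_geojson",
    "write_permits_csv",
    "read_permits_csv",
    "write_buildings_csv",
    "read_buildings_csv",
    "write_parcels_csv",
    "read_parcels_csv",
    "write_strata_csv",
    "read_strata_csv",
]

FACILITY_CSV_COLUMNS = [
    "facility_id",
    "latitude",
    "longitude",
    "lat_min",
    "lon_min",
    "lat_max",
    "lon_max",
    "n_buildings",
    "footprint_sq_m",
    "county",
    "zip_code",
    "census_tract",
    "census_blockgroup",
    "animal_type",
    "construction_lower",
    "construction_upper",
    "destruction_lower",
    "destruction_upper",
]

METERS_PER_DEG_LAT = 111_320.0


class SchemaError(ValueError):
    """A file does not conform to the documented schema."""


def _to_csv_lossless(df: pd.DataFrame, path: str | Path) -> None:
    """Write CSV with floats in shortest round-trippable form."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else repr(v))
        elif out[col].dtype.kind == "O":
            out[col] = out[col].map(
                lambda v: "" if v is None else (repr(v) if isinstance(v, float) else v)
            )
    out.to_csv(path, index=False)


@dataclass(frozen=True)
class LocalProjection:
    """Equirectangular planar frame anchored at (origin_lon, origin_lat).

    x is meters east of the origin, y meters north; exactly invertible,
    adequate over the ~100 km extents of a study region.
    """

    origin_lon: float = -120.0
    origin_lat: float = 36.5

    @property
    def _m_per_deg_lon(self) -> float:
        return METERS_PER_DEG_LAT * math.cos(math.radians(self.origin_lat))

    def to_lonlat(self, x: float, y: float) -> tuple[float, float]:
        return (
            self.origin_lon + x / self._m_per_deg_lon,
            self.origin_lat + y / METERS_PER_DEG_LAT,
        )

    def to_planar(self, lon: float, lat: float) -> tuple[float, float]:
        return (
            (lon - self.origin_lon) * self._m_per_deg_lon,
            (lat - self.origin_lat) * METERS_PER_DEG_LAT,
        )

    def polygon_to_lonlat(self, poly: Polygon) -> Polygon:
        ext = [self.to_lonlat(x, y) for x, y in poly.exterior.coords]
        ints = [
            [self.to_lonlat(x, y) for x, y in ring.coords]
            for ring in poly.interiors
        ]
        return Polygon(ext, ints)


def _animal_type_str(facility: Facility) -> str:
    label = facility.animal_type
    if label is None:
        return ""
    return "+".join(sorted(label.types))


def _date_str(d: dt.date | None) -> str:
    return d.isoformat() if d is not None else ""


def _bounds_fields(facility: Facility) -> dict[str, str]:
    b = facility.date_bounds
    if b is None:
        return {
            "construction_lower": "",
            "construction_upper": "",
            "destruction_lower": "",
            "destruction_upper": "",
        }
    return {
        "construction_lower": _date_str(b.construction_lower),
        "construction_upper": _date_str(b.construction_upper),
        "destruction_lower": _date_str(b.destruction_lower),
        "destruction_upper": _date_str(b.destruction_upper),
    }


def facility_flat_record(facility: Facility, proj: LocalProjection) -> dict:
    """The flat-CSV row for one facility (WGS84 at the boundary)."""
    if facility.centroid is None or facility.bbox is None:
        raise ValueError(f"facility {facility.facility_id}: attributes not derived")
    lon, lat = proj.to_lonlat(facility.centroid.x, facility.centroid.y)
    minx, miny, maxx, maxy = facility.bbox
    lon_min, lat_min = proj.to_lonlat(minx, miny)
    lon_max, lat_max = proj.to_lonlat(maxx, maxy)
    rec = {
        "facility_id": facility.facility_id,
        "latitude": lat,
        "longitude": lon,
        "lat_min": lat_min,
        "lon_min": lon_min,
        "lat_max": lat_max,
        "lon_max": lon_max,
        "n_buildings": facility.n_buildings,
        "footprint_sq_m": facility.footprint_sq_m,
        "county": facility.county or "",
        "zip_code": facility.zip_code or "",
        "census_tract": facility.census_tract or "",
        "census_blockgroup": facility.census_blockgroup or "",
        "animal_type": _animal_type_str(facility),
    }
    rec.update(_bounds_fields(facility))
    return rec


def write_facilities_csv(
    facilities: Sequence[Facility],
    path: str | Path,
    proj: LocalProjection = LocalProjection(),
) -> None:
    rows = [facility_flat_record(f, proj) for f in facilities]
    df = pd.DataFrame(rows, columns=FACILITY_CSV_COLUMNS)
    _to_csv_lossless(df, path)


def read_facilities_csv(path: str | Path) -> pd.DataFrame:
    """Read and schema-check the flat facility CSV."""
    df = pd.read_csv(path, dtype={"zip_code": str, "census_tract": str,
                                  "census_blockgroup": str, "county": str},
                     keep_default_na=False, na_values=[],
                     float_precision="round_trip")
    missing = [c for c in FACILITY_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"facilities CSV missing column(s): {missing}")
    extra = [c for c in df.columns if c not in FACILITY_CSV_COLUMNS]
    if extra:
        raise SchemaError(f"facilities CSV has undocumented column(s): {extra}")
    for col in ("latitude", "longitude", "lat_min", "lon_min", "lat_max",
                "lon_max", "footprint_sq_m"):
        df[col] = df[col].astype(float)
    df["n_buildings"] = df["n_buildings"].astype(int)
    bad = df[(df.lat_min > df.lat_max) | (df.lon_min > df.lon_max)]
    if len(bad):
        raise SchemaError(
            f"inconsistent bounding box for facilities {list(bad.facility_id)}"
        )
    return df


def _permit_dict(permit: Permit, proj: LocalProjection) -> dict:
    lat = lon = None
    if permit.registered_point is not None:
        lon, lat = proj.to_lonlat(permit.registered_point.x, permit.registered_point.y)
    return {
        "wdid": permit.wdid,
        "regulatory_program": permit.regulatory_program,
        "activation_date": _date_str(permit.activation_date),
        "termination_date": _date_str(permit.termination_date),
        "facility_name": permit.facility_name,
        "facility_address": permit.facility_address,
        "agency_name": permit.agency_name,
        "agency_address": permit.agency_address,
        "npdes_no": permit.npdes_no,
        "cafo_population": permit.cafo_population,
        "latitude": lat,
        "longitude": lon,
    }


def write_facilities_geojson(
    facilities: Sequence[Facility],
    path: str | Path,
    buildings: Mapping[str, Building] | None = None,
    permits: Mapping[str, Permit] | None = None,
    proj: LocalProjection = LocalProjection(),
    private: bool = False,
) -> None:
    """Write the rich GeoJSON FeatureCollection (RFC 7946).

    Each facility is a MultiPolygon feature, one polygon per building, with
    the flat fields plus nested parcel and permit lists and a census_block
    object.  Parcel owner names are withheld unless ``private`` is set.
    """
    seen_best: dict[str, str] = {}
    features = []
    for fac in sorted(facilities, key=lambda f: f.facility_id):
        if buildings is not None:
            polys = [
                proj.polygon_to_lonlat(buildings[bid].footprint)
                for bid in fac.building_ids
            ]
        elif fac.geometry is not None:
            geoms = getattr(fac.geometry, "geoms", [fac.geometry])
            polys = [proj.polygon_to_lonlat(p) for p in geoms]
        else:
            raise ValueError(f"facility {fac.facility_id}: no geometry")
        if len(polys) != fac.n_buildings:
            raise ValueError(
                f"facility {fac.facility_id}: {len(polys)} polygons for "
                f"{fac.n_buildings} buildings"
            )
        for wdid in fac.best_permit_ids:
            if wdid in seen_best:
                raise ValueError(
                    f"permit {wdid} best-matched to both {seen_best[wdid]} "
                    f"and {fac.facility_id}"
                )
            seen_best[wdid] = fac.facility_id

        props = facility_flat_record(fac, proj)
        parcels = []
        for p in fac.parcels:
            rec = {"number": p.number, "county": p.county, "zip_code": p.zip_code}
            if private:
                rec["owner_name"] = p.owner_name
            parcels.append(rec)
        props["parcels"] = parcels
        if permits is not None:
            props["best_permit_matches"] = [
                _permit_dict(permits[w], proj) for w in fac.best_permit_ids
            ]
            props["expanded_permit_matches"] = [
                _permit_dict(permits[w], proj) for w in fac.expanded_permit_ids
            ]
        else:
            props["best_permit_matches"] = list(fac.best_permit_ids)
            props["expanded_permit_matches"] = list(fac.expanded_permit_ids)
        props["census_block"] = {
            "countyfp": fac.county or "",
            "tractce": fac.census_tract or "",
            "blockce": "",
            "geoid": "",
        }
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "MultiPolygon",
                    "coordinates": [
                        [[list(c) for c in poly.exterior.coords]] for poly in polys
                    ],
                },
                "properties": props,
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(collection, indent=1, sort_keys=True))


def read_facilities_geojson(path: str | Path) -> dict:
    """Read and validate the facility FeatureCollection.

    Checks GeoJSON structure, geometry validity, polygon-count/n_buildings
    agreement, and that no permit appears in two best-match lists.
    """
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection":
        raise SchemaError("not a GeoJSON FeatureCollection")
    seen_best: dict[str, str] = {}
    for feat in data.get("features", []):
        geom = shape(feat["geometry"])
        if geom.geom_type != "MultiPolygon":
            raise SchemaError("facility geometry must be a MultiPolygon")
        if not geom.is_valid:
            raise SchemaError("invalid facility geometry")
        props = feat["properties"]
        if len(geom.geoms) != int(props["n_buildings"]):
            raise SchemaError(
                f"facility {props.get('facility_id')}: polygon count "
                f"{len(geom.geoms)} != n_buildings {props['n_buildings']}"
            )
        for entry in props.get("best_permit_matches", []):
            wdid = entry["wdid"] if isinstance(entry, dict) else entry
            if wdid in seen_best:
                raise SchemaError(
                    f"permit {wdid} appears in two best_permit_matches lists"
                )
            seen_best[wdid] = props.get("facility_id")
    return data


PERMIT_CSV_COLUMNS = [
    "wdid", "regulatory_program", "activation_date", "termination_date",
    "facility_name", "facility_address", "agency_name", "agency_address",
    "npdes_no", "cafo_population", "latitude", "longitude",
    "address_latitude", "address_longitude",
]


def write_permits_csv(
    permits: Sequence[Permit],
    path: str | Path,
    proj: LocalProjection = LocalProjection(),
) -> None:
    rows = []
    for p in permits:
        rec = _permit_dict(p, proj)
        if p.address_point is not None:
            alon, alat = proj.to_lonlat(p.address_point.x, p.address_point.y)
        else:
            alon = alat = None
        rec["address_latitude"] = alat
        rec["address_longitude"] = alon
        rows.append(rec)
    _to_csv_lossless(pd.DataFrame(rows, columns=PERMIT_CSV_COLUMNS), path)


def read_permits_csv(
    path: str | Path, proj: LocalProjection = LocalProjection()
) -> list[Permit]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[],
                     float_precision="round_trip")
    missing = [c for c in PERMIT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"permits CSV missing column(s): {missing}")

    def pt(lat, lon) -> Point | None:
        if lat == "" or lon == "":
            return None
        x, y = proj.to_planar(float(lon), float(lat))
        return Point(x, y)

    def date(v) -> dt.date | None:
        return dt.date.fromisoformat(v) if v else None

    permits = []
    for _, r in df.iterrows():
        pop = r["cafo_population"]
        if isinstance(pop, float) and pd.isna(pop):
            pop = ""
        permits.append(
            Permit(
                wdid=str(r["wdid"]),
                regulatory_program=str(r["regulatory_program"]),
                activation_date=date(r["activation_date"]),
                termination_date=date(r["termination_date"]),
                facility_name=str(r["facility_name"]),
                facility_address=str(r["facility_address"]),
                agency_name=str(r["agency_name"]),
                agency_address=str(r["agency_address"]),
                npdes_no=str(r["npdes_no"]),
                cafo_population=None if pop == "" else int(float(pop)),
                registered_point=pt(r["latitude"], r["longitude"]),
                address_point=pt(r["address_latitude"], r["address_longitude"]),
            )
        )
    return permits


BUILDING_CSV_COLUMNS = ["building_id", "parcel_id", "confidence",
                        "minx", "miny", "maxx", "maxy"]


def write_buildings_csv(buildings: Sequence[Building], path: str | Path) -> None:
    """Planar-frame building table (axis-aligned footprint bounds)."""
    rows = []
    for b in buildings:
        minx, miny, maxx, maxy = b.footprint.bounds
        rows.append(
            {
                "building_id": b.building_id,
                "parcel_id": b.parcel_id or "",
                "confidence": "" if b.confidence is None else b.confidence,
                "minx": minx, "miny": miny, "maxx": maxx, "maxy": maxy,
            }
        )
    _to_csv_lossless(pd.DataFrame(rows, columns=BUILDING_CSV_COLUMNS), path)


def read_buildings_csv(path: str | Path) -> list[Building]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[],
                     float_precision="round_trip")
    missing = [c for c in BUILDING_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"buildings CSV missing column(s): {missing}")
    return [
        Building(
            building_id=str(r["building_id"]),
            footprint=box(float(r["minx"]), float(r["miny"]),
                          float(r["maxx"]), float(r["maxy"])),
            parcel_id=str(r["parcel_id"]) or None,
            confidence=None if r["confidence"] == "" else float(r["confidence"]),
        )
        for _, r in df.iterrows()
    ]


PARCEL_CSV_COLUMNS = ["parcel_id", "number", "county", "zip_code", "owner_name",
                      "minx", "miny", "maxx", "maxy"]


def write_parcels_csv(
    parcels: Sequence[Parcel], path: str | Path, private: bool = True
) -> None:
    rows = []
    for p in parcels:
        bounds = p.geometry.bounds if p.geometry is not None else ("", "", "", "")
        rows.append(
            {
                "parcel_id": p.parcel_id,
                "number": p.number,
                "county": p.county,
                "zip_code": p.zip_code,
                "owner_name": (p.owner_name or "") if private else "",
                "minx": bounds[0], "miny": bounds[1],
                "maxx": bounds[2], "maxy": bounds[3],
            }
        )
    _to_csv_lossless(pd.DataFrame(rows, columns=PARCEL_CSV_COLUMNS), path)


def read_parcels_csv(path: str | Path) -> list[Parcel]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    missing = [c for c in PARCEL_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"parcels CSV missing column(s): {missing}")
    out = []
    for _, r in df.iterrows():
        geom = None
        if r["minx"] != "":
            geom = box(float(r["minx"]), float(r["miny"]),
                       float(r["maxx"]), float(r["maxy"]))
        out.append(
            Parcel(
                parcel_id=r["parcel_id"],
                number=r["number"],
                county=r["county"],
                zip_code=r["zip_code"],
                owner_name=r["owner_name"] or None,
                geometry=geom,
            )
        )
    return out


STRATA_CSV_COLUMNS = ["stratum_id", "category", "county_cluster", "N", "n", "x"]


def write_strata_csv(strata: Sequence[Stratum], path: str | Path) -> None:
    rows = []
    for s in strata:
        cluster = s.stratum_id.rsplit("/", 1)[-1]
        rows.append(
            {
                "stratum_id": s.stratum_id,
                "category": s.category,
                "county_cluster": cluster,
                "N": s.total,
                "n": s.labeled,
                "x": s.positives,
            }
        )
    pd.DataFrame(rows, columns=STRATA_CSV_COLUMNS).to_csv(path, index=False)


def read_strata_csv(path: str | Path) -> list[Stratum]:
    df = pd.read_csv(path)
    missing = [c for c in STRATA_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"strata CSV missing column(s): {missing}")
    return [
        Stratum(
            stratum_id=str(r["stratum_id"]),
            category=str(r["category"]),
            total=int(r["N"]),
            labeled=int(r["n"]),
            positives=int(r["x"]),
        )
        for _, r in df.iterrows()
    ]
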