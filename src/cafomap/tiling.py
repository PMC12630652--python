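"""Survey-frame construction: tiling, urban masking, and stratification.

The study region is cut into ~1 km² square tiles with half-open extents
(so the grid is a partition), urban areas are masked out and tiles more
than 70% masked are dropped from the frame, tiles straddling county
boundaries are duplicated per county, and tiles outside the human review
set are stratified by detection category × county cluster for the
completeness survey.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

__all__ = [
    "Tile",
    "Detection",
    "StratumDesign",
    "make_tile_grid",
    "apply_urban_mask",
    "duplicate_boundary_tiles",
    "assign_detections",
    "select_review_set",
    "stratify_tiles",
]

DEFAULT_TILE_SIZE_M = 1000.0
DEFAULT_MASK_THRESHOLD = 0.70
DEFAULT_CONFIDENCE_THRESHOLD = 0.5


@dataclass(frozen=True)
class Detection:
    """A model detection: a point (building-box center) with confidence."""

    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("detection confidence must lie in [0, 1]")


@dataclass(frozen=True)
class Tile:
    """A square survey cell with half-open extent [x0,x0+s) × [y0,y0+s)."""

    tile_id: str
    x0: float
    y0: float
    size: float
    geometry: Polygon          # possibly clipped to the region / county
    county_id: str | None = None
    mask_fraction: float = 0.0
    max_confidence: float | None = None
    stratum_id: str | None = None
    row: int = 0
    col: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mask_fraction <= 1.0:
            raise ValueError(f"tile {self.tile_id}: mask_fraction outside [0,1]")

    def contains_point(self, x: float, y: float) -> bool:
        return (
            self.x0 <= x < self.x0 + self.size
            and self.y0 <= y < self.y0 + self.size
        )


@dataclass(frozen=True)
class StratumDesign:
    """A survey cell: detection category × county cluster."""

    category: str              # "no_detection" | "low_confidence"
    county_cluster_id: int

    def __post_init__(self) -> None:
        if self.category not in ("no_detection", "low_confidence"):
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def stratum_id(self) -> str:
        return f"{self.category}/{self.county_cluster_id}"


def make_tile_grid(region: Polygon, tile_size_m: float = DEFAULT_TILE_SIZE_M) -> list[Tile]:
    """Tile the region's bounding box into half-open squares.

    Boundary tiles are clipped to the bounding box, so the tiles' areas sum
    exactly to the region bounding-box area and no point belongs to two
    tiles.
    """
    if tile_size_m <= 0:
        raise ValueError("tile size must be positive")
    if region.is_empty:
        raise ValueError("region is empty")
    minx, miny, maxx, maxy = region.bounds
    ncols = math.ceil((maxx - minx) / tile_size_m)
    nrows = math.ceil((maxy - miny) / tile_size_m)
    tiles = []
    for r in range(nrows):
        for c in range(ncols):
            x0 = minx + c * tile_size_m
            y0 = miny + r * tile_size_m
            x1 = min(x0 + tile_size_m, maxx)
            y1 = min(y0 + tile_size_m, maxy)
            tiles.append(
                Tile(
                    tile_id=f"T{r:04d}_{c:04d}",
                    x0=x0,
                    y0=y0,
                    size=tile_size_m,
                    geometry=box(x0, y0, x1, y1),
                    row=r,
                    col=c,
                )
            )
    return tiles


def apply_urban_mask(
    tiles: Sequence[Tile],
    urban_polygons: Iterable[Polygon],
    threshold: float = DEFAULT_MASK_THRESHOLD,
) -> list[Tile]:
    """Compute each tile's masked fraction; drop tiles above the threshold.

    The mask fraction is the urban-intersection area divided by the tile's
    (clipped) area.
    """
    polys = list(urban_polygons)
    for p in polys:
        if not p.is_valid:
            raise ValueError("invalid urban mask geometry")
    mask = unary_union(polys) if polys else None
    out = []
    for t in tiles:
        frac = 0.0
        if mask is not None:
            inter = t.geometry.intersection(mask)
            frac = inter.area / t.geometry.area
            frac = min(max(frac, 0.0), 1.0)
        if frac <= threshold:
            out.append(replace(t, mask_fraction=frac))
    return out


def duplicate_boundary_tiles(
    tiles: Sequence[Tile], county_polygons: Mapping[str, Polygon]
) -> list[Tile]:
    """One tile entry per county it intersects, clipped to that county.

    A tile intersecting k counties yields k entries whose geometries
    partition the original tile, so per-county areas sum to the tile area.
    A tile intersecting no county is an error (counties must cover the
    region).
    """
    out = []
    for t in tiles:
        entries = []
        for county_id in sorted(county_polygons):
            inter = t.geometry.intersection(county_polygons[county_id])
            if not inter.is_empty and inter.area > 0:
                entries.append(
                    replace(
                        t,
                        tile_id=f"{t.tile_id}@{county_id}",
                        geometry=inter,
                        county_id=county_id,
                    )
                )
        if not entries:
            raise ValueError(f"tile {t.tile_id} intersects no county")
        out.extend(entries)
    return out


def assign_detections(
    tiles: Sequence[Tile], detections: Sequence[Detection]
) -> list[Tile]:
    """Attach to each tile the maximum confidence of detections it contains.

    Membership uses the half-open square extent (a detection on a shared
    edge belongs to exactly one un-duplicated tile); for county-duplicated
    tiles the clipped geometry must also contain the point.
    """
    out = []
    for t in tiles:
        confs = [
            d.confidence
            for d in detections
            if t.contains_point(d.x, d.y)
            and (t.county_id is None or t.geometry.buffer(1e-9).covers(Point(d.x, d.y)))
        ]
        out.append(replace(t, max_confidence=max(confs) if confs else None))
    return out


def _neighbors(row: int, col: int) -> list[tuple[int, int]]:
    return [
        (row + dr, col + dc)
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if (dr, dc) != (0, 0)
    ]


def select_review_set(
    tiles: Sequence[Tile],
    permit_points: Sequence[Point],
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    confirmed_positive_fn: Callable[[Tile], bool] | None = None,
) -> list[Tile]:
    """The human-review tile set: seeds plus the adjacency closure.

    Seeds are tiles containing a known permit point or a detection with
    confidence at or above the threshold (``max_confidence`` must already
    be assigned).  Every 8-neighbor (edge or corner contact) of a tile
    confirmed positive is added, iterating until no new tile joins —
    chains of positive facilities spanning many tiles are fully captured.

    ``confirmed_positive_fn`` maps a tile to the human label it would
    receive; when omitted, no expansion beyond the seeds occurs.
    """
    by_cell: dict[tuple[int, int], list[Tile]] = {}
    for t in tiles:
        by_cell.setdefault((t.row, t.col), []).append(t)

    selected: dict[str, Tile] = {}
    frontier: list[Tile] = []
    for t in tiles:
        has_permit = any(t.contains_point(p.x, p.y) for p in permit_points)
        high_conf = (
            t.max_confidence is not None
            and t.max_confidence >= confidence_threshold
        )
        if has_permit or high_conf:
            selected[t.tile_id] = t
            frontier.append(t)

    if confirmed_positive_fn is not None:
        while frontier:
            nxt: list[Tile] = []
            for t in frontier:
                if not confirmed_positive_fn(t):
                    continue
                for cell in _neighbors(t.row, t.col):
                    for nb in by_cell.get(cell, []):
                        if nb.tile_id not in selected:
                            selected[nb.tile_id] = nb
                            nxt.append(nb)
            frontier = nxt
    return sorted(selected.values(), key=lambda t: t.tile_id)


def stratify_tiles(
    tiles: Sequence[Tile],
    county_clusters: Mapping[str, int],
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> list[Tile]:
    """Assign unreviewed tiles to (category × county cluster) strata.

    Tiles with any detection below the threshold are ``low_confidence``;
    tiles with no detection at all are ``no_detection``.  A tile carrying a
    detection at or above the threshold belongs to the review set and must
    not be passed here.
    """
    out = []
    for t in tiles:
        if t.max_confidence is not None and t.max_confidence >= confidence_threshold:
            raise ValueError(
                f"tile {t.tile_id} has a high-confidence detection; "
                "it belongs to the review set, not a stratum"
            )
        if t.county_id is None or t.county_id not in county_clusters:
            raise ValueError(f"tile {t.tile_id}: county not in any cluster")
        category = "no_detection" if t.max_confidence is None else "low_confidence"
        design = StratumDesign(category, county_clusters[t.county_id])
        out.append(replace(t, stratum_id=design.stratum_id))
    return out
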