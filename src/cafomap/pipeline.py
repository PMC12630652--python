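"""End-to-end survey pipeline over a synthetic landscape.

Chains the stages: cluster buildings into facilities, derive attributes,
link permits, select the human-review tile set (permit seeds +
high-confidence detections + adjacency closure), stratify the remaining
tiles, simulate stratified labeling against ground truth, and estimate the
total facility population with the stratified exact-binomial interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import (
    ClusterThresholds,
    Facility,
    cluster_buildings,
    derive_facility_attributes,
)
from .completeness import Stratum, estimate_population, images_per_facility_ratio
from .permits import MatchResult, match_permits
from .synthetic import Landscape
from .tiling import Tile, select_review_set, stratify_tiles

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    facilities: list[Facility]
    matches: MatchResult
    review_tiles: list[Tile]
    strata: list[Stratum]
    observed_facility_ids: set[str]
    images_per_facility: float
    report: dict
    building_to_facility: dict[str, str] = field(default_factory=dict)


def _facility_tiles(
    facility: Facility, buildings_by_id: dict, tiles: list[Tile]
) -> set[str]:
    """Tile ids (county-duplicated frame) touched by the facility's buildings."""
    out = set()
    for bid in facility.building_ids:
        c = buildings_by_id[bid].footprint.centroid
        for t in tiles:
            if t.contains_point(c.x, c.y) and t.geometry.buffer(1e-9).covers(c):
                out.add(t.tile_id)
                break
    return out


def run_pipeline(
    landscape: Landscape,
    label_fraction: float = 0.10,
    alpha: float = 0.05,
    thresholds: ClusterThresholds = ClusterThresholds(),
    seed: int = 0,
) -> PipelineResult:
    """Run cluster → match → survey → estimate on a generated landscape.

    ``label_fraction`` is the share of each stratum's tiles that gets a
    human label in the completeness survey; facilities surfacing on a
    sampled positive tile join the observed set, exactly as review-stage
    finds do.
    """
    truth = landscape.ground_truth
    buildings_by_id = {b.building_id: b for b in landscape.buildings}
    parcels_by_id = {p.parcel_id: p for p in landscape.parcels}

    facilities = cluster_buildings(landscape.buildings, parcels_by_id, thresholds)
    admin = {"county": landscape.county_polygons}
    for fac in facilities:
        derive_facility_attributes(
            fac, buildings_by_id, admin_polygons=admin,
            parcels=parcels_by_id, seed=seed,
        )
    matches = match_permits(
        facilities, landscape.permits, parcel_geoms=landscape.parcel_geoms
    )

    permit_points = [p for perm in landscape.permits for p in perm.points]
    review = select_review_set(
        landscape.tiles,
        permit_points,
        confirmed_positive_fn=lambda t: t.tile_id in truth.true_positive_tiles,
    )
    review_ids = {t.tile_id for t in review}

    fac_tiles = {
        f.facility_id: _facility_tiles(f, buildings_by_id, landscape.tiles)
        for f in facilities
    }
    observed = {
        fid for fid, tids in fac_tiles.items() if tids & review_ids
    }

    # Stratify the unreviewed frame and draw the labeling sample.
    rng = np.random.default_rng(seed)
    unreviewed = [t for t in landscape.tiles if t.tile_id not in review_ids]
    stratified = stratify_tiles(unreviewed, landscape.county_clusters)
    by_stratum: dict[str, list[Tile]] = {}
    for t in stratified:
        by_stratum.setdefault(t.stratum_id, []).append(t)

    strata: list[Stratum] = []
    sampled_positive_tiles: set[str] = set()
    for sid in sorted(by_stratum):
        tiles = sorted(by_stratum[sid], key=lambda t: t.tile_id)
        n_total = len(tiles)
        n_label = min(n_total, max(1, int(round(label_fraction * n_total))))
        idx = rng.choice(n_total, size=n_label, replace=False)
        sampled = [tiles[i] for i in idx]
        pos = [t for t in sampled if t.tile_id in truth.true_positive_tiles]
        sampled_positive_tiles.update(t.tile_id for t in pos)
        strata.append(
            Stratum(
                stratum_id=sid,
                category=sid.split("/")[0],
                total=n_total,
                labeled=n_label,
                positives=len(pos),
            )
        )

    # Facilities surfaced by the survey sample join the observed set.
    for fid, tids in fac_tiles.items():
        if tids & sampled_positive_tiles:
            observed.add(fid)

    # Images-per-facility ratio among labeled positive tiles.
    labeled_positive = (review_ids | sampled_positive_tiles) & {
        t.tile_id for t in landscape.tiles if t.tile_id in truth.true_positive_tiles
    }
    facs_on_positive = {
        fid for fid in observed if fac_tiles[fid] & labeled_positive
    }
    if facs_on_positive:
        ratio = images_per_facility_ratio(
            len(labeled_positive), len(facs_on_positive)
        )
    else:
        ratio = 1.0

    report = estimate_population(
        strata,
        observed_facilities=len(observed),
        images_per_facility=ratio,
        alpha=alpha,
    )
    report["true_facility_count"] = truth.true_facility_count
    report["observed_facility_count"] = len(observed)

    b2f = {
        bid: fid for fid, fac in
        ((f.facility_id, f) for f in facilities)
        for bid in fac.building_ids
    }
    return PipelineResult(
        facilities=facilities,
        matches=matches,
        review_tiles=review,
        strata=strata,
        observed_facility_ids=observed,
        images_per_facility=ratio,
        report=report,
        building_to_facility=b2f,
    )
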