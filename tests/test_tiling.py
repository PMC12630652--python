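"""Tile grid, urban masking, county duplication, review set, stratification."""

import pytest
from shapely.geometry import Point, Polygon, box

from cafomap import (
    Detection,
    StratumDesign,
    apply_urban_mask,
    assign_detections,
    duplicate_boundary_tiles,
    make_tile_grid,
    select_review_set,
    stratify_tiles,
)


class TestTileGrid:
    def test_exact_division(self):
        tiles = make_tile_grid(box(0, 0, 3000, 2000), 1000)
        assert len(tiles) == 6
        assert sum(t.geometry.area for t in tiles) == pytest.approx(6e6)

    def test_partial_column_clipped(self):
        tiles = make_tile_grid(box(0, 0, 2500, 1000), 1000)
        assert len(tiles) == 3
        assert sum(t.geometry.area for t in tiles) == pytest.approx(2500 * 1000)

    def test_half_open_extents_partition(self):
        tiles = make_tile_grid(box(0, 0, 2000, 2000), 1000)
        for x, y in [(1000.0, 500.0), (0.0, 0.0), (999.999, 1000.0)]:
            owners = [t for t in tiles if t.contains_point(x, y)]
            assert len(owners) == 1

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            make_tile_grid(Polygon(), 1000)

    def test_non_positive_tile_size_rejected(self):
        with pytest.raises(ValueError):
            make_tile_grid(box(0, 0, 1000, 1000), 0)


class TestUrbanMask:
    def test_no_polygons_keeps_everything(self):
        tiles = make_tile_grid(box(0, 0, 2000, 1000), 1000)
        kept = apply_urban_mask(tiles, [])
        assert len(kept) == 2 and all(t.mask_fraction == 0.0 for t in kept)

    def test_fully_urban_tile_dropped(self):
        tiles = make_tile_grid(box(0, 0, 2000, 1000), 1000)
        kept = apply_urban_mask(tiles, [box(-10, -10, 1010, 1010)])
        assert [t.tile_id for t in kept] == ["T0000_0001"]

    def test_half_covered_tile_retained_with_fraction(self):
        tiles = make_tile_grid(box(0, 0, 1000, 1000), 1000)
        kept = apply_urban_mask(tiles, [box(0, 0, 500, 1000)])
        assert len(kept) == 1
        assert kept[0].mask_fraction == pytest.approx(0.5)

    def test_threshold_is_inclusive(self):
        tiles = make_tile_grid(box(0, 0, 1000, 1000), 1000)
        at_threshold = apply_urban_mask(tiles, [box(0, 0, 700, 1000)])
        above = apply_urban_mask(tiles, [box(0, 0, 701, 1000)])
        assert len(at_threshold) == 1 and len(above) == 0


class TestCountyDuplication:
    def test_interior_tile_single_entry(self):
        tiles = make_tile_grid(box(0, 0, 1000, 1000), 1000)
        out = duplicate_boundary_tiles(tiles, {"A": box(-1, -1, 2000, 2000)})
        assert len(out) == 1 and out[0].county_id == "A"

    def test_straddling_tile_duplicated_with_area_conserved(self):
        tiles = make_tile_grid(box(0, 0, 1000, 1000), 1000)
        counties = {"A": box(0, 0, 600, 1000), "B": box(600, 0, 1000, 1000)}
        out = duplicate_boundary_tiles(tiles, counties)
        assert len(out) == 2
        assert sum(t.geometry.area for t in out) == pytest.approx(1e6)

    def test_uncovered_tile_is_an_error(self):
        tiles = make_tile_grid(box(0, 0, 1000, 1000), 1000)
        with pytest.raises(ValueError):
            duplicate_boundary_tiles(tiles, {"A": box(5000, 5000, 6000, 6000)})


def grid_with_detections(detections, size=3):
    tiles = make_tile_grid(box(0, 0, size * 1000, size * 1000), 1000)
    return assign_detections(tiles, detections)


class TestReviewSet:
    def test_empty_without_seeds(self):
        tiles = grid_with_detections([])
        assert select_review_set(tiles, []) == []

    def test_high_confidence_detection_seeds(self):
        tiles = grid_with_detections([Detection(1500, 1500, 0.9)])
        out = select_review_set(tiles, [])
        assert [t.tile_id for t in out] == ["T0001_0001"]

    def test_threshold_is_inclusive_at_half(self):
        tiles = grid_with_detections([Detection(1500, 1500, 0.5)])
        assert len(select_review_set(tiles, [])) == 1

    def test_permit_point_seeds(self):
        tiles = grid_with_detections([])
        out = select_review_set(tiles, [Point(500, 2500)])
        assert [t.tile_id for t in out] == ["T0002_0000"]

    def test_confirmed_positive_pulls_in_eight_neighbors(self):
        tiles = grid_with_detections([Detection(1500, 1500, 0.9)])
        out = select_review_set(
            tiles, [], confirmed_positive_fn=lambda t: t.tile_id == "T0001_0001"
        )
        assert len(out) == 9  # whole 3x3 grid after one round

    def test_chain_closure_to_fixpoint(self):
        # positives in a horizontal chain across a 7x3 grid, one seed
        positives = {f"T0001_{c:04d}" for c in range(5)}
        tiles = grid_with_detections([Detection(500, 1500, 0.9)], size=7)
        tiles = [t for t in tiles if t.row < 3]
        out = select_review_set(
            tiles, [], confirmed_positive_fn=lambda t: t.tile_id in positives
        )
        ids = {t.tile_id for t in out}
        assert positives <= ids
        # neighbors of the far end of the chain are reached
        assert "T0000_0005" in ids and "T0002_0005" in ids

    def test_monotone_in_detections(self):
        base = grid_with_detections([Detection(500, 500, 0.8)])
        more = grid_with_detections(
            [Detection(500, 500, 0.8), Detection(2500, 2500, 0.7)]
        )
        out_base = {t.tile_id for t in select_review_set(base, [])}
        out_more = {t.tile_id for t in select_review_set(more, [])}
        assert out_base <= out_more


class TestStratification:
    def test_low_confidence_category(self):
        tiles = grid_with_detections([Detection(500, 500, 0.3)], size=1)
        tiles = [t.__class__(**{**t.__dict__, "county_id": "A"}) for t in tiles]
        out = stratify_tiles(tiles, {"A": 1})
        assert out[0].stratum_id == "low_confidence/1"

    def test_no_detection_category(self):
        tiles = grid_with_detections([], size=1)
        tiles = [t.__class__(**{**t.__dict__, "county_id": "A"}) for t in tiles]
        out = stratify_tiles(tiles, {"A": 1})
        assert out[0].stratum_id == "no_detection/1"

    def test_high_confidence_tile_rejected(self):
        tiles = grid_with_detections([Detection(500, 500, 0.5)], size=1)
        tiles = [t.__class__(**{**t.__dict__, "county_id": "A"}) for t in tiles]
        with pytest.raises(ValueError, match="review set"):
            stratify_tiles(tiles, {"A": 1})

    def test_unknown_county_rejected(self):
        tiles = grid_with_detections([], size=1)
        with pytest.raises(ValueError, match="county"):
            stratify_tiles(tiles, {"A": 1})

    def test_twenty_six_strata_design(self):
        designs = [
            StratumDesign(cat, k)
            for cat in ("no_detection", "low_confidence")
            for k in range(1, 14)
        ]
        assert len({d.stratum_id for d in designs}) == 26

    def test_review_and_strata_partition_frame(self, quiet_landscape):
        truth = quiet_landscape.ground_truth
        permit_points = [p for perm in quiet_landscape.permits for p in perm.points]
        review = select_review_set(
            quiet_landscape.tiles,
            permit_points,
            confirmed_positive_fn=lambda t: t.tile_id in truth.true_positive_tiles,
        )
        review_ids = {t.tile_id for t in review}
        rest = [t for t in quiet_landscape.tiles if t.tile_id not in review_ids]
        stratified = stratify_tiles(rest, quiet_landscape.county_clusters)
        assert len(review) + len(stratified) == len(quiet_landscape.tiles)
        assert all(t.stratum_id is not None for t in stratified)
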