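"""Building relatedness rules, facility partitioning, attribute derivation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import box
from sklearn.metrics import adjusted_rand_score

from cafomap import (
    Building,
    ClusterThresholds,
    Parcel,
    building_distance,
    cluster_buildings,
    derive_facility_attributes,
    owner_similarity,
    related,
)
from cafomap.clustering import normalize_owner_name


def bld(bid, x0, y0, w=1.0, h=1.0, parcel=None, conf=None):
    return Building(bid, box(x0, y0, x0 + w, y0 + h), parcel_id=parcel, confidence=conf)


def parcel_map(*pairs):
    return {
        pid: Parcel(pid, f"APN-{pid}", "C00", "90000", owner_name=owner)
        for pid, owner in pairs
    }


class TestBuildingDistance:
    def test_identical_boxes(self):
        assert building_distance(bld("a", 0, 0), bld("b", 0, 0)) == 0.0

    def test_axis_gap(self):
        assert building_distance(bld("a", 0, 0), bld("b", 4, 0)) == pytest.approx(3.0)

    def test_diagonal_gap_is_euclidean(self):
        a = bld("a", 0, 0)
        b = Building("b", box(4, 5, 6, 7))
        assert building_distance(a, b) == pytest.approx(5.0)  # sqrt(3^2+4^2)

    def test_overlapping_boxes(self):
        assert building_distance(bld("a", 0, 0, 2, 2), bld("b", 1, 1)) == 0.0


class TestOwnerSimilarity:
    def test_punctuation_case_and_suffix_invariance(self):
        assert owner_similarity("SMITH DAIRY LLC", "Smith Dairy, L.L.C.") == 1.0
        assert owner_similarity("SMITH DAIRY LLC", "Smith Dairy") == 1.0

    def test_disjoint_names_score_low(self):
        assert owner_similarity("SMITH DAIRY", "JONES POULTRY") < 0.5

    def test_normalization(self):
        assert normalize_owner_name("  Smith   Dairy, L.L.C. ") == "smith dairy l l c"

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.text(alphabet="abcdefg XYZ.", min_size=1, max_size=20),
        st.text(alphabet="abcdefg XYZ.", min_size=1, max_size=20),
    )
    def test_symmetric(self, a, b):
        if not normalize_owner_name(a) or not normalize_owner_name(b):
            return
        assert owner_similarity(a, b) == pytest.approx(owner_similarity(b, a))

    def test_empty_after_normalization_rejected(self):
        with pytest.raises(ValueError):
            owner_similarity("...", "Smith")


class TestRelatednessRules:
    def test_same_parcel_unbounded_distance(self):
        parcels = parcel_map(("p1", "SMITH DAIRY"))
        a = bld("a", 0, 0, parcel="p1")
        b = bld("b", 10_000, 0, parcel="p1")
        assert related(a, b, parcels)

    def test_similar_owners_within_400m(self):
        parcels = parcel_map(("p1", "Smith Dairy LLC"), ("p2", "Smith Dairy"))
        a = bld("a", 0, 0, parcel="p1")
        assert related(a, bld("b", 300, 0, parcel="p2"), parcels)
        assert not related(a, bld("c", 450, 0, parcel="p2"), parcels)

    def test_dissimilar_owners_not_related(self):
        parcels = parcel_map(("p1", "Smith Dairy"), ("p2", "Jones Poultry"))
        assert not related(
            bld("a", 0, 0, parcel="p1"), bld("b", 100, 0, parcel="p2"), parcels
        )

    def test_missing_parcel_within_200m_boundary(self):
        parcels = parcel_map(("p1", "Smith Dairy"))
        a = bld("a", 0, 0, parcel="p1")
        assert related(a, bld("b", 151, 0), parcels)       # gap 150 m
        assert not related(a, bld("c", 251, 0), parcels)   # gap 250 m

    def test_lone_building_rule_second_pass(self):
        parcels = parcel_map(("p1", "Smith Dairy"), ("p2", "Jones Poultry"))
        a = bld("a", 0, 0, parcel="p1")
        b = bld("b", 41, 0, parcel="p2")  # 40 m gap, dissimilar owners
        assert not related(a, b, parcels)  # rules 1-3 alone
        facilities = cluster_buildings([a, b], parcels)
        assert len(facilities) == 1  # both lone -> rule 4 joins them


class TestClusterPartition:
    def test_isolated_buildings_become_singletons(self):
        parcels = parcel_map(*[(f"p{i}", f"OWNER {'X'*(i+1)} RANCH") for i in range(5)])
        buildings = [bld(f"b{i}", i * 2_000, 0, parcel=f"p{i}") for i in range(5)]
        facilities = cluster_buildings(buildings, parcels)
        assert [f.n_buildings for f in facilities] == [1] * 5

    def test_chain_merges_transitively(self):
        parcels = parcel_map(("p1", "Smith Dairy"), ("p2", "Smith Dairy LLC"),
                             ("p3", "Smith Dairy Inc"))
        a = bld("a", 0, 0, parcel="p1")
        b = bld("b", 350, 0, parcel="p2")
        c = bld("c", 700, 0, parcel="p3")  # a-c 699 m apart: unrelated directly
        assert not related(a, c, parcels)
        facilities = cluster_buildings([a, b, c], parcels)
        assert len(facilities) == 1
        assert facilities[0].building_ids == ["a", "b", "c"]

    def test_partition_covers_every_building_once(self, noisy_landscape):
        parcels = {p.parcel_id: p for p in noisy_landscape.parcels}
        facilities = cluster_buildings(noisy_landscape.buildings, parcels)
        seen = [bid for f in facilities for bid in f.building_ids]
        assert sorted(seen) == sorted(b.building_id for b in noisy_landscape.buildings)

    def test_order_invariance(self, noisy_landscape):
        parcels = {p.parcel_id: p for p in noisy_landscape.parcels}
        base = cluster_buildings(noisy_landscape.buildings, parcels)
        rng = np.random.default_rng(0)
        perm = list(noisy_landscape.buildings)
        rng.shuffle(perm)
        shuffled = cluster_buildings(perm, parcels)
        as_sets = lambda fs: {frozenset(f.building_ids) for f in fs}
        assert as_sets(base) == as_sets(shuffled)

    def test_threshold_monotonicity(self, noisy_landscape):
        parcels = {p.parcel_id: p for p in noisy_landscape.parcels}
        counts = []
        for d in (100.0, 400.0, 800.0):
            t = ClusterThresholds(owner_match_m=d)
            counts.append(len(cluster_buildings(noisy_landscape.buildings, parcels, t)))
        assert counts[0] >= counts[1] >= counts[2]

    def test_zero_noise_recovers_ground_truth(self, quiet_landscape):
        parcels = {p.parcel_id: p for p in quiet_landscape.parcels}
        facilities = cluster_buildings(quiet_landscape.buildings, parcels)
        truth = quiet_landscape.ground_truth.facility_assignment
        order = sorted(truth)
        pred, true = [], []
        lookup = {bid: f.facility_id for f in facilities for bid in f.building_ids}
        for bid in order:
            pred.append(lookup[bid])
            true.append(truth[bid])
        assert adjusted_rand_score(true, pred) == 1.0
        assert len(facilities) == quiet_landscape.ground_truth.true_facility_count

    def test_duplicate_building_ids_rejected(self):
        with pytest.raises(ValueError):
            cluster_buildings([bld("a", 0, 0), bld("a", 10, 0)], {})


class TestFacilityAttributes:
    def test_single_square_building(self):
        b = Building("a", box(0, 0, 10, 10))
        facilities = cluster_buildings([b], {})
        fac = derive_facility_attributes(facilities[0], {"a": b})
        assert fac.centroid.x == pytest.approx(5.0)
        assert fac.bbox == (0.0, 0.0, 10.0, 10.0)
        assert fac.footprint_sq_m == pytest.approx(100.0)

    def test_county_by_plurality(self):
        buildings = {b.building_id: b for b in
                     [bld("a", 0, 0), bld("b", 30, 0), bld("c", 120, 0)]}
        admin = {"county": {"X": box(-10, -10, 100, 100), "Y": box(100, -10, 300, 100)}}
        facilities = cluster_buildings(list(buildings.values()), {})
        fac = derive_facility_attributes(facilities[0], buildings, admin_polygons=admin)
        assert fac.county == "X"

    def test_tie_break_is_seeded_and_stable(self):
        buildings = {b.building_id: b for b in [bld("a", 0, 0), bld("b", 120, 0)]}
        admin = {"census_blockgroup": {"B1": box(-10, -10, 100, 100),
                                       "B2": box(100, -10, 300, 100)}}
        facilities = cluster_buildings(list(buildings.values()), {})
        picks = {
            derive_facility_attributes(
                cluster_buildings(list(buildings.values()), {})[0],
                buildings, admin_polygons=admin, seed=s,
            ).census_blockgroup
            for _ in range(3)
            for s in (7,)
        }
        assert len(picks) == 1  # same seed, same choice, every run

    def test_uncovered_centroids_flagged(self):
        buildings = {"a": bld("a", 0, 0)}
        admin = {"county": {"X": box(500, 500, 600, 600)}}
        facilities = cluster_buildings(list(buildings.values()), {})
        fac = derive_facility_attributes(facilities[0], buildings, admin_polygons=admin)
        assert fac.county is None and fac.admin_unresolved

    def test_missing_parcel_flags_incomplete(self):
        facilities = cluster_buildings([bld("a", 0, 0)], {})
        assert facilities[0].incomplete_parcel_info
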