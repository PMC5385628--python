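"""Range processing: name matching, level resolution, merging,
covariates, occupancy and point validation."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from legrange.geo import KM_PER_DEGREE
from legrange.ranges import (
    CovariateError,
    Gazetteer,
    GeometryError,
    MappingError,
    MatchedRecord,
    RegionPolygon,
    SpeciesRange,
    UnmatchedRecordError,
    build_occupancy,
    build_species_range,
    dispersion,
    match_name,
    merge_contiguous,
    point_validation,
    range_covariates,
    resolve_levels,
)


def rec(species="s1", name="Northland", level="region", parent="Continent 0", status="native"):
    return {
        "species_id": species,
        "unit_name": name,
        "level": level,
        "parent_name": parent,
        "status": status,
    }


class TestMatchName:
    def test_exact_match(self, toy_gazetteer):
        m = match_name(rec(name="Northland West", level="area", parent="Northland"), toy_gazetteer)
        assert m.unit.id == "r0a0"
        assert not m.promoted

    def test_promotion_one_level_up(self, toy_gazetteer):
        # area name unknown -> falls back to its region
        m = match_name(rec(name="Northland Highlands", level="area", parent="Northland"), toy_gazetteer)
        assert m.unit.id == "r0"
        assert m.promoted

    def test_unmatched_raises_with_name(self, toy_gazetteer):
        with pytest.raises(UnmatchedRecordError, match="Atlantis"):
            match_name(rec(name="Atlantis", level="area", parent="Midland"), toy_gazetteer)

    def test_exhaustive_toy_gazetteer(self, toy_gazetteer):
        # every (level, name) combination either matches, promotes, or errors
        outcomes = {}
        for level, name, parent in [
            ("region", "Northland", "Continent 0"),
            ("region", "Southland", "Continent 0"),
            ("area", "Northland West", "Northland"),
            ("area", "Southland East", "Southland"),
            ("area", "Nowhere", "Nowhere"),
        ]:
            try:
                m = match_name(rec(name=name, level=level, parent=parent), toy_gazetteer)
                outcomes[name] = "promoted" if m.promoted else "exact"
            except UnmatchedRecordError:
                outcomes[name] = "error"
        assert outcomes == {
            "Northland": "exact",
            "Southland": "exact",
            "Northland West": "exact",
            "Southland East": "promoted",
            "Nowhere": "error",
        }


class TestResolveLevels:
    def test_nested_keeps_deepest(self, toy_gazetteer):
        matched = [
            MatchedRecord("s1", toy_gazetteer.by_id("r0"), "native"),
            MatchedRecord("s1", toy_gazetteer.by_id("r0a0"), "native"),
        ]
        out = resolve_levels(matched, toy_gazetteer)
        assert [m.unit.id for m in out] == ["r0a0"]

    def test_unknown_only_species_dropped(self, toy_gazetteer):
        matched = [
            MatchedRecord("s1", toy_gazetteer.by_id("r0"), "unknown"),
            MatchedRecord("s2", toy_gazetteer.by_id("r1"), "native"),
        ]
        out = resolve_levels(matched, toy_gazetteer)
        assert {m.species_id for m in out} == {"s2"}

    def test_single_record_unchanged(self, toy_gazetteer):
        matched = [MatchedRecord("s1", toy_gazetteer.by_id("r1"), "introduced")]
        assert resolve_levels(matched, toy_gazetteer) == matched


class TestMergeContiguous:
    def test_disjoint_same_status_stay_separate(self):
        comps = merge_contiguous(
            [("a", "native", box(0, 0, 1, 1)), ("b", "native", box(5, 0, 6, 1))]
        )
        assert len(comps) == 2

    def test_touching_same_status_merge_with_additive_area(self):
        g1, g2 = box(0, 0, 1, 1), box(1, 0, 2, 1)
        comps = merge_contiguous([("a", "native", g1), ("b", "native", g2)])
        assert len(comps) == 1
        from legrange.geo import spherical_area_km2

        assert comps[0].area_km2 == pytest.approx(
            spherical_area_km2(g1) + spherical_area_km2(g2), rel=1e-9
        )

    def test_touching_different_status_stay_separate(self):
        comps = merge_contiguous(
            [("a", "native", box(0, 0, 1, 1)), ("b", "introduced", box(1, 0, 2, 1))]
        )
        assert len(comps) == 2

    def test_unknown_status_excluded(self):
        comps = merge_contiguous(
            [("a", "native", box(0, 0, 1, 1)), ("b", "unknown", box(1, 0, 2, 1))]
        )
        assert len(comps) == 1

    def test_idempotent(self):
        polys = [
            ("a", "native", box(0, 0, 1, 1)),
            ("b", "native", box(1, 0, 2, 1)),
            ("c", "introduced", box(10, 0, 11, 1)),
        ]
        once = merge_contiguous(polys)
        again = merge_contiguous(
            [(",".join(c.member_ids), c.status, c.geometry) for c in once]
        )
        assert len(again) == len(once)
        for c1, c2 in zip(once, again):
            assert c2.area_km2 == pytest.approx(c1.area_km2, rel=1e-9)
            assert c2.centroid == pytest.approx(c1.centroid, rel=1e-9)

    def test_component_count_and_area_bounds(self, rng):
        # random unit cells: n_components <= n_inputs and union area <=
        # sum of areas, equality iff disjoint
        from legrange.geo import spherical_area_km2

        cells = [
            (f"p{k}", "native", box(x, y, x + 1, y + 1))
            for k, (x, y) in enumerate(
                zip(rng.integers(0, 6, 12), rng.integers(0, 6, 12))
            )
        ]
        comps = merge_contiguous(cells)
        assert len(comps) <= len(cells)
        total_in = sum(spherical_area_km2(g) for _, _, g in cells)
        total_out = sum(c.area_km2 for c in comps)
        assert total_out <= total_in + 1e-6

    def test_invalid_geometry_raises(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(GeometryError):
            merge_contiguous([("a", "native", bowtie)])


class TestRangeCovariates:
    def _range(self, comps):
        return SpeciesRange("s1", merge_contiguous(comps))

    def test_abs_latitude_of_single_square(self):
        sr = self._range([("a", "native", box(19.5, -10.5, 20.5, -9.5))])
        out = range_covariates(sr)
        assert out["abs_native_centroid_lat"] == pytest.approx(10.0, abs=1e-6)

    def test_area_weighted_latitude(self):
        # near-equal-area squares at lat 0 and 40 -> abs centroid lat ~ 20
        sr = self._range(
            [("a", "native", box(0, -0.5, 1, 0.5)), ("b", "native", box(0, 39.5, 1, 40.5))]
        )
        out = range_covariates(sr)
        w1 = sr.components[0].area_km2
        w2 = sr.components[1].area_km2
        expected = abs((0.0 * w1 + 40.0 * w2) / (w1 + w2))
        assert out["abs_native_centroid_lat"] == pytest.approx(expected, abs=1e-6)

    def test_total_area_of_two_equatorial_cells(self):
        sr = self._range(
            [("a", "native", box(0, -0.5, 1, 0.5)), ("b", "native", box(5, -0.5, 6, 0.5))]
        )
        out = range_covariates(sr)
        assert out["total_native_area_km2"] == pytest.approx(2 * 111.19**2, rel=0.01)
        assert len(out["per_range_areas_km2"]) == 2

    def test_no_native_range_errors(self):
        sr = self._range([("a", "introduced", box(0, 0, 1, 1))])
        with pytest.raises(CovariateError):
            range_covariates(sr)


class TestDispersion:
    def test_quarter_circle(self):
        sr = SpeciesRange(
            "s1",
            merge_contiguous(
                [
                    ("a", "introduced", box(-0.5, -0.5, 0.5, 0.5)),
                    ("b", "introduced", box(89.5, -0.5, 90.5, 0.5)),
                ]
            ),
        )
        assert dispersion(sr) == pytest.approx(6371.0 * np.pi / 2, rel=1e-4)

    def test_three_centroids_brute_force(self):
        comps = merge_contiguous(
            [
                ("a", "introduced", box(0, 0, 1, 1)),
                ("b", "introduced", box(10, 0, 11, 1)),
                ("c", "introduced", box(0, 20, 1, 21)),
            ]
        )
        sr = SpeciesRange("s1", comps)
        from legrange.geo import haversine_km

        cents = [c.centroid for c in comps]
        pairs = [
            haversine_km(cents[i][0], cents[i][1], cents[j][0], cents[j][1])
            for i in range(3)
            for j in range(i + 1, 3)
        ]
        assert dispersion(sr) == pytest.approx(np.mean(pairs))

    def test_fewer_than_two_ranges_signalled(self):
        sr = SpeciesRange("s1", merge_contiguous([("a", "introduced", box(0, 0, 1, 1))]))
        with pytest.raises(ValueError, match="undefined"):
            dispersion(sr)


class TestBuildOccupancy:
    def test_toy_world_hand_enumeration(self, toy_gazetteer):
        matched = [
            MatchedRecord("s1", toy_gazetteer.by_id("r0"), "native"),
            MatchedRecord("s1", toy_gazetteer.by_id("r1"), "introduced"),
            MatchedRecord("s2", toy_gazetteer.by_id("r0a0"), "introduced"),
            MatchedRecord("s3", toy_gazetteer.by_id("r0"), "native"),
            MatchedRecord("s3", toy_gazetteer.by_id("r1"), "native"),
            MatchedRecord("s4", toy_gazetteer.by_id("r1"), "introduced"),
        ]
        occ = build_occupancy(matched, toy_gazetteer)
        expected = pd.DataFrame(
            [[0, 1], [1, 0], [0, 0], [0, 1]],
            index=["s1", "s2", "s3", "s4"],
            columns=["r0", "r1"],
        )
        pd.testing.assert_frame_equal(occ.Y, expected)
        assert occ.status.loc["s2", "r0"] == "nonnative"  # area rolled up
        assert occ.status.loc["s3", "r0"] == "native"
        assert occ.status.loc["s2", "r1"] == "absent"

    def test_row_sums_count_distinct_regions(self, toy_gazetteer):
        matched = [
            MatchedRecord("s1", toy_gazetteer.by_id("r0a0"), "introduced"),
            MatchedRecord("s1", toy_gazetteer.by_id("r1"), "introduced"),
        ]
        occ = build_occupancy(matched, toy_gazetteer)
        assert occ.Y.loc["s1"].sum() == 2

    def test_no_region_ancestor_errors(self, toy_gazetteer):
        matched = [MatchedRecord("s1", toy_gazetteer.by_id("c0"), "introduced")]
        with pytest.raises(MappingError):
            build_occupancy(matched, toy_gazetteer)


class TestPointValidation:
    def _range(self):
        return build_species_range(
            "s1",
            [
                MatchedRecord(
                    "s1",
                    RegionPolygon("x", "X", "region", None, box(0, 0, 10, 10)),
                    "native",
                )
            ],
        )

    def test_full_coverage(self):
        cov, dists = point_validation([(5.0, 5.0), (0.0, 0.0)], self._range())
        assert cov == 1.0
        assert dists == []

    def test_partial_coverage_fraction(self, rng):
        inside = [(float(a), float(b)) for a, b in rng.uniform(1, 9, (93, 2))]
        outside = [(float(a), float(b)) for a, b in rng.uniform(20, 30, (7, 2))]
        cov, dists = point_validation(inside + outside, self._range())
        assert cov == pytest.approx(0.93)
        assert len(dists) == 7

    def test_outside_distance_haversine(self):
        # a point 1 degree due east of the boundary on the equator
        cov, dists = point_validation([(0.0, 11.0)], self._range())
        assert cov == 0.0
        assert dists[0] == pytest.approx(KM_PER_DEGREE, rel=1e-3)

    def test_empty_points_signalled(self):
        with pytest.raises(ValueError, match="undefined"):
            point_validation([], self._range())
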