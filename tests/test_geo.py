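"""Event preparation: filtering, spatial join, centroids, aggregation."""
import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

import scanwatch as sw
from scanwatch.geo import GeometryError, StructuralError, month_index

# independently derived via the shoelace area-moment formula for the
# L-shape (0,0),(2,0),(2,1),(1,1),(1,2),(0,2): area 3, centroid (5/6, 5/6)
L_SHAPE = Polygon([(0, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2)])
L_CENTROID = (0.8333333333333334, 0.8333333333333334)


class TestFilter:
    def test_register_sized_exclusion_count(self, small_geo):
        """5,106 records with 128 invalid coordinates leave 4,978."""
        rng = np.random.default_rng(0)
        n, n_bad = 5106, 128
        lon = rng.uniform(0, 8, n)
        lat = rng.uniform(0, 8, n)
        valid = np.ones(n, dtype=bool)
        bad = rng.choice(n, size=n_bad, replace=False)
        valid[bad] = False
        events = pd.DataFrame({
            "event_id": [f"E{k}" for k in range(n)],
            "date": "2015-06-15", "age": 40,
            "lat": lat, "lon": lon, "coord_valid": valid,
        })
        kept, n_excluded = sw.filter_events(events, small_geo)
        assert n_excluded == 128
        assert len(kept) == 4978

    def test_all_valid_keeps_everything(self, small_events, small_geo):
        valid = small_events.loc[small_events["coord_valid"]].reset_index(drop=True)
        kept, n_excluded = sw.filter_events(valid, small_geo)
        assert n_excluded == 0
        assert len(kept) == len(valid)

    def test_out_of_extent_coordinates_excluded(self, small_geo):
        events = pd.DataFrame({
            "event_id": ["a", "b"], "date": "2015-01-01", "age": 30,
            "lat": [1.0, 999.0], "lon": [1.0, 999.0],
            "coord_valid": [True, True],
        })
        kept, n_excluded = sw.filter_events(events, small_geo)
        assert len(kept) == 1 and n_excluded == 1

    def test_empty_input(self, small_geo, small_events):
        kept, n_excluded = sw.filter_events(small_events.iloc[0:0], small_geo)
        assert len(kept) == 0 and n_excluded == 0


class TestSpatialJoin:
    def test_grid_join_agrees_with_index_arithmetic(self, small_geo, small_events):
        kept, _ = sw.filter_events(small_events, small_geo)
        joined, unmatched = sw.spatial_join(kept, small_geo, "MB")
        assert len(unmatched) == 0
        ck = small_geo.grid.cell_km
        nx = small_geo.grid.nx
        idx = (np.floor(joined["lat"] / ck).astype(int) * nx
               + np.floor(joined["lon"] / ck).astype(int))
        expect = small_geo.areas("MB")["area_id"].to_numpy()[idx]
        assert (joined["area_MB"].to_numpy() == expect).all()

    def test_centroid_point_maps_to_own_area(self, small_geo):
        mb = small_geo.areas("MB")
        events = pd.DataFrame({
            "event_id": mb["area_id"], "date": "2015-01-01", "age": 30,
            "lat": mb["cy_all"], "lon": mb["cx_all"], "coord_valid": True,
        })
        joined, _ = sw.spatial_join(events, small_geo, "MB")
        assert (joined["area_MB"].to_numpy() == mb["area_id"].to_numpy()).all()

    def test_shared_edge_assigned_deterministically(self, small_geo):
        # a point exactly on the boundary between cell (0,0) and (1,0)
        events = pd.DataFrame({
            "event_id": ["edge"], "date": "2015-01-01", "age": 30,
            "lat": [0.5], "lon": [small_geo.grid.cell_km], "coord_valid": True,
        })
        a, _ = sw.spatial_join(events, small_geo, "MB")
        b, _ = sw.spatial_join(events, small_geo, "MB")
        # half-open convention: the point belongs to the cell whose
        # min-corner it touches
        assert a["area_MB"].iloc[0] == small_geo.areas("MB")["area_id"].iloc[1]
        assert a["area_MB"].iloc[0] == b["area_MB"].iloc[0]

    def test_join_levels_consistent_with_parents(self, small_geo, small_events):
        kept, _ = sw.filter_events(small_events, small_geo)
        mb_joined, _ = sw.spatial_join(kept, small_geo, "MB")
        sa1_joined, _ = sw.spatial_join(kept, small_geo, "SA1")
        parent = small_geo.areas("MB").set_index("area_id")["parent_id"]
        assert (parent.loc[mb_joined["area_MB"]].to_numpy()
                == sa1_joined["area_SA1"].to_numpy()).all()

    def test_polygon_join_matches_grid_join(self, small_geo, small_events):
        """The generic covers-based join agrees with index arithmetic."""
        kept, _ = sw.filter_events(small_events, small_geo)
        grid_joined, _ = sw.spatial_join(kept, small_geo, "MB")
        poly_geo = sw.Geography(small_geo.levels, mode="planar", grid=None)
        poly_joined, unmatched = sw.spatial_join(kept, poly_geo, "MB")
        assert len(unmatched) == 0
        # interior points agree everywhere; boundary points may differ by
        # convention, so compare only events off cell edges
        ck = small_geo.grid.cell_km
        off_edge = (~np.isclose(kept["lon"] % ck, 0)) & (~np.isclose(kept["lat"] % ck, 0))
        a = grid_joined.set_index("event_id")["area_MB"]
        b = poly_joined.set_index("event_id")["area_MB"]
        ids = kept.loc[off_edge, "event_id"]
        assert (a.loc[ids] == b.loc[ids]).all()

    def test_join_idempotent(self, small_geo, small_events):
        kept, _ = sw.filter_events(small_events, small_geo)
        once, _ = sw.spatial_join(kept, small_geo, "MB")
        twice, _ = sw.spatial_join(once, small_geo, "MB")
        pd.testing.assert_frame_equal(once, twice)


class TestCentroids:
    def test_equal_weights_symmetric(self):
        assert sw.weighted_centroid([(0, 0), (2, 0)], [1, 1]) == (1.0, 0.0)

    def test_hand_computed_weighted_mean(self):
        assert sw.weighted_centroid([(0, 0), (4, 0)], [3, 1]) == (1.0, 0.0)

    def test_single_child_identity(self):
        assert sw.weighted_centroid([(2.5, -1.0)], [7]) == (2.5, -1.0)

    def test_zero_weights_fall_back_to_mean(self):
        assert sw.weighted_centroid([(0, 0), (4, 2)], [0, 0]) == (2.0, 1.0)

    def test_no_children_rejected(self):
        with pytest.raises(StructuralError):
            sw.weighted_centroid(np.empty((0, 2)), [])

    def test_geometric_centroid_unit_square(self):
        assert sw.geometric_centroid(box(0, 0, 1, 1)) == (0.5, 0.5)

    def test_geometric_centroid_l_shape_matches_shoelace(self):
        cx, cy = sw.geometric_centroid(L_SHAPE)
        assert cx == pytest.approx(L_CENTROID[0])
        assert cy == pytest.approx(L_CENTROID[1])

    def test_geometric_centroid_rectangle_is_midpoint(self):
        assert sw.geometric_centroid(box(1, 2, 5, 10)) == (3.0, 6.0)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(GeometryError):
            sw.geometric_centroid(Polygon([(0, 0), (1, 1), (2, 2)]))

    def test_parent_centroid_inside_child_hull(self, small_geo):
        mb = small_geo.areas("MB")
        for _, row in small_geo.areas("SA1").iterrows():
            kids = mb.loc[mb["parent_id"] == row["area_id"]]
            assert kids["cx_all"].min() <= row["cx_all"] <= kids["cx_all"].max()
            assert kids["cy_all"].min() <= row["cy_all"] <= kids["cy_all"].max()


class TestAggregation:
    def test_counts_single_cell(self, small_geo):
        events = pd.DataFrame({
            "event_id": ["a", "b", "c"],
            "date": ["2015-03-01", "2015-03-15", "2015-03-31"],
            "age": [30, 40, 50],
            "lat": [0.5] * 3, "lon": [0.5] * 3, "coord_valid": True,
        })
        joined, _ = sw.spatial_join(events, small_geo, "MB")
        series, oor = sw.aggregate_counts(joined, small_geo, "MB", "all", "2015-01", 12)
        assert series.total_C == 3
        assert series.counts[0, 2] == 3
        assert len(oor) == 0

    def test_age_exactly_25_excluded_from_under25(self, small_geo):
        events = pd.DataFrame({
            "event_id": ["a", "b"], "date": "2015-01-10",
            "age": [25, 24],
            "lat": [0.5] * 2, "lon": [0.5] * 2, "coord_valid": True,
        })
        joined, _ = sw.spatial_join(events, small_geo, "MB")
        series, _ = sw.aggregate_counts(joined, small_geo, "MB", "under25", "2015-01", 12)
        assert series.total_C == 1

    def test_out_of_range_reported_not_dropped(self, small_geo):
        events = pd.DataFrame({
            "event_id": ["in", "late"],
            "date": ["2015-06-01", "2030-01-01"], "age": 30,
            "lat": [0.5] * 2, "lon": [0.5] * 2, "coord_valid": True,
        })
        joined, _ = sw.spatial_join(events, small_geo, "MB")
        series, oor = sw.aggregate_counts(joined, small_geo, "MB", "all", "2015-01", 12)
        assert series.total_C == 1
        assert list(oor["event_id"]) == ["late"]

    def test_pipeline_conserves_events(self, small_geo, small_events):
        kept, n_exc = sw.filter_events(small_events, small_geo)
        assert len(kept) + n_exc == len(small_events)
        for level in ("MB", "SA1", "SA2"):
            joined, unmatched = sw.spatial_join(kept, small_geo, level)
            assert len(joined) + len(unmatched) == len(kept)
            series, oor = sw.aggregate_counts(
                joined, small_geo, level, "all", "2015-01", 36
            )
            assert series.total_C + len(oor) == len(joined)

    def test_strata_partition_cases(self, small_geo, small_events):
        kept, _ = sw.filter_events(small_events, small_geo)
        joined, _ = sw.spatial_join(kept, small_geo, "MB")
        s_all, _ = sw.aggregate_counts(joined, small_geo, "MB", "all", "2015-01", 36)
        s_u25, _ = sw.aggregate_counts(joined, small_geo, "MB", "under25", "2015-01", 36)
        n_u25 = (joined["age"] < 25).sum()
        assert s_u25.total_C == n_u25
        assert s_all.total_C == len(joined)

    def test_month_index_anchoring(self):
        m = month_index(["2015-01-31", "2016-12-01", "2022-06-15"], "2015-01")
        assert list(m) == [0, 23, 89]

    def test_slice_months_is_closed_interval(self, small_series):
        sub = small_series.slice_months(12, 35)
        assert sub.n_months == 24
        assert sub.months[0] == 12 and sub.months[-1] == 35
        assert sub.total_C == small_series.counts[:, 12:36].sum()
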