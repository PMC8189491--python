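"""Feature construction: point assignment, normalized counts, smoothing,
land-cover statistics, census passthrough and merging."""

import numpy as np
import pandas as pd
import pytest

import tractprev as tp
from tractprev.errors import (
    AlignmentError,
    InconsistentIndexError,
    InvalidParameterError,
    MissingDataError,
    SchemaError,
)
from tractprev.feature_engineering import (
    FeatureTable,
    NeighborIndex,
    adjacency_features,
    assign_points_to_tracts,
    category_sums,
    census_features,
    landcover_proportions,
    merge_features,
    nearest_neighbors,
    neighbor_smooth,
    normalized_counts,
)
from tractprev.keyword_selection import KeywordSet
from tractprev.synthetic_city import (
    CENSUS_COLUMNS,
    LandCoverRaster,
    QueryLog,
    generate_census,
    generate_tracts,
)


class TestAssignPoints:
    def test_centroids_map_to_own_tract(self, grid_tracts):
        out = assign_points_to_tracts(grid_tracts.centroids, grid_tracts)
        assert out == grid_tracts.ids

    def test_shared_edge_goes_to_lexicographically_smallest(self, grid_tracts):
        # x=2 is the boundary between the first two columns of the 3x3 grid
        out = assign_points_to_tracts([(2.0, 1.0)], grid_tracts)
        candidates = [t.tract_id for t in grid_tracts.tracts
                      if t.polygon.covers(__import__("shapely").geometry.Point(2.0, 1.0))]
        assert len(candidates) >= 2
        assert out[0] == min(candidates)

    def test_outside_point_unassigned(self, grid_tracts):
        assert assign_points_to_tracts([(99.0, 99.0)], grid_tracts) == [None]

    def test_matches_brute_force_scan(self):
        from shapely.geometry import Point
        tracts = generate_tracts(60, seed=2, jitter=0.4)
        rng = np.random.default_rng(0)
        xmin, ymin, xmax, ymax = tracts.region_bounds
        pts = np.column_stack([rng.uniform(xmin, xmax, 1000), rng.uniform(ymin, ymax, 1000)])
        fast = assign_points_to_tracts(pts, tracts)
        for k in range(1000):
            p = Point(*pts[k])
            hits = sorted(t.tract_id for t in tracts.tracts if t.polygon.covers(p))
            assert fast[k] == (hits[0] if hits else None)


def _toy_log():
    # tract A: 10 events, 2 contain "cough"; tract B: 4 events, all contain "juul"
    users, tids, toks = [], [], []
    for i in range(10):
        users.append(f"ua{i}")
        tids.append("A")
        toks.append(("cough", "weather") if i < 2 else ("weather", "news"))
    for i in range(4):
        users.append(f"ub{i}")
        tids.append("B")
        toks.append(("juul", "juul", "news"))
    return QueryLog(users, tids, toks)


def _toy_tracts():
    ts = generate_tracts(4, region_size=4.0, jitter=0.0, seed=0)
    renamed = [tp.Tract(n, t.state_code, t.polygon, t.population)
               for n, t in zip(["A", "B", "C", "D"], ts.tracts)]
    return tp.TractSet(renamed, ts.region_bounds)


class TestNormalizedCounts:
    def test_hand_counts(self):
        kws = KeywordSet({"cough": "symptom", "juul": "smoking"})
        table = normalized_counts(_toy_log(), kws, _toy_tracts())
        assert table.data.loc["A", "cough"] == pytest.approx(0.2)
        assert table.data.loc["A", "juul"] == 0.0          # no event contains it
        assert table.data.loc["B", "juul"] == pytest.approx(1.0)  # every event does
        assert table.data.loc["B", "cough"] == 0.0

    def test_repeated_token_counts_once_per_query(self):
        kws = KeywordSet({"juul": "smoking"})
        table = normalized_counts(_toy_log(), kws, _toy_tracts())
        assert table.data.loc["B", "juul"] == 1.0  # not 2.0

    def test_zero_event_tracts_flagged_with_zeros(self):
        kws = KeywordSet({"cough": "symptom"})
        table = normalized_counts(_toy_log(), kws, _toy_tracts())
        assert set(table.flags["zero_event_tracts"]) == {"C", "D"}
        assert (table.data.loc[["C", "D"]] == 0).all().all()

    def test_unknown_tract_rejected(self, grid_tracts):
        log = QueryLog(["u"], ["nope"], [("cough",)])
        with pytest.raises(MissingDataError):
            normalized_counts(log, KeywordSet({"cough": "symptom"}), grid_tracts)


class TestCategorySums:
    def test_hand_sums_and_empty_category(self):
        kws = KeywordSet({"cough": "symptom", "wheezing": "symptom", "advair": "medication"})
        df = pd.DataFrame({"cough": [0.1], "wheezing": [0.05], "advair": [0.0]},
                          index=["A"])
        table = FeatureTable(df, provenance={c: "query" for c in df.columns})
        out = category_sums(table, kws)
        assert out.data.loc["A", "sum_symptoms"] == pytest.approx(0.15)
        assert out.data.loc["A", "sum_medications"] == 0.0
        assert out.data.loc["A", "sum_diseases"] == 0.0  # empty category
        assert "cough" in out.data.columns  # originals retained


class TestNearestNeighbors:
    def test_m1_is_self_only(self, grid_tracts):
        index = nearest_neighbors(grid_tracts, 1)
        assert all(v == [k] for k, v in index.index.items())

    def test_collinear_example(self):
        from shapely.geometry import Polygon
        def strip(x):  # unit squares centred at (x+0.5, 0.5)
            return Polygon([(x, 0), (x + 1, 0), (x + 1, 1), (x, 1)])
        tracts = tp.TractSet(
            [tp.Tract("P", "S", strip(-0.5), 100),   # centroid x=0
             tp.Tract("Q", "S", strip(0.5), 100),    # centroid x=1
             tp.Tract("R", "S", strip(2.5), 100)],   # centroid x=3
            (-0.5, 0, 3.5, 1))
        index = nearest_neighbors(tracts, 2)
        assert index.index["P"] == ["P", "Q"]

    def test_matches_all_pairs_oracle(self):
        tracts = generate_tracts(150, seed=9)
        ids = tracts.ids
        cents = tracts.centroids
        for m in (1, 4, 8):
            index = nearest_neighbors(tracts, m)
            for i in range(0, 150, 17):
                d = [(float(np.hypot(*(cents[j] - cents[i]))), ids[j])
                     for j in range(150) if j != i]
                expected = [ids[i]] + [t for _, t in sorted(d)[: m - 1]]
                assert index.index[ids[i]] == expected

    def test_m_bounds(self, grid_tracts):
        with pytest.raises(InvalidParameterError):
            nearest_neighbors(grid_tracts, 0)
        with pytest.raises(InvalidParameterError):
            nearest_neighbors(grid_tracts, 10)


class TestNeighborSmooth:
    def _table(self, values):
        df = pd.DataFrame({"f": values}, index=list("AB")[: len(values)])
        return FeatureTable(df, provenance={"f": "query"})

    def test_m1_identity(self, grid_tracts):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"f": rng.random(9)}, index=grid_tracts.ids)
        table = FeatureTable(df, provenance={"f": "query"})
        out = neighbor_smooth(table, nearest_neighbors(grid_tracts, 1))
        pd.testing.assert_frame_equal(out.data, table.data)

    def test_hand_average(self):
        table = self._table([0.1, 0.2])
        index = NeighborIndex({"A": ["A", "B"], "B": ["B", "A"]}, m=2)
        out = neighbor_smooth(table, index)
        assert out.data.loc["A", "f"] == pytest.approx(0.15)
        assert out.m == 2

    def test_constant_column_invariant(self, grid_tracts):
        df = pd.DataFrame({"f": [0.4] * 9}, index=grid_tracts.ids)
        table = FeatureTable(df, provenance={"f": "query"})
        for m in (1, 3, 9):
            out = neighbor_smooth(table, nearest_neighbors(grid_tracts, m))
            np.testing.assert_allclose(out.data["f"], 0.4)

    def test_convex_range_preservation(self, grid_tracts):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"f": rng.random(9)}, index=grid_tracts.ids)
        table = FeatureTable(df, provenance={"f": "query"})
        out = neighbor_smooth(table, nearest_neighbors(grid_tracts, 4))
        assert out.data["f"].min() >= df["f"].min() - 1e-12
        assert out.data["f"].max() <= df["f"].max() + 1e-12

    def test_missing_tract_raises(self):
        table = self._table([0.1, 0.2])
        index = NeighborIndex({"A": ["A", "B"]}, m=2)
        with pytest.raises(InconsistentIndexError):
            neighbor_smooth(table, index)


class TestLandcoverProportions:
    def test_uniform_raster(self, grid_tracts):
        grid = np.full((12, 12), 24, dtype=np.int32)
        ras = LandCoverRaster(grid, cell_km=0.5)
        out = landcover_proportions(ras, grid_tracts)
        assert (out.data["landcover_developed_high"] == 1.0).all()
        assert out.data.drop(columns="landcover_developed_high").to_numpy().sum() == 0.0

    def test_half_and_half_toy_raster(self):
        ts = generate_tracts(2, region_size=None, jitter=0.0, seed=0)
        # 2 tracts side by side spanning the full height; alternate raster rows
        # so each tract gets exactly half forest, half high-developed cells
        xmin, ymin, xmax, ymax = ts.region_bounds
        n = 10
        cell = (xmax - xmin) / n
        grid = np.where(np.arange(n)[:, None] % 2 == 0, 41, 24) * np.ones((1, n), int)
        ras = LandCoverRaster(grid.astype(np.int32), cell_km=cell, origin=(xmin, ymin))
        out = landcover_proportions(ras, ts)
        for t in ts.ids:
            assert out.data.loc[t, "landcover_forest_deciduous"] == pytest.approx(0.5)
            assert out.data.loc[t, "landcover_developed_high"] == pytest.approx(0.5)

    def test_row_sums_to_one(self, small_city):
        out = landcover_proportions(small_city.landcover, small_city.tracts)
        np.testing.assert_allclose(out.data.sum(axis=1), 1.0, atol=1e-9)


class TestAdjacencyFeatures:
    def _single_tract(self, size):
        from shapely.geometry import Polygon
        poly = Polygon([(0, 0), (size, 0), (size, size), (0, size)])
        return tp.TractSet([tp.Tract("A", "S", poly, 100)], (0, 0, size, size))

    def test_all_forest_is_fully_adjacent(self):
        ts = self._single_tract(3.0)
        ras = LandCoverRaster(np.full((3, 3), 41, dtype=np.int32), cell_km=1.0)
        out = adjacency_features(ras, ts)
        assert out.data.loc["A", "forest_adj_forest"] == 1.0

    def test_center_forest_ring_highdev(self):
        # 3x3: center forest, 8 high-developed around; under 4-neighborhood
        # exactly the 4 edge-adjacent high-dev pixels touch forest -> 4/8
        ts = self._single_tract(3.0)
        grid = np.full((3, 3), 24, dtype=np.int32)
        grid[1, 1] = 41
        out = adjacency_features(LandCoverRaster(grid, cell_km=1.0), ts)
        assert out.data.loc["A", "highdev_adj_forest"] == pytest.approx(4 / 8)
        assert out.data.loc["A", "forest_adj_forest"] == 0.0

    def test_no_focal_pixels_scores_zero(self):
        ts = self._single_tract(3.0)
        ras = LandCoverRaster(np.full((3, 3), 11, dtype=np.int32), cell_km=1.0)
        out = adjacency_features(ras, ts)
        assert (out.data.loc["A"] == 0.0).all()

    def test_matches_pixel_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        ts = self._single_tract(8.0)
        grid = rng.choice([24, 41, 11], size=(8, 8), p=[0.4, 0.4, 0.2]).astype(np.int32)
        out = adjacency_features(LandCoverRaster(grid, cell_km=1.0), ts)

        def oracle(focal_codes, target_codes):
            focal = qual = 0
            for r in range(8):
                for c in range(8):
                    if grid[r, c] not in focal_codes:
                        continue
                    focal += 1
                    nbrs = [(r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)]
                    if any(0 <= rr < 8 and 0 <= cc < 8 and grid[rr, cc] in target_codes
                           for rr, cc in nbrs):
                        qual += 1
            return qual / focal if focal else 0.0

        assert out.data.loc["A", "highdev_adj_highdev"] == pytest.approx(oracle({24}, {24}))
        assert out.data.loc["A", "highdev_adj_forest"] == pytest.approx(oracle({24}, {41}))
        assert out.data.loc["A", "forest_adj_forest"] == pytest.approx(oracle({41}, {41}))


class TestCensusFeatures:
    def test_passthrough_and_column_count(self, grid_tracts):
        census = generate_census(grid_tracts, seed=1)
        out = census_features(census, grid_tracts)
        assert out.data.shape[1] == 20
        pd.testing.assert_series_equal(out.data["poverty"], census.data["poverty"])

    def test_missing_tract_raises(self, grid_tracts):
        census = generate_census(grid_tracts, seed=1)
        trimmed = tp.CensusTable(census.data.iloc[:-1])
        with pytest.raises(MissingDataError):
            census_features(trimmed, grid_tracts)


class TestMergeFeatures:
    def _parts(self, grid_tracts):
        a = FeatureTable(pd.DataFrame({"x": range(9)}, index=grid_tracts.ids, dtype=float),
                         provenance={"x": "query"})
        b = FeatureTable(pd.DataFrame({"y": range(9)}, index=grid_tracts.ids, dtype=float),
                         provenance={"y": "landcover"})
        return a, b

    def test_column_count_is_sum_of_parts(self, grid_tracts):
        a, b = self._parts(grid_tracts)
        out = merge_features([a, b])
        assert list(out.data.columns) == ["x", "y"]

    def test_state_feature_codes(self, grid_tracts):
        a, _ = self._parts(grid_tracts)
        out = merge_features([a], state_feature=True, tracts=grid_tracts)
        assert out.data["state"].nunique() == 3
        assert out.state_code_map is not None
        assert out.provenance["state"] == "state"

    def test_row_mismatch_raises(self, grid_tracts):
        a, b = self._parts(grid_tracts)
        b.data = b.data.iloc[:-1]
        with pytest.raises(AlignmentError):
            merge_features([a, b])

    def test_duplicate_columns_raise(self, grid_tracts):
        a, _ = self._parts(grid_tracts)
        with pytest.raises(SchemaError):
            merge_features([a, a])
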