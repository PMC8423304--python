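import json

import numpy as np
import pytest
from shapely.geometry import box

import enmpipe as ep
from enmpipe.consensus import (
    BinaryMap,
    binarize,
    change_stats,
    consensus,
    overlap_with_polygons,
    read_polygons_geojson,
    suitable_area_km2,
)
from enmpipe.ensemble import SuitabilityMap
from enmpipe.grids import EARTH_RADIUS_KM, GridSpec


GRID = GridSpec(west=0.0, north=2.0, cell_deg=1.0, n_rows=2, n_cols=2)


def smap(values):
    return SuitabilityMap(grid=GRID, values=np.asarray(values, dtype=float))


def bmap(values, threshold=0.5, label="current", grid=GRID):
    return BinaryMap(grid=grid, values=np.asarray(values, dtype=float),
                     threshold=threshold, scenario_label=label)


class TestBinarize:
    def test_cell_equal_to_threshold_is_present(self):
        out = binarize(smap([[0.5, 0.49], [0.51, 0.0]]), 0.5)
        assert out.values[0, 0] == 1.0
        assert out.values[0, 1] == 0.0

    def test_zero_threshold_marks_all_valid_cells(self):
        out = binarize(smap([[0.0, 0.2], [0.9, 1.0]]), 0.0)
        assert np.all(out.values == 1.0)

    def test_threshold_above_one_rejected(self):
        with pytest.raises(ValueError):
            binarize(smap([[0.5, 0.5], [0.5, 0.5]]), 1.0 + 1e-9)

    def test_nodata_preserved(self):
        out = binarize(smap([[np.nan, 0.6], [0.4, 0.6]]), 0.5)
        assert np.isnan(out.values[0, 0])


class TestConsensus:
    def test_majority_vote(self):
        maps = [bmap([[1, 0], [0, 0]]), bmap([[1, 0], [0, 0]]), bmap([[0, 0], [1, 0]])]
        cmap, freq = consensus(maps, [1, 1, 1])
        assert cmap.values[0, 0] == 1.0  # votes 1,1,0
        assert cmap.values[1, 0] == 0.0  # votes 0,0,1
        assert freq[0, 0] == pytest.approx(2 / 3)

    def test_tie_rounds_to_presence(self):
        maps = [bmap([[1, 0], [0, 0]]), bmap([[0, 0], [0, 0]])]
        cmap, _ = consensus(maps, [1, 1])
        assert cmap.values[0, 0] == 1.0

    def test_only_qualifying_maps_contribute(self):
        maps = [bmap([[1, 1], [1, 1]]), bmap([[0, 0], [0, 0]]), bmap([[1, 1], [1, 1]])]
        cmap, freq = consensus(maps, [1, 0, 1])
        assert np.all(freq == 1.0)

    def test_single_qualifying_map_is_identity(self):
        only = bmap([[1, 0], [0, 1]])
        cmap, _ = consensus([only, bmap([[0, 0], [0, 0]])], [1, 0])
        assert np.array_equal(cmap.values, only.values)

    def test_zero_qualifying_maps_error(self):
        with pytest.raises(ValueError, match="no valid replicates"):
            consensus([bmap([[1, 0], [0, 0]])], [0])


class TestSuitableArea:
    def test_empty_map_is_zero(self):
        assert suitable_area_km2(bmap([[0, 0], [0, 0]])) == 0.0

    def test_one_degree_band_matches_closed_form(self):
        grid = GridSpec(west=-180.0, north=1.0, cell_deg=1.0 / 12.0,
                        n_rows=12, n_cols=4320)
        full = BinaryMap(grid=grid, values=np.ones((12, 4320)), threshold=0.5)
        closed = 2 * np.pi * EARTH_RADIUS_KM**2 * np.sin(np.radians(1.0))
        assert suitable_area_km2(full) == pytest.approx(closed, rel=1e-3)


class TestChangeStats:
    def test_thirty_percent_loss(self):
        cur = bmap([[1, 1], [1, 1]])
        # future keeps ~70% of area: approximate with per-cell areas equal enough
        grid = GridSpec(west=-180.0, north=0.5, cell_deg=1.0, n_rows=1, n_cols=10)
        cur = BinaryMap(grid=grid, values=np.ones((1, 10)), threshold=0.5)
        fut = BinaryMap(grid=grid, values=np.array([[1, 1, 1, 1, 1, 1, 1, 0, 0, 0]],
                                                   dtype=float),
                        threshold=0.5, scenario_label="fut")
        cc = change_stats(cur, {"fut": fut})
        assert cc.loss_pct["fut"] == pytest.approx(30.0)
        assert cc.gain_pct["fut"] == 0.0

    def test_identical_maps_are_stable(self):
        cur = bmap([[1, 0], [1, 1]])
        fut = bmap([[1, 0], [1, 1]], label="fut")
        cc = change_stats(cur, {"fut": fut})
        assert cc.loss_pct["fut"] == 0.0
        assert cc.stable_km2["fut"] == pytest.approx(cc.areas_km2["current"])
        assert cc.lost_km2["fut"] == 0.0

    def test_disjoint_equal_area_maps(self):
        grid = GridSpec(west=-1.0, north=0.5, cell_deg=1.0, n_rows=1, n_cols=2)
        cur = BinaryMap(grid=grid, values=np.array([[1.0, 0.0]]), threshold=0.5)
        fut = BinaryMap(grid=grid, values=np.array([[0.0, 1.0]]), threshold=0.5,
                        scenario_label="fut")
        cc = change_stats(cur, {"fut": fut})
        assert cc.loss_pct["fut"] == 0.0  # totals are equal
        assert cc.stable_km2["fut"] == 0.0
        assert cc.lost_km2["fut"] == pytest.approx(cc.areas_km2["current"])
        assert cc.gained_km2["fut"] == pytest.approx(cc.areas_km2["current"])

    def test_empty_current_reports_not_applicable(self):
        cur = bmap([[0, 0], [0, 0]])
        fut = bmap([[1, 0], [0, 0]], label="fut")
        cc = change_stats(cur, {"fut": fut})
        assert cc.loss_pct["fut"] is None


class TestPolygonOverlap:
    def test_full_cover_none_cover_and_half_cover(self):
        grid = GridSpec(west=0.0, north=0.5, cell_deg=1.0, n_rows=1, n_cols=4)
        present = BinaryMap(grid=grid, values=np.ones((1, 4)), threshold=0.5)
        total = suitable_area_km2(present)
        whole = ("all", box(-1.0, -1.0, 5.0, 1.0))
        nothing = ("none", box(10.0, 10.0, 11.0, 11.0))
        half = ("half", box(0.0, -1.0, 2.0, 1.0))  # covers centres of cells 0,1
        table, union_pct = overlap_with_polygons(present, [whole, nothing, half])
        t = table.set_index("name")
        assert t.loc["all", "overlap_km2"] == pytest.approx(total)
        assert t.loc["all", "pct_of_suitable"] == pytest.approx(100.0)
        assert t.loc["none", "overlap_km2"] == 0.0
        assert t.loc["half", "overlap_km2"] == pytest.approx(total / 2)
        assert union_pct == pytest.approx(100.0)

    def test_disjoint_polygons_are_additive(self):
        grid = GridSpec(west=0.0, north=0.5, cell_deg=1.0, n_rows=1, n_cols=4)
        present = BinaryMap(grid=grid, values=np.ones((1, 4)), threshold=0.5)
        left = ("left", box(0.0, -1.0, 2.0, 1.0))
        right = ("right", box(2.0, -1.0, 4.0, 1.0))
        table, union_pct = overlap_with_polygons(present, [left, right])
        assert table["overlap_km2"].sum() == pytest.approx(suitable_area_km2(present))
        assert union_pct == pytest.approx(100.0)

    def test_empty_polygon_list(self):
        grid = GridSpec(west=0.0, north=0.5, cell_deg=1.0, n_rows=1, n_cols=2)
        present = BinaryMap(grid=grid, values=np.ones((1, 2)), threshold=0.5)
        table, union_pct = overlap_with_polygons(present, [])
        assert table.empty and union_pct == 0.0

    def test_geojson_reader(self, tmp_path):
        gj = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"name": "reserve"},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[[0, 0], [2, 0], [2, 2], [0, 2], [0, 0]]],
                    },
                }
            ],
        }
        p = tmp_path / "polys.geojson"
        p.write_text(json.dumps(gj))
        polys = read_polygons_geojson(p)
        assert polys[0][0] == "reserve"
        assert polys[0][1].contains(box(0.5, 0.5, 1.0, 1.0))
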