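"""Grid data model, raster round trips, point extraction and thinning."""

import json

import numpy as np
import pandas as pd
import pytest

from ensdm import (
    GridSpec,
    OccurrenceSet,
    extract_values,
    read_map,
    read_occurrences,
    read_stack,
    regions_from_geojson,
    thin_occurrences,
    write_map,
    write_occurrences,
)
from ensdm.errors import ExtentError, GeometryError, NamingError, ValidationError
from ensdm.geodata import PRESENCE, ClimateStack


def _write(tmp_path, name, values, grid, mask=None, dtype="float32"):
    path = tmp_path / name
    write_map(np.asarray(values), grid, path, dtype, mask)
    return path


class TestRasterIO:
    def test_float_round_trip_is_identity(self, tmp_path, small_grid):
        rng = np.random.default_rng(0)
        values = rng.random(small_grid.shape).astype(np.float32)
        mask = np.zeros(small_grid.shape, bool)
        mask[0, 0] = True
        path = _write(tmp_path, "p.tif", values, small_grid, mask)
        v2, g2, m2 = read_map(path)
        assert g2 == small_grid
        np.testing.assert_array_equal(m2, mask)
        np.testing.assert_array_equal(v2[~mask], values[~mask])

    def test_class_map_byte_round_trip(self, tmp_path, small_grid):
        classes = np.arange(100).reshape(10, 10) % 5
        path = _write(tmp_path, "c.tif", classes, small_grid, dtype="uint8")
        v2, _, m2 = read_map(path)
        assert set(np.unique(v2)) <= set(range(6))
        np.testing.assert_array_equal(v2, classes)
        assert not m2.any()

    def test_nodata_sentinel_read_back_as_mask(self, tmp_path, small_grid):
        values = np.ones(small_grid.shape)
        mask = np.zeros(small_grid.shape, bool)
        mask[3, 4] = True
        path = _write(tmp_path, "n.tif", values, small_grid, mask)
        raw, _, m2 = read_map(path)
        assert raw[3, 4] == -9999.0  # sentinel on disk
        assert m2[3, 4] and m2.sum() == 1

    def test_read_stack_unions_nodata_masks(self, tmp_path, small_grid):
        a = np.ones(small_grid.shape)
        mask_a = np.zeros(small_grid.shape, bool)
        mask_a[0, 0] = True
        mask_b = np.zeros(small_grid.shape, bool)
        mask_b[1, 1] = True
        pa = _write(tmp_path, "a.tif", a, small_grid, mask_a)
        pb = _write(tmp_path, "b.tif", a, small_grid, mask_b)
        stack = read_stack([pa, pb], ["bio1", "bio12"])
        assert stack.names == ["bio1", "bio12"]
        assert stack.nodata_mask[0, 0] and stack.nodata_mask[1, 1]
        assert stack.nodata_mask.sum() == 2

    def test_read_stack_rejects_mismatched_grids(self, tmp_path, small_grid):
        other = GridSpec(10, 11, small_grid.origin, small_grid.cell_size)
        pa = _write(tmp_path, "a.tif", np.ones((10, 10)), small_grid)
        pb = _write(tmp_path, "b.tif", np.ones((10, 11)), other)
        with pytest.raises(GeometryError):
            read_stack([pa, pb], ["bio1", "bio2"])

    def test_multiband_file_reads_as_stack(self, tmp_path, small_grid):
        import tifffile

        from ensdm.geodata import _geo_extratags

        data = np.random.default_rng(1).random((3, 10, 10)).astype(np.float32)
        path = tmp_path / "multi.tif"
        tifffile.imwrite(
            path, data, photometric="minisblack",
            extratags=_geo_extratags(small_grid, -9999.0),
        )
        stack = read_stack([path], ["bio1", "bio2", "bio3"])
        assert stack.names == ["bio1", "bio2", "bio3"]
        np.testing.assert_allclose(stack.layers["bio2"], data[1])

    def test_duplicate_layer_names_rejected(self, tmp_path, small_grid):
        pa = _write(tmp_path, "a.tif", np.ones((10, 10)), small_grid)
        with pytest.raises(NamingError):
            read_stack([pa, pa], ["bio1", "bio1"])


class TestExtractValues:
    def _stack(self, grid, value=7.0):
        return ClimateStack(
            grid,
            {"bio1": np.full(grid.shape, value)},
            np.zeros(grid.shape, bool),
        )

    def test_nw_corner_belongs_to_cell(self, small_grid):
        # the grid origin is the NW corner of cell (0, 0); half-open rule
        occ = OccurrenceSet.from_arrays([33.0], [-9.0], PRESENCE)
        X, y, dropped = extract_values(self._stack(small_grid), occ)
        assert len(X) == 1 and X["bio1"].iloc[0] == 7.0 and not dropped

    def test_cell_center_reads_cell_value(self, small_grid):
        lons, lats = small_grid.cell_centers()
        occ = OccurrenceSet.from_arrays([lons[3]], [lats[2]], PRESENCE)
        X, _, _ = extract_values(self._stack(small_grid), occ)
        assert X["bio1"].iloc[0] == 7.0

    def test_nodata_rows_dropped_and_reported(self):
        grid = GridSpec(2, 2, (0.0, 2.0), 1.0)
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = True
        stack = ClimateStack(grid, {"bio1": np.ones((2, 2))}, mask)
        occ = OccurrenceSet.from_arrays(
            [0.5, 1.5, 0.5], [1.5, 1.5, 0.5], PRESENCE
        )  # first point sits on the nodata cell
        X, y, dropped = extract_values(stack, occ)
        assert len(X) == 2
        assert dropped == [0]

    def test_point_outside_extent_raises(self, small_grid):
        occ = OccurrenceSet.from_arrays([0.0], [0.0], PRESENCE)
        with pytest.raises(ExtentError):
            extract_values(self._stack(small_grid), occ)

    def test_permutation_equivariance(self, small_grid):
        rng = np.random.default_rng(3)
        stack = ClimateStack(
            small_grid,
            {"bio1": rng.random(small_grid.shape)},
            np.zeros(small_grid.shape, bool),
        )
        lons, lats = small_grid.cell_centers()
        pts = [(lons[i], lats[j]) for i, j in rng.integers(0, 10, (20, 2))]
        occ = OccurrenceSet.from_arrays(*zip(*pts), PRESENCE)
        perm = rng.permutation(20)
        occ_p = occ.subset(perm)
        X, _, _ = extract_values(stack, occ)
        Xp, _, _ = extract_values(stack, occ_p)
        np.testing.assert_array_equal(X.to_numpy()[perm], Xp.to_numpy())


class TestThinning:
    def test_one_point_per_cell(self, small_grid):
        lons, lats = small_grid.cell_centers()
        occ = OccurrenceSet.from_arrays(
            [lons[0], lons[0] + 0.01, lons[5]],
            [lats[0], lats[0] - 0.01, lats[5]],
            PRESENCE,
        )
        thinned = thin_occurrences(occ, small_grid, seed=0)
        assert len(thinned) == 2

    def test_distinct_cells_are_identity(self, small_grid):
        lons, lats = small_grid.cell_centers()
        occ = OccurrenceSet.from_arrays(lons[:5], lats[:5], PRESENCE)
        thinned = thin_occurrences(occ, small_grid, seed=0)
        pd.testing.assert_frame_equal(thinned.points, occ.points)

    def test_120_points_thin_to_84(self):
        # 36 cells hold 2 points each, 48 cells hold 1: 120 -> 84 retained
        grid = GridSpec(20, 20, (0.0, 20.0), 1.0)
        lons, lats = grid.cell_centers()
        cells = [(i // 20, i % 20) for i in range(84)]
        xs, ys = [], []
        for k, (r, c) in enumerate(cells):
            xs.append(lons[c])
            ys.append(lats[r])
            if k < 36:  # duplicate within the same cell
                xs.append(lons[c] + 0.2)
                ys.append(lats[r] - 0.2)
        occ = OccurrenceSet.from_arrays(xs, ys, PRESENCE)
        assert len(occ) == 120
        assert len(thin_occurrences(occ, grid, seed=7)) == 84

    def test_idempotent(self, small_grid):
        rng = np.random.default_rng(11)
        lons = 33.0 + rng.random(50) * 0.5
        lats = -9.5 + rng.random(50) * 0.5
        occ = OccurrenceSet.from_arrays(lons, lats, PRESENCE)
        once = thin_occurrences(occ, small_grid, seed=1)
        twice = thin_occurrences(once, small_grid, seed=99)
        pd.testing.assert_frame_equal(once.points, twice.points)


class TestOccurrenceCSV:
    def test_round_trip_and_default_label(self, tmp_path):
        path = tmp_path / "occ.csv"
        path.write_text("lon,lat\n33.5,-9.5\n34.0,-10.0\n")
        occ = read_occurrences(path)
        assert occ.n_presence == 2 and occ.n_background == 0
        out = tmp_path / "occ2.csv"
        write_occurrences(occ, out)
        occ2 = read_occurrences(out)
        pd.testing.assert_frame_equal(occ.points, occ2.points)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            OccurrenceSet.from_arrays([1.0], [1.0], "maybe")


def test_regions_from_geojson(small_grid):
    # western half vs eastern half of the 0.5 x 0.5 degree extent
    def box(lon0, lon1):
        return {
            "type": "Polygon",
            "coordinates": [[
                [lon0, -9.5], [lon1, -9.5], [lon1, -9.0], [lon0, -9.0], [lon0, -9.5]
            ]],
        }

    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"name": "west"}, "geometry": box(33.0, 33.25)},
            {"type": "Feature", "properties": {"name": "east"}, "geometry": box(33.25, 33.5)},
        ],
    }
    mask = regions_from_geojson(doc, small_grid)
    assert mask.region_names == {1: "west", 2: "east"}
    assert (mask.region_id[:, :5] == 1).all()
    assert (mask.region_id[:, 5:] == 2).all()
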