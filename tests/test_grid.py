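"""Raster model, I/O, nearest-neighbour fill, extent masking, snapping."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_layer, make_stack
from sdmshift.grid import (Grid, ModelingExtent, fill_missing, mask_to_extent,
                           read_layer, snap_and_dedupe, write_layer, NODATA)


class TestRasterIO:
    def test_ascii_header_nodata_cell_masked(self, tmp_path):
        p = tmp_path / "t.asc"
        p.write_text("ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
                     "NODATA_value -9999\n1 2\n-9999 4\n")
        layer = read_layer(p, "t")
        assert layer.grid.shape == (2, 2)
        assert layer.mask.sum() == 1 and layer.mask[1, 0]
        assert layer.values[0, 1] == 2.0

    def test_read_is_deterministic(self, tmp_path, small_grid, rng):
        layer = make_layer(small_grid, rng.normal(size=(4, 4)).round(4))
        path = write_layer(layer, tmp_path / "a.asc")
        l1, l2 = read_layer(path, "a"), read_layer(path, "a")
        np.testing.assert_array_equal(l1.values, l2.values)
        np.testing.assert_array_equal(l1.mask, l2.mask)

    def test_ascii_roundtrip_bit_exact_at_precision(self, tmp_path, small_grid, rng):
        # after one write/read cycle the representation is a fixed point
        layer = make_layer(small_grid, rng.normal(size=(4, 4)))
        l1 = read_layer(write_layer(layer, tmp_path / "a.asc"), "a")
        l2 = read_layer(write_layer(l1, tmp_path / "b.asc"), "a")
        np.testing.assert_array_equal(l1.values, l2.values)

    def test_geotiff_and_ascii_encode_same_field(self, tmp_path, small_grid, rng):
        vals = rng.normal(size=(4, 4)).round(6)  # exactly representable at %.10g
        mask = np.zeros((4, 4), bool)
        mask[2, 3] = True
        layer = make_layer(small_grid, vals, mask=mask)
        la = read_layer(write_layer(layer, tmp_path / "x.asc"), "x")
        lt = read_layer(write_layer(layer, tmp_path / "x.tif"), "x")
        assert la.grid.approx_equal(lt.grid)
        np.testing.assert_array_equal(la.mask, lt.mask)
        np.testing.assert_allclose(la.values[~la.mask], lt.values[~lt.mask], rtol=0, atol=0)

    def test_unreadable_and_mismatched_grid_rejected(self, tmp_path, small_grid):
        with pytest.raises(FileNotFoundError):
            read_layer(tmp_path / "missing.asc", "x")
        p = tmp_path / "bad.asc"
        p.write_text("ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
                     "NODATA_value -9999\n1 2\n3 4\n")
        with pytest.raises(ValueError, match="grid does not match"):
            read_layer(p, "x", grid=small_grid)

    def test_negative_elevation_depth_negated(self, tmp_path, small_grid):
        layer = make_layer(small_grid, -100.0 * np.ones((4, 4)), name="depth")
        got = read_layer(write_layer(layer, tmp_path / "depth.asc"), "depth")
        assert np.all(got.values == 100.0)


class TestFillMissing:
    def test_constant_field_stays_constant(self, small_grid):
        mask = np.zeros((4, 4), bool)
        mask[1:3, 1:3] = True
        layer = make_layer(small_grid, np.full((4, 4), 7.0), mask=mask)
        filled = fill_missing(layer)
        assert np.all(filled.values == 7.0) and not filled.mask.any()

    def test_single_seed_floods_everything(self, small_grid):
        mask = np.ones((4, 4), bool)
        mask[2, 1] = False
        vals = np.zeros((4, 4))
        vals[2, 1] = 3.5
        filled = fill_missing(make_layer(small_grid, vals, mask=mask))
        assert np.all(filled.values == 3.5)

    def test_two_seeds_make_voronoi_partition(self):
        # oracle: per-cell nearest seed, row-major tie-break
        grid = Grid(5, 7, 0.0, 0.0, 1.0)
        mask = np.ones(grid.shape, bool)
        seeds = [(0, 0, 1.0), (4, 6, 2.0)]
        vals = np.zeros(grid.shape)
        for r, c, v in seeds:
            mask[r, c] = False
            vals[r, c] = v
        filled = fill_missing(make_layer(grid, vals, mask=mask))
        for r in range(5):
            for c in range(7):
                d = [((r - sr) ** 2 + (c - sc) ** 2, sr * 7 + sc, v)
                     for sr, sc, v in seeds]
                expected = min(d)[2]
                assert filled.values[r, c] == expected, (r, c)

    def test_idempotent_and_observed_untouched(self, small_grid, rng):
        vals = rng.normal(size=(4, 4))
        mask = rng.random((4, 4)) < 0.4
        mask[0, 0] = False
        layer = make_layer(small_grid, np.where(mask, 0, vals), mask=mask)
        f1 = fill_missing(layer)
        np.testing.assert_array_equal(f1.values[~mask], vals[~mask])
        f2 = fill_missing(f1)
        np.testing.assert_array_equal(f1.values, f2.values)

    def test_fully_missing_rejected(self, small_grid):
        layer = make_layer(small_grid, np.zeros((4, 4)), mask=np.ones((4, 4), bool))
        with pytest.raises(ValueError, match="fully missing"):
            fill_missing(layer)


class TestMaskToExtent:
    def _stack(self, grid, depth):
        return make_stack(grid, {"depth": depth, "temp": np.ones(grid.shape)})

    def test_all_too_deep_is_empty_error(self, small_grid):
        stack = self._stack(small_grid, np.full((4, 4), 2000.0))
        ext = ModelingExtent(0, 4, 0, 4, max_depth=1000)
        with pytest.raises(ValueError, match="empty modeling area"):
            mask_to_extent(stack, ext)

    def test_full_box_shallow_depth_is_identity(self, small_grid):
        stack = self._stack(small_grid, np.full((4, 4), 10.0))
        out = mask_to_extent(stack, ModelingExtent(0, 4, 0, 4, max_depth=1000))
        assert not out["temp"].mask.any()

    def test_depth_rows_enumerated(self, small_grid):
        # depth = 100 * row index (row 0 north); max 250 keeps rows 0..2
        depth = 100.0 * np.arange(4)[:, None] * np.ones((1, 4))
        out = mask_to_extent(self._stack(small_grid, depth),
                             ModelingExtent(0, 4, 0, 4, max_depth=250))
        unmasked_rows = sorted(set(np.nonzero(~out["temp"].mask)[0]))
        assert unmasked_rows == [0, 1, 2]

    def test_never_unmasks_and_composes_as_intersection(self, small_grid):
        depth = np.full((4, 4), 10.0)
        stack = self._stack(small_grid, depth)
        stack["temp"].mask[0, 0] = True
        big = ModelingExtent(0, 4, 0, 4, max_depth=1000)
        small = ModelingExtent(0, 2.0, 0, 4, max_depth=1000)
        out_big = mask_to_extent(stack, big)
        assert out_big["temp"].mask[0, 0]  # stays masked
        seq = mask_to_extent(out_big, small)
        direct = mask_to_extent(stack, small)
        np.testing.assert_array_equal(seq["temp"].mask, direct["temp"].mask)


class TestSnapAndDedupe:
    def test_five_records_one_cell(self, small_grid):
        recs = [(0.5 + 0.01 * i, 3.5) for i in range(5)]
        occ = snap_and_dedupe(recs, small_grid)
        assert len(occ) == 1

    def test_three_distinct_cells(self, small_grid):
        occ = snap_and_dedupe([(0.5, 0.5), (1.5, 0.5), (2.5, 2.5)], small_grid)
        assert len(occ) == 3

    def test_interior_edge_goes_east_south(self, small_grid):
        # lon=2, lat=2 sits on interior edges; floor convention puts it in
        # the cell east of lon 2 (col 2) and south of lat 2 (row 2)
        occ = snap_and_dedupe([(2.0, 2.0)], small_grid)
        assert occ.rows[0] == 2 and occ.cols[0] == 2

    def test_out_of_grid_dropped_and_all_out_errors(self, small_grid):
        occ = snap_and_dedupe([(0.5, 0.5), (99.0, 99.0)], small_grid)
        assert len(occ) == 1
        with pytest.raises(ValueError, match="no occurrence records"):
            snap_and_dedupe([(99.0, 99.0)], small_grid)

    def test_idempotent_and_never_grows(self, small_grid, rng):
        recs = list(zip(rng.uniform(0, 4, 50), rng.uniform(0, 4, 50)))
        occ = snap_and_dedupe(recs, small_grid)
        assert len(occ) <= 50
        again = snap_and_dedupe(list(zip(occ.lon, occ.lat)), small_grid)
        np.testing.assert_array_equal(np.sort(occ.flat_cells), np.sort(again.flat_cells))

    def test_dataframe_input_with_species(self, small_grid):
        df = pd.DataFrame({"species": ["sp1"] * 3, "longitude": [0.5, 0.6, 1.5],
                           "latitude": [0.5, 0.5, 1.5]})
        occ = snap_and_dedupe(df, small_grid)
        assert occ.species == "sp1" and len(occ) == 2
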