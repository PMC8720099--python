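import numpy as np
import pytest

from geobiodiv.raster import (PlotGeometry, RasterGrid, extract_plot_values,
                              ndvi, rbvi, read_raster, tpi, write_raster)


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path, rng):
        vals = rng.normal(size=(10, 10))
        vals[2, 3] = -9999.0
        grid = RasterGrid(vals, origin=(500.0, 1200.0), cell_size=30.0,
                          nodata=-9999.0, crs_tag="EPSG:32717")
        p = tmp_path / "g.tif"
        write_raster(grid, p)
        back = read_raster(p)
        np.testing.assert_array_equal(back.values, grid.values)
        assert back.origin == grid.origin
        assert back.cell_size == grid.cell_size
        assert back.nodata == grid.nodata
        assert back.crs_tag == grid.crs_tag
        # nodata cells stay nodata
        assert not back.valid_mask()[2, 3]

    def test_rectangular_cells_rejected(self, tmp_path):
        import tifffile
        p = tmp_path / "rect.tif"
        tifffile.imwrite(str(p), np.zeros((4, 4)), extratags=[
            (33550, "d", 3, (30.0, 60.0, 0.0)),
            (33922, "d", 6, (0.0, 0.0, 0.0, 0.0, 120.0, 0.0)),
        ])
        with pytest.raises(ValueError, match="square"):
            read_raster(p)


class TestCoordinates:
    def test_world_cell_world_identity_on_centers(self, small_grid):
        for r in range(5):
            for c in range(4):
                x, y = small_grid.cell_center(r, c)
                assert small_grid.world_to_cell(x, y) == (r, c)

    def test_shared_edge_belongs_to_larger_index(self, small_grid):
        # x = 30 is the edge between columns 0 and 1
        assert small_grid.world_to_cell(30.0, 145.0)[1] == 1
        # y = 120 is the edge between rows 0 and 1
        assert small_grid.world_to_cell(5.0, 120.0)[0] == 1

    def test_point_outside_raises(self, small_grid):
        with pytest.raises(ValueError, match="outside"):
            small_grid.world_to_cell(-1.0, 100.0)


class TestBandIndices:
    def test_ndvi_matches_formula(self, small_grid):
        nir = small_grid.with_values(np.full((5, 4), 0.8))
        red = small_grid.with_values(np.full((5, 4), 0.2))
        out = ndvi(nir, red)
        np.testing.assert_allclose(out.values, 0.6)

    def test_equal_bands_give_zero(self, small_grid):
        band = small_grid.with_values(np.full((5, 4), 0.4))
        assert np.all(ndvi(band, band).values == 0.0)
        assert np.all(rbvi(band, band).values == 0.0)

    def test_rbvi_matches_formula(self, small_grid):
        red = small_grid.with_values(np.full((5, 4), 0.3))
        blue = small_grid.with_values(np.full((5, 4), 0.1))
        np.testing.assert_allclose(rbvi(red, blue).values, 0.5)

    def test_zero_denominator_and_nodata_propagate(self, small_grid):
        a = np.full((5, 4), 0.5)
        b = np.full((5, 4), 0.5)
        a[0, 0] = 0.0
        b[0, 0] = 0.0          # 0/0 cell
        a[1, 1] = small_grid.nodata if False else -9999.0
        nir = RasterGrid(a, origin=small_grid.origin, cell_size=30.0)
        red = RasterGrid(b, origin=small_grid.origin, cell_size=30.0)
        out = ndvi(nir, red)
        assert not out.valid_mask()[0, 0]
        assert not out.valid_mask()[1, 1]

    def test_outputs_bounded(self, rng, small_grid):
        nir = small_grid.with_values(rng.uniform(0.01, 1, (5, 4)))
        red = small_grid.with_values(rng.uniform(0.01, 1, (5, 4)))
        out = ndvi(nir, red)
        v = out.values[out.valid_mask()]
        assert np.all((v >= -1) & (v <= 1))

    def test_mismatched_grids_rejected(self, small_grid):
        other = RasterGrid(np.zeros((5, 4)), origin=(10.0, 150.0), cell_size=30.0)
        with pytest.raises(ValueError, match="co-registered"):
            ndvi(small_grid, other)


class TestTPI:
    def test_flat_surface_zero(self, small_grid):
        flat = small_grid.with_values(np.full((5, 4), 1234.5))
        np.testing.assert_allclose(tpi(flat, 1).values, 0.0, atol=1e-9)

    def test_single_peak(self):
        vals = np.zeros((5, 5))
        vals[2, 2] = 7.0
        dem = RasterGrid(vals, origin=(0, 150), cell_size=30.0)
        out = tpi(dem, 1)
        assert out.values[2, 2] == pytest.approx(7.0)
        assert out.values[2, 1] == pytest.approx(-7.0 / 8)

    def test_linear_ramp_interior_zero(self):
        vals = np.tile(np.arange(8, dtype=float), (8, 1))
        dem = RasterGrid(vals, origin=(0, 240), cell_size=30.0)
        out = tpi(dem, 1)
        np.testing.assert_allclose(out.values[1:-1, 1:-1], 0.0, atol=1e-9)

    def test_translation_invariance(self, rng):
        vals = rng.normal(size=(9, 9))
        dem = RasterGrid(vals, origin=(0, 270), cell_size=30.0)
        shifted = RasterGrid(vals + 1000.0, origin=(0, 270), cell_size=30.0)
        np.testing.assert_allclose(tpi(dem, 2).values, tpi(shifted, 2).values,
                                   atol=1e-8)

    def test_window_larger_than_grid_rejected(self, small_grid):
        with pytest.raises(ValueError, match="window"):
            tpi(small_grid, 10)


class TestExtraction:
    def test_point_in_constant_grid(self, small_grid):
        const = small_grid.with_values(np.full((5, 4), 3.14))
        plot = PlotGeometry("p1", (45.0, 75.0))
        assert extract_plot_values(const, plot) == pytest.approx(3.14)

    def test_polygon_mean(self, small_grid):
        # polygon covering the centers of cells (0,0..2) valued 0, 1, 2
        plot = PlotGeometry("p2", [(5, 148), (95, 148), (95, 122), (5, 122)])
        assert extract_plot_values(small_grid, plot) == pytest.approx(1.0)

    def test_polygon_all_nodata_raises(self, small_grid):
        vals = np.full((5, 4), -9999.0)
        vals[4, :] = 1.0
        grid = RasterGrid(vals, origin=(0, 150), cell_size=30.0)
        plot = PlotGeometry("p3", [(5, 148), (95, 148), (95, 122), (5, 122)])
        with pytest.raises(ValueError, match="nodata"):
            extract_plot_values(grid, plot)

    def test_plot_outside_extent_raises(self, small_grid):
        plot = PlotGeometry("p4", (-50.0, 75.0))
        with pytest.raises(ValueError, match="outside"):
            extract_plot_values(small_grid, plot)
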