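"""Grid model, raster I/O, block aggregation, and carbon conversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from silvocool import (CARBON_FRACTION, Field, GeoGrid, aggregate_biomass,
                       biomass_to_carbon, build_pixel_table, classify_density,
                       coverage_mask, read_raster, write_raster)
from silvocool.grids import NODATA

from conftest import make_field


class TestGeoGrid:
    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            GeoGrid(0, 0, -0.1, 4, 4)
        with pytest.raises(ValueError):
            GeoGrid(0, 0, 0.1, 0, 4)

    def test_lat_centers_run_north_to_south(self, small_grid):
        lats = small_grid.lat_centers()
        assert lats[0] == pytest.approx(2.0 - 0.125)
        assert np.all(np.diff(lats) < 0)

    def test_fields_on_different_grids_do_not_combine(self, small_grid):
        other = GeoGrid(2.0, 10.0, 0.25, 8, 9)
        a = make_field(small_grid, 1.0)
        b = make_field(other, 1.0)
        from silvocool.grids import require_same_grid
        with pytest.raises(ValueError, match="different grids"):
            require_same_grid(a, b)


class TestRasterIO:
    def test_identity_read(self, tmp_path):
        grid = GeoGrid(1.0, 0.0, 0.5, 2, 2)
        write_raster(Field(grid, np.full((2, 2), 5.0), "°C"), tmp_path / "t.asc")
        f = read_raster(tmp_path / "t.asc", "°C")
        assert f.valid.all()
        assert np.array_equal(f.values, np.full((2, 2), 5.0))

    def test_nodata_becomes_missing_exactly_there(self, tmp_path):
        grid = GeoGrid(1.0, 0.0, 0.5, 2, 2)
        vals = np.array([[1.0, NODATA], [3.0, 4.0]])
        (tmp_path / "t.asc").write_text(
            "ncols 2\nnrows 2\nxllcorner 0.0\nyllcorner 0.0\ncellsize 0.5\n"
            f"NODATA_value {NODATA:g}\n1.0 {NODATA:g}\n3.0 4.0\n")
        f = read_raster(tmp_path / "t.asc", "°C")
        assert f.missing.tolist() == [[False, True], [False, False]]
        assert f.grid == grid

    def test_round_trip_preserves_values_mask_and_grid(self, small_grid, rng, tmp_path):
        vals = rng.normal(25, 3, small_grid.shape)
        missing = rng.random(small_grid.shape) < 0.2
        f = Field(small_grid, vals, "°C", missing)
        write_raster(f, tmp_path / "r.asc")
        g = read_raster(tmp_path / "r.asc", "°C")
        assert g.grid == small_grid
        assert np.array_equal(g.missing, f.missing)
        assert np.allclose(g.values[g.valid], f.values[f.valid], atol=1e-9)

    def test_netcdf_round_trip(self, small_grid, rng, tmp_path):
        f = Field(small_grid, rng.normal(2, 0.5, small_grid.shape), "°C")
        write_raster(f, tmp_path / "w.nc")
        g = read_raster(tmp_path / "w.nc", "°C")
        assert g.grid == small_grid
        assert np.allclose(g.values, f.values, atol=1e-9)

    def test_netcdf_irregular_grid_rejected(self, tmp_path):
        import xarray as xr
        da = xr.DataArray(np.zeros((3, 3)), dims=("lat", "lon"),
                          coords={"lat": [0.0, 1.0, 3.0], "lon": [0.0, 1.0, 2.0]},
                          name="t")
        da.to_dataset().to_netcdf(tmp_path / "bad.nc", engine="scipy")
        with pytest.raises(ValueError, match="irregular"):
            read_raster(tmp_path / "bad.nc", "°C")

    def test_netcdf_unit_mismatch_rejected(self, small_grid, tmp_path):
        f = Field(small_grid, np.zeros(small_grid.shape), "t/ha")
        write_raster(f, tmp_path / "b.nc")
        with pytest.raises(ValueError, match="units"):
            read_raster(tmp_path / "b.nc", "°C")

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_raster("does-not-exist.asc", "°C")


def _fine_and_coarse(block=4, n=2):
    fine = GeoGrid(1.0, 0.0, 0.1, n * block, n * block)
    coarse = GeoGrid(1.0, 0.0, 0.1 * block, n, n)
    return fine, coarse


class TestAggregation:
    def test_fully_pasture_uniform(self):
        fine, coarse = _fine_and_coarse()
        b, frac = aggregate_biomass(make_field(fine, 10.0, "t/ha"),
                                    make_field(fine, 1.0, "categorical"), coarse)
        assert np.allclose(b.values, 10.0)
        assert np.allclose(frac.values, 1.0)

    def test_half_pasture_weighting(self):
        fine, coarse = _fine_and_coarse()
        mask = np.zeros(fine.shape)
        mask[:, ::2] = 1.0                      # half the cells of every block
        biomass = np.where(mask > 0, 20.0, 999.0)
        b, frac = aggregate_biomass(Field(fine, biomass, "t/ha"),
                                    Field(fine, mask, "categorical"), coarse)
        assert np.allclose(b.values, 10.0)      # 20 t/ha × fraction 0.5
        assert np.allclose(frac.values, 0.5)

    def test_no_pasture_block_gives_zero(self):
        fine, coarse = _fine_and_coarse()
        b, frac = aggregate_biomass(make_field(fine, 7.0, "t/ha"),
                                    make_field(fine, 0.0, "categorical"), coarse)
        assert np.all(b.values == 0.0) and np.all(frac.values == 0.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_random_blocks_match_brute_force_oracle(self, seed):
        """Block aggregation equals per-cell summation done by hand."""
        rng = np.random.default_rng(seed)
        fine, coarse = _fine_and_coarse(block=4, n=3)
        biomass = rng.uniform(0, 50, fine.shape)
        mask = (rng.random(fine.shape) < 0.6).astype(float)
        b, frac = aggregate_biomass(Field(fine, biomass, "t/ha"),
                                    Field(fine, mask, "categorical"), coarse)
        for i in range(coarse.n_rows):
            for j in range(coarse.n_cols):
                blk_b = biomass[4 * i:4 * i + 4, 4 * j:4 * j + 4]
                blk_m = mask[4 * i:4 * i + 4, 4 * j:4 * j + 4] > 0
                n_p = blk_m.sum()
                expect = (blk_b[blk_m].mean() * n_p / 16.0) if n_p else 0.0
                assert abs(b.values[i, j] - expect) < 1e-12
                assert abs(frac.values[i, j] - n_p / 16.0) < 1e-12

    def test_pasture_area_conserved(self, rng):
        fine, coarse = _fine_and_coarse(block=4, n=3)
        mask = (rng.random(fine.shape) < 0.37).astype(float)
        _, frac = aggregate_biomass(make_field(fine, 1.0, "t/ha"),
                                    Field(fine, mask, "categorical"), coarse)
        assert frac.values.sum() * 16 == pytest.approx(mask.sum())

    def test_conversion_commutes_with_aggregation(self, rng):
        fine, coarse = _fine_and_coarse()
        biomass = Field(fine, rng.uniform(0, 30, fine.shape), "t/ha")
        mask = Field(fine, (rng.random(fine.shape) < 0.5).astype(float), "categorical")
        via_coarse = biomass_to_carbon(aggregate_biomass(biomass, mask, coarse)[0])
        fine_carbon = biomass_to_carbon(biomass)
        fine_carbon_as_biomass = Field(fine, fine_carbon.values, "t/ha")
        via_fine = aggregate_biomass(fine_carbon_as_biomass, mask, coarse)[0]
        assert np.allclose(via_coarse.values, via_fine.values, atol=1e-12)

    def test_non_nesting_grids_rejected(self):
        fine = GeoGrid(1.0, 0.0, 0.1, 8, 8)
        coarse = GeoGrid(1.0, 0.0, 0.3, 3, 3)
        with pytest.raises(ValueError, match="nest"):
            aggregate_biomass(make_field(fine, 1.0, "t/ha"),
                              make_field(fine, 1.0, "categorical"), coarse)


class TestCarbonAndClasses:
    @pytest.mark.parametrize("biomass,carbon", [(100.0, 47.0), (0.0, 0.0), (10.0, 4.7)])
    def test_conversion_factor(self, small_grid, biomass, carbon):
        out = biomass_to_carbon(make_field(small_grid, biomass, "t/ha"))
        assert out.units == "tC/ha"
        assert np.allclose(out.values, carbon)

    def test_wrong_units_rejected(self, small_grid):
        with pytest.raises(ValueError, match="t/ha"):
            biomass_to_carbon(make_field(small_grid, 1.0, "°C"))

    def test_conversion_preserves_missing(self, small_grid):
        missing = np.zeros(small_grid.shape, bool)
        missing[0, 0] = True
        out = biomass_to_carbon(make_field(small_grid, 1.0, "t/ha", missing))
        assert out.missing[0, 0] and not out.missing[1, 1]

    @pytest.mark.parametrize("frac,included", [(0.51, True), (0.50, False), (0.0, False)])
    def test_coverage_rule_is_strict(self, small_grid, frac, included):
        mask = coverage_mask(make_field(small_grid, frac, "fraction"))
        assert mask.all() == included

    def test_coverage_missing_is_excluded(self, small_grid):
        missing = np.zeros(small_grid.shape, bool)
        missing[0, 0] = True
        mask = coverage_mask(make_field(small_grid, 0.9, "fraction", missing))
        assert not mask[0, 0] and mask[1, 1]

    @pytest.mark.parametrize("carbon,cls", [
        (0.5, "no_low"), (1.0, "no_low"),        # boundary to the lower class
        (1.01, "low"), (3.0, "low"), (5.0, "low"),
        (5.01, "silvopasture"), (6.0, "silvopasture"),
    ])
    def test_density_class_boundaries(self, carbon, cls):
        assert classify_density(carbon) == cls


class TestPixelTable:
    def _inputs(self, small_grid, uniform_biomes, carbon_value=6.0):
        t = make_field(small_grid, 30.0)
        c = make_field(small_grid, carbon_value, "tC/ha")
        frac = make_field(small_grid, 1.0, "fraction")
        return t, c, frac, uniform_biomes.codes_field()

    def test_all_missing_temperature_gives_empty_table(self, small_grid, uniform_biomes):
        t, c, frac, codes = self._inputs(small_grid, uniform_biomes)
        t = make_field(small_grid, 30.0, missing=np.ones(small_grid.shape, bool))
        table = build_pixel_table(t, c, frac, codes)
        assert len(table) == 0

    def test_single_eligible_pixel_classified_silvopasture(self, small_grid, uniform_biomes):
        t, c, frac, codes = self._inputs(small_grid, uniform_biomes, carbon_value=6.0)
        frac_vals = np.zeros(small_grid.shape)
        frac_vals[3, 4] = 0.8
        frac = Field(small_grid, frac_vals, "fraction")
        table = build_pixel_table(t, c, frac, codes)
        assert len(table) == 1
        assert table.iloc[0]["density_class"] == "silvopasture"
        assert table.iloc[0]["row"] == 3 and table.iloc[0]["col"] == 4

    def test_mid_density_pixel_classified_low(self, small_grid, uniform_biomes):
        t, c, frac, codes = self._inputs(small_grid, uniform_biomes, carbon_value=3.0)
        table = build_pixel_table(t, c, frac, codes)
        assert (table["density_class"] == "low").all()

    def test_grid_mismatch_rejected(self, small_grid, uniform_biomes):
        t, c, frac, codes = self._inputs(small_grid, uniform_biomes)
        other = GeoGrid(2.0, 10.0, 0.25, 8, 9)
        with pytest.raises(ValueError, match="different grids"):
            build_pixel_table(make_field(other, 30.0), c, frac, codes)
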