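"""Regional indicator arithmetic: totals, bloom areas, masks, convergence."""

import numpy as np
import pytest
import xarray as xr

from chla3d.fields import cell_areas_km2, layer_slice, make_grid
from chla3d.indicators import (RegionMask, default_bohai_regions, high_chla_area,
                               indicator_table, total_chla_integrated,
                               total_chla_mean_method)


def uniform_layer(grid, value):
    """A single-layer dataset with constant concentration over water."""
    conc = np.full(grid["water_mask"].shape, float(value))
    conc[~grid["water_mask"].values] = np.nan
    out = grid.copy()
    out["chla"] = (("lat", "lon"), conc)
    return out


@pytest.fixture()
def small_grid():
    return make_grid((119.0, 119.5), (38.0, 38.5), depths=(0.5,), resolution_deg=0.1)


class TestCellAreas:
    def test_band_area_matches_spherical_formula(self):
        lon = np.array([119.0, 119.1])
        lat = np.array([38.0, 38.1])
        areas = cell_areas_km2(lon, lat)
        R = 6371.0
        dlam = np.deg2rad(0.1)
        expected = R**2 * dlam * (np.sin(np.deg2rad(38.05)) - np.sin(np.deg2rad(37.95)))
        assert areas[0, 0] == pytest.approx(expected)
        # cells shrink toward the pole
        assert areas[1, 0] < areas[0, 0]


class TestIntegratedTotal:
    def test_uniform_field_is_c_times_area(self, small_grid):
        region = RegionMask.from_bbox("R", small_grid, (119.0, 119.5), (38.0, 38.5))
        layer = uniform_layer(small_grid, 2.0)
        got = total_chla_integrated(layer, region)
        assert got["total"] == pytest.approx(2.0 * region.area_km2)
        assert got["coverage"] == 1.0

    def test_additive_over_disjoint_regions(self, small_grid):
        west = RegionMask.from_bbox("W", small_grid, (119.0, 119.2), (38.0, 38.5))
        east = RegionMask.from_bbox("E", small_grid, (119.2, 119.5), (38.0, 38.5))
        union = RegionMask.from_bbox("U", small_grid, (119.0, 119.5), (38.0, 38.5))
        assert not (west.mask & east.mask).any()
        layer = uniform_layer(small_grid, 3.3)
        assert (total_chla_integrated(layer, west)["total"]
                + total_chla_integrated(layer, east)["total"]) == pytest.approx(
                    total_chla_integrated(layer, union)["total"])

    def test_three_by_three_hand_sum(self):
        grid = make_grid((119.0, 119.3), (38.0, 38.3), depths=(0.5,), resolution_deg=0.1)
        conc = np.arange(1.0, 10.0).reshape(3, 3)  # linear-gradient toy field
        layer = grid.copy()
        layer["chla"] = (("lat", "lon"), conc)
        region = RegionMask.from_bbox("R", grid, (118.9, 119.3), (37.9, 38.3))
        expected = float((conc * grid["cell_area_km2"].values).sum())
        assert total_chla_integrated(layer, region)["total"] == pytest.approx(expected)

    def test_missing_cells_counted_not_summed(self, small_grid):
        layer = uniform_layer(small_grid, 2.0)
        vals = layer["chla"].values
        vals[0, 0] = np.nan
        region = RegionMask.from_bbox("R", small_grid, (119.0, 119.5), (38.0, 38.5))
        got = total_chla_integrated(layer, region)
        assert got["n_missing"] == 1
        assert got["coverage"] < 1.0

    def test_grid_refinement_changes_smooth_total_under_2pct(self):
        def smooth_field(res):
            grid = make_grid((119.0, 120.0), (38.0, 39.0), depths=(0.5,),
                             resolution_deg=res)
            glon, glat = np.meshgrid(grid["lon"].values, grid["lat"].values)
            conc = 1.0 + 0.5 * np.sin(2 * np.pi * glon) * np.cos(2 * np.pi * glat)
            layer = grid.copy()
            layer["chla"] = (("lat", "lon"), conc)
            region = RegionMask.from_bbox("R", grid, (118, 121), (37, 40))
            return total_chla_integrated(layer, region)["total"]

        coarse, fine = smooth_field(0.05), smooth_field(0.025)
        assert abs(fine - coarse) / abs(fine) < 0.02


class TestMeanMethodTotal:
    def test_mean_times_area(self):
        assert total_chla_mean_method([1.0, 3.0], 10.0) == pytest.approx(20.0)

    def test_agrees_with_integration_on_constant_field(self, small_grid):
        region = RegionMask.from_bbox("R", small_grid, (119.0, 119.5), (38.0, 38.5))
        layer = uniform_layer(small_grid, 4.2)
        integ = total_chla_integrated(layer, region)["total"]
        mean_m = total_chla_mean_method([4.2, 4.2, 4.2], region.area_km2)
        assert mean_m == pytest.approx(integ, rel=1e-12)

    def test_no_stations_is_an_error(self):
        with pytest.raises(ValueError):
            total_chla_mean_method([], 10.0)


class TestBloomArea:
    def test_all_above_and_all_below(self, small_grid):
        region = RegionMask.from_bbox("R", small_grid, (119.0, 119.5), (38.0, 38.5))
        assert high_chla_area(uniform_layer(small_grid, 12.0), region) == pytest.approx(
            region.area_km2)
        assert high_chla_area(uniform_layer(small_grid, 9.9), region) == 0.0

    def test_threshold_is_strict(self, small_grid):
        region = RegionMask.from_bbox("R", small_grid, (119.0, 119.5), (38.0, 38.5))
        assert high_chla_area(uniform_layer(small_grid, 10.0), region, threshold=10.0) == 0.0

    def test_monotone_nonincreasing_in_threshold(self, small_grid, rng):
        layer = uniform_layer(small_grid, 1.0)
        layer["chla"].values[:] = 10.0 ** rng.uniform(-1, 1.5, layer["chla"].shape)
        region = RegionMask.from_bbox("R", small_grid, (119.0, 119.5), (38.0, 38.5))
        areas = [high_chla_area(layer, region, threshold=t) for t in (5, 10, 15)]
        assert areas[0] >= areas[1] >= areas[2]

    def test_subregions_plus_remainder_cover_domain(self, small_grid, rng):
        layer = uniform_layer(small_grid, 1.0)
        layer["chla"].values[:] = 10.0 ** rng.uniform(0.5, 1.5, layer["chla"].shape)
        whole = RegionMask.from_bbox("ALL", small_grid, (119.0, 119.5), (38.0, 38.5))
        west = RegionMask.from_bbox("W", small_grid, (119.0, 119.2), (38.0, 38.5))
        east = RegionMask.from_bbox("E", small_grid, (119.2, 119.5), (38.0, 38.5))
        total = high_chla_area(layer, whole)
        assert high_chla_area(layer, west) + high_chla_area(layer, east) == pytest.approx(total)

    def test_bad_threshold(self, small_grid):
        region = RegionMask.from_bbox("R", small_grid, (119.0, 119.5), (38.0, 38.5))
        with pytest.raises(ValueError):
            high_chla_area(uniform_layer(small_grid, 1.0), region, threshold=0.0)


class TestRegionMask:
    def test_empty_region_rejected(self, small_grid):
        with pytest.raises(ValueError, match="empty"):
            RegionMask.from_bbox("X", small_grid, (10.0, 11.0), (0.0, 1.0))

    def test_geojson_polygon_matches_bbox(self, small_grid):
        geom = {"type": "Polygon", "coordinates": [[
            (119.0, 38.0), (119.5, 38.0), (119.5, 38.5), (119.0, 38.5), (119.0, 38.0),
        ]]}
        from_poly = RegionMask.from_geojson("P", small_grid, geom)
        from_box = RegionMask.from_bbox("B", small_grid, (119.0, 119.5), (38.0, 38.5))
        # boundary cells may differ by the strictness of `contains`; interiors agree
        interior = from_box.mask.copy()
        interior[[0, -1], :] = False
        interior[:, [0, -1]] = False
        assert (from_poly.mask & interior).sum() == interior.sum()

    def test_default_bohai_regions_disjoint(self):
        grid = make_grid(resolution_deg=0.2)
        regions = default_bohai_regions(grid)
        assert {r.name for r in regions} == {"BHB", "LDB", "LZB", "CBS"}
        for i, a in enumerate(regions):
            for b in regions[i + 1:]:
                assert not (a.mask & b.mask).any()


class TestIndicatorTable:
    def test_tidy_table_shape_and_columns(self, truth_field, paperlike_stations):
        regions = default_bohai_regions(truth_field)
        tbl = indicator_table(truth_field, regions, stations=paperlike_stations,
                              layer_depths=(0.5, 10.0))
        assert len(tbl) == 2 * len(regions)
        assert {"region", "layer_m", "total_integrated", "total_mean_method",
                "bloom_area_km2", "coverage"} <= set(tbl.columns)
        assert (tbl["total_integrated"] > 0).all()
        # the 10 m layer holds less chlorophyll than the surface everywhere
        surf = tbl[tbl["layer_m"] == 0.5].set_index("region")["total_integrated"]
        deep = tbl[tbl["layer_m"] == 10.0].set_index("region")["total_integrated"]
        assert (deep < surf).all()
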