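"""Gridded climate fields: I/O, reductions, site series and isoscapes."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from elasmoiso import climate, isotopes, synthetic
from elasmoiso.climate import (
    ClimateGrid,
    GridLoadError,
    SiteSpec,
    climatology_mean,
    depth_average,
    extract_site_series,
    isoscape,
    load_grid,
    save_grid,
)


def _tiny_grid(t_values, w_values, lats=(-65.0, -64.0), lons=(-58.0, -57.0)):
    """Build a small ClimateGrid from per-cell (lat, lon) values, constant in month."""
    t = np.broadcast_to(np.asarray(t_values, dtype=float), (12, len(lats), len(lons))).copy()
    w = np.broadcast_to(np.asarray(w_values, dtype=float), (12, len(lats), len(lons))).copy()
    ds = xr.Dataset(
        {
            "temperature": (("month", "lat", "lon"), t),
            "d18Ow": (("month", "lat", "lon"), w),
        },
        coords={"month": np.arange(1, 13), "lat": list(lats), "lon": list(lons)},
    )
    return ClimateGrid(ds)


class TestIO:
    def test_netcdf_round_trip(self, grid_3x, tmp_path):
        p = tmp_path / "grid.nc"
        save_grid(grid_3x, p)
        back = load_grid(p)
        assert back.co2_case == grid_3x.co2_case
        assert back.equals(grid_3x)

    def test_csv_and_netcdf_encodings_agree(self, grid_3x, tmp_path):
        pn, pc = tmp_path / "g.nc", tmp_path / "g.csv"
        save_grid(grid_3x, pn)
        save_grid(grid_3x, pc)
        from_nc = load_grid(pn)
        from_csv = load_grid(pc)
        assert from_nc.equals(from_csv)
        assert from_csv.co2_case == grid_3x.co2_case

    def test_missing_variable_named_in_error(self, grid_3x, tmp_path):
        p = tmp_path / "broken.csv"
        df = grid_3x.data.to_dataframe().reset_index().drop(columns=["d18Ow"])
        df.to_csv(p, index=False)
        with pytest.raises(GridLoadError, match="d18Ow"):
            load_grid(p)

    def test_incomplete_months_rejected(self, grid_3x):
        ds = grid_3x.data.sel(month=[1, 2, 3])
        with pytest.raises(GridLoadError, match="month"):
            ClimateGrid(ds)

    def test_longitude_normalized_to_pm180(self, grid_3x):
        ds = grid_3x.data.assign_coords(lon=(grid_3x.data["lon"] + 360.0) % 360.0)
        norm = ClimateGrid(ds)
        assert norm.data["lon"].min() >= -180.0
        assert norm.data["lon"].max() < 180.0
        assert norm.equals(grid_3x)


class TestDepthAverage:
    def test_uniform_profile_is_identity(self):
        v = np.full(3, 7.5)
        out = depth_average(v, [0.0, 10.0, 20.0], [10.0, 20.0, 30.0], max_depth=25.0)
        assert out == pytest.approx(7.5)

    def test_equal_thickness_layers(self):
        out = depth_average(
            np.array([10.0, 20.0]), [0.0, 12.5], [12.5, 25.0], max_depth=25.0
        )
        assert out == pytest.approx(15.0)

    def test_partial_bottom_layer_clipped(self):
        out = depth_average(
            np.array([10.0, 30.0]), [0.0, 20.0], [20.0, 40.0], max_depth=25.0
        )
        assert out == pytest.approx(14.0)

    def test_no_levels_above_max_depth_errors(self):
        with pytest.raises(ValueError):
            depth_average(np.array([5.0]), [30.0], [40.0], max_depth=25.0)

    def test_bounded_by_contributing_layers(self, rng):
        v = rng.uniform(-2, 20, 5)
        tops = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
        out = depth_average(v, tops, tops + 5.0, max_depth=22.0)
        assert v.min() <= out <= v.max()


class TestClimatology:
    def test_identical_years_equal_any_year(self):
        multi = synthetic.make_multiyear_fields(n_years=5, interannual_sd=0.0, seed=3)
        mean = climatology_mean(multi, last_n_years=5)
        xr.testing.assert_allclose(mean, multi.isel(year=0).drop_vars("year"))

    def test_trailing_window_mean(self):
        years = np.arange(1, 5)
        t = years[:, None, None, None] * np.ones((1, 12, 1, 1))
        ds = xr.Dataset(
            {"temperature": (("year", "month", "lat", "lon"), t),
             "d18Ow": (("year", "month", "lat", "lon"), t * 0.0)},
            coords={"year": years, "month": np.arange(1, 13), "lat": [0.0], "lon": [0.0]},
        )
        out = climatology_mean(ds, last_n_years=2)
        assert float(out["temperature"].isel(month=0, lat=0, lon=0)) == pytest.approx(3.5)

    def test_window_longer_than_record_errors(self):
        multi = synthetic.make_multiyear_fields(n_years=3, seed=0)
        with pytest.raises(ValueError):
            climatology_mean(multi, last_n_years=100)


class TestSiteSeries:
    def test_single_cell_site_returns_cell_series(self, grid_3x):
        lat = float(grid_3x.data["lat"][5])
        lon = float(grid_3x.data["lon"][5])
        site = SiteSpec("cell", (lat - 0.01, lat + 0.01), (lon - 0.01, lon + 0.01))
        env = extract_site_series(grid_3x, site)
        cell = grid_3x.data.sel(lat=lat, lon=lon)
        np.testing.assert_allclose(env.temperature, cell["temperature"], atol=1e-12)

    def test_two_cells_equal_latitude_average_equally(self):
        g = _tiny_grid([[10.0, 20.0]], [[-1.0, -1.0]], lats=(-64.0,), lons=(-58.0, -57.0))
        env = extract_site_series(g, SiteSpec("pair", (-65, -63), (-59, -56)))
        assert env.temperature[0] == pytest.approx(15.0)

    def test_seasonal_extrema_in_march_and_september(self, seymour_envelope):
        assert seymour_envelope.warmest_month == 3
        assert seymour_envelope.coldest_month in (9, 10)

    def test_all_land_site_errors(self, grid_3x):
        # the synthetic continent sits north of -52
        site = SiteSpec("land", (-51.5, -50.0), (-80.0, -40.0))
        with pytest.raises(ValueError, match="ocean"):
            extract_site_series(grid_3x, site)

    def test_derived_series_match_elementwise_transforms(self, seymour_envelope):
        np.testing.assert_allclose(
            seymour_envelope.d18Op_star,
            isotopes.predict_d18Op(seymour_envelope.temperature, seymour_envelope.d18Ow),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            seymour_envelope.d18Oc_star,
            isotopes.predict_d18Oc(seymour_envelope.temperature, seymour_envelope.d18Ow),
            atol=1e-12,
        )


class TestIsoscape:
    def test_constant_field_gives_zero_sd(self):
        g = _tiny_grid([[13.9, 13.9], [13.9, 13.9]], -1.0)
        _, summ = isoscape(g, SiteSpec("box", (-66, -63), (-59, -56)))
        assert summ["mean"] == pytest.approx(22.0, abs=1e-9)
        assert summ["sd"] == pytest.approx(0.0, abs=1e-9)

    def test_two_cell_sample_sd_convention(self):
        # cells at the same latitude predicting 20 and 22 permil
        t20 = 117.4 - 4.5 * (20.0 - (-1.0))
        t22 = 117.4 - 4.5 * (22.0 - (-1.0))
        g = _tiny_grid([[t20, t22]], -1.0, lats=(-64.0,), lons=(-58.0, -57.0))
        _, summ = isoscape(g, SiteSpec("pair", (-65, -63), (-59, -56)))
        assert summ["mean"] == pytest.approx(21.0, abs=1e-9)
        assert summ["sd"] == pytest.approx(np.sqrt(2.0), abs=1e-9)
        assert summ["mean_plus_2sd"] == pytest.approx(21.0 + 2 * np.sqrt(2.0), abs=1e-9)

    def test_missing_cells_excluded(self):
        g = _tiny_grid([[13.9, np.nan]], -1.0, lats=(-64.0,), lons=(-58.0, -57.0))
        _, summ = isoscape(g, SiteSpec("pair", (-65, -63), (-59, -56)))
        assert summ["n_cells"] == 1
        assert summ["mean"] == pytest.approx(22.0, abs=1e-6)

    def test_matches_elementwise_forward_prediction(self, grid_3x):
        region = SiteSpec("box", (-70, -60), (-70, -50))
        field, _ = isoscape(grid_3x, region, month_aggregation="per_month")
        sub = grid_3x.subset(region)
        expected = isotopes.predict_d18Op(sub["temperature"].values, sub["d18Ow"].values)
        np.testing.assert_allclose(field.values, expected, atol=1e-12)

    def test_empty_region_errors(self, grid_3x):
        with pytest.raises(ValueError):
            isoscape(grid_3x, SiteSpec("off-grid", (30, 40), (0, 10)))

    def test_map_renders_to_image(self, grid_3x, tmp_path):
        field, _ = isoscape(grid_3x, SiteSpec("box", (-70, -60), (-70, -50)))
        out = tmp_path / "iso.png"
        climate.plot_isoscape(field, out, title="test")
        assert out.stat().st_size > 0


class TestAreaWeightingInvariance:
    def test_longitude_order_invariance(self, grid_3x):
        region = SiteSpec("box", (-70, -60), (-70, -50))
        _, s1 = isoscape(grid_3x, region)
        flipped = ClimateGrid(
            grid_3x.data.isel(lon=slice(None, None, -1)),
            co2_case=grid_3x.co2_case,
        )
        _, s2 = isoscape(flipped, region)
        assert s1["mean"] == pytest.approx(s2["mean"], abs=1e-9)

    def test_split_and_recombine_with_weights(self, grid_3x):
        region = SiteSpec("box", (-70, -60), (-70, -50))
        west = SiteSpec("w", (-70, -60), (-70, -60.5))
        east = SiteSpec("e", (-70, -60), (-60.4, -50))
        env = extract_site_series(grid_3x, region)
        env_w = extract_site_series(grid_3x, west)
        env_e = extract_site_series(grid_3x, east)
        # recombine with ocean-cell cos-lat weights
        def wsum(site):
            sub = grid_3x.subset(site)
            ocean = sub["temperature"].notnull().all("month")
            w = np.cos(np.deg2rad(sub["lat"])).broadcast_like(ocean).where(ocean)
            return float(w.sum())
        ww, we = wsum(west), wsum(east)
        combined = (env_w.temperature * ww + env_e.temperature * we) / (ww + we)
        np.testing.assert_allclose(combined, env.temperature, atol=1e-9)
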