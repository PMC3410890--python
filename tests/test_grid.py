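"""Grid pipeline: masks, areas, cell runs, aggregation and site comparison."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

import soilghg as sg
from soilghg.grid import DEFAULT_BIN_WIDTH, EARTH_RADIUS_M, make_climate_grid, make_soil_grid


def tiny_soil(bd=1.2, **flags):
    return make_soil_grid(
        [0.25], [0.25], cnr=[[15.0]], bd=[[bd]], sand_pct=[[40.0]], clay_pct=[[20.0]],
        flags={k: [[v]] for k, v in flags.items()},
    )


class TestMask:
    def test_peat_threshold_inclusive(self):
        assert not sg.build_mask(tiny_soil(bd=0.28)).values[0, 0]
        assert sg.build_mask(tiny_soil(bd=0.29)).values[0, 0]

    def test_surface_flags_exclude(self):
        assert not sg.build_mask(tiny_soil(bd=1.2, flag_mangrove=True)).values[0, 0]
        assert not sg.build_mask(tiny_soil(bd=1.2, flag_ice=True)).values[0, 0]
        assert not sg.build_mask(tiny_soil(bd=1.2, flag_water=True)).values[0, 0]

    def test_missing_property_excludes(self):
        soil = tiny_soil()
        soil["cnr"][0, 0] = np.nan
        assert not sg.build_mask(soil).values[0, 0]


class TestCellArea:
    def test_full_sphere_partition(self):
        lat = np.linspace(-90, 90, 37)[:-1] + 2.5
        lon = np.linspace(-180, 180, 73)[:-1] + 2.5
        total = float(sg.cell_areas(lat, lon).sum())
        assert total == pytest.approx(4 * np.pi * EARTH_RADIUS_M**2, rel=1e-12)

    def test_mirrored_latitudes_equal(self):
        north = sg.cell_area((40.0, 40.5), (0.0, 0.5))
        south = sg.cell_area((-40.5, -40.0), (0.0, 0.5))
        assert north == pytest.approx(south, rel=1e-12)

    def test_equatorial_half_degree_cell(self):
        # oracle: numerical integration of cos(phi) gives the same value
        assert sg.cell_area((-0.25, 0.25), (0.0, 0.5)) == pytest.approx(3_091_068_119.6, rel=1e-9)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            sg.cell_area((10.0, 10.0), (0.0, 0.5))

    def test_resolution_refinement_conserves_area(self):
        lat1 = np.linspace(-90, 90, 19)[:-1] + 5.0
        lon1 = np.linspace(-180, 180, 37)[:-1] + 5.0
        lat2 = np.linspace(-90, 90, 37)[:-1] + 2.5
        lon2 = np.linspace(-180, 180, 73)[:-1] + 2.5
        a1 = float(sg.cell_areas(lat1, lon1).sum())
        a2 = float(sg.cell_areas(lat2, lon2).sum())
        assert abs(a1 - a2) / a2 < 1e-3


class TestRunCell:
    def test_pinned_factors_give_soil_factor_every_month(self, params):
        """Climate pinned so g = 1 and h = 1: CO2 flux equals f(SP)."""
        lp = params.land()
        soil = sg.SoilPhysiochem(cnr=15.0, bd=1.2, sand_pct=40.0, clay_pct=20.0)
        # air temperature such that the linear soil-temperature line gives 0 C
        t_air = (0.0 - lp.i_st) / lp.s_st
        ws0 = sg.saxton_ws0(40.0, 20.0, 1.2)
        # pin the moisture state at its optimum and keep the cell snow-free and unfrozen
        params2 = params.with_values(
            {
                "co2.wfps_b": ws0,
                "land.wfps_lnr_slope": 0.0,
                "land.t_w": t_air - 1.0,
                "land.t_snow": t_air - 10.0,
                "land.t_melt": t_air - 9.0,
            }
        )
        out = sg.run_cell(
            np.full(24, t_air), np.full(24, 50.0), 40.0,
            soil, params2, np.full(24, params.ch4_reference_ppb),
        )
        expected = sg.f_sp(params2.gas("co2"), soil)
        assert np.allclose(out["co2"], expected, rtol=1e-6)

    def test_frozen_snowbound_cell_has_constant_flux(self, params):
        out = sg.run_cell(
            np.full(24, -15.0), np.full(24, 30.0), 65.0,
            sg.SoilPhysiochem(cnr=15.0, bd=1.2, sand_pct=40.0, clay_pct=20.0),
            params, np.full(24, params.ch4_reference_ppb),
        )
        for gas in ("co2", "ch4", "n2o"):
            assert np.allclose(out[gas], out[gas].iloc[0])

    def test_doubling_ch4_series_doubles_only_ch4(self, params):
        t = 12.0 + 8.0 * np.cos(np.arange(24) * np.pi / 6)
        pre = np.full(24, 60.0)
        soil = sg.SoilPhysiochem(cnr=15.0, bd=1.0, sand_pct=40.0, clay_pct=20.0)
        ref = np.full(24, params.ch4_reference_ppb)
        base = sg.run_cell(t, pre, 40.0, soil, params, ref)
        doubled = sg.run_cell(t, pre, 40.0, soil, params, 2 * ref)
        assert np.allclose(doubled["ch4"], 2 * base["ch4"])
        assert np.allclose(doubled["co2"], base["co2"])
        assert np.allclose(doubled["n2o"], base["n2o"])

    def test_length_mismatch_rejected(self, params):
        soil = sg.SoilPhysiochem(cnr=15.0, bd=1.0, sand_pct=40.0, clay_pct=20.0)
        with pytest.raises(ValueError):
            sg.run_cell(np.zeros(24), np.zeros(23), 0.0, soil, params, np.full(24, 1790.0))


class TestAggregation:
    def _uniform_flux(self, co2=1.0, ch4=0.0, n2o=0.0):
        lat, lon = [0.25, 0.75], [0.25]
        shape = (12, 2, 1)
        ds = xr.Dataset(
            {
                "co2": (("time", "lat", "lon"), np.full(shape, co2)),
                "ch4": (("time", "lat", "lon"), np.full(shape, ch4)),
                "n2o": (("time", "lat", "lon"), np.full(shape, n2o)),
            },
            coords={
                "time": np.arange(12),
                "year": ("time", np.repeat(2000, 12)),
                "month": ("time", np.arange(1, 13)),
                "lat": lat,
                "lon": lon,
            },
        )
        return ds

    def test_constant_rates_integrate_to_hand_values(self):
        """1 ug/m2/s over a 365-day year -> 31.536 g; 1 ug/m2/h -> 8.76e-3 g."""
        annual = sg.monthly_to_annual(self._uniform_flux(co2=1.0, ch4=1.0, n2o=1.0))
        assert float(annual["co2"][0, 0, 0]) == pytest.approx(31.536, rel=1e-12)
        assert float(annual["ch4"][0, 0, 0]) == pytest.approx(8.76e-3, rel=1e-12)
        assert float(annual["n2o"][0, 0, 0]) == pytest.approx(8.76e-3, rel=1e-12)

    def test_zero_flux_gives_zero_annual(self):
        annual = sg.monthly_to_annual(self._uniform_flux(co2=0.0))
        assert float(annual["co2"].sum()) == 0.0

    def test_partial_year_rejected(self):
        flux = self._uniform_flux().isel(time=slice(0, 7))
        with pytest.raises(ValueError):
            sg.monthly_to_annual(flux)

    def test_global_total_arithmetic(self):
        """Uniform 100 g C m-2 yr-1 over 1e12 m2 is 0.1 Pg C yr-1."""
        annual = xr.Dataset(
            {g: (("lat", "lon"), np.full((1, 1), 100.0)) for g in ("co2", "ch4", "n2o")},
            coords={"lat": [0.0], "lon": [0.0]},
        )
        areas = xr.DataArray(np.full((1, 1), 1e12), coords=annual.coords, dims=("lat", "lon"))
        totals = sg.global_total(annual, areas)
        assert totals["co2"] == pytest.approx(0.1)
        assert totals["ch4"] == pytest.approx(100.0)  # Tg

    def test_masked_cell_contributes_nothing(self):
        vals = np.array([[100.0, np.nan]])
        annual = xr.Dataset(
            {g: (("lat", "lon"), vals) for g in ("co2", "ch4", "n2o")},
            coords={"lat": [0.0], "lon": [0.0, 1.0]},
        )
        areas = xr.DataArray(np.full((1, 2), 1e12), coords=annual.coords, dims=("lat", "lon"))
        assert sg.global_total(annual, areas)["co2"] == pytest.approx(0.1)

    def test_annual_then_total_equals_monthly_then_total(self, flux_field, world):
        climate, _, _ = world
        areas = sg.cell_areas(climate["lat"].values, climate["lon"].values)
        annual = sg.monthly_to_annual(flux_field)
        via_annual = sg.global_total(annual, areas)
        # aggregate monthly totals directly: sum over months of rate*duration*area
        days = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)
        months = flux_field["month"].values
        nyears = len(np.unique(flux_field["year"].values))
        dur_s = days[months - 1] * 86400.0
        dur_h = days[months - 1] * 24.0
        direct = {}
        for gas, dur in (("co2", dur_s), ("ch4", dur_h), ("n2o", dur_h)):
            monthly_g = flux_field[gas].values * dur[:, None, None] * 1e-6
            direct[gas] = np.nansum(np.nansum(monthly_g, axis=0) / nyears * areas.values)
        assert via_annual["co2"] == pytest.approx(direct["co2"] * 1e-15, rel=1e-12)
        assert via_annual["ch4"] == pytest.approx(direct["ch4"] * 1e-12, rel=1e-12)


class TestZones:
    @pytest.mark.parametrize(
        "mat,zone",
        [(1.99, "boreal"), (2.0, "temperate"), (17.0, "temperate"), (17.000001, "tropical")],
    )
    def test_boundary_conventions(self, mat, zone):
        assert sg.classify_zone(mat) == zone

    def test_single_zone_grid_fraction_one(self):
        annual = xr.Dataset(
            {g: (("lat", "lon"), np.full((2, 2), 10.0)) for g in ("co2", "ch4", "n2o")},
            coords={"lat": [0.0, 1.0], "lon": [0.0, 1.0]},
        )
        mat = xr.DataArray(np.full((2, 2), 25.0), coords=annual.coords, dims=("lat", "lon"))
        areas = xr.DataArray(np.full((2, 2), 1e10), coords=annual.coords, dims=("lat", "lon"))
        fr = sg.zone_contributions(annual, mat, areas)
        assert fr["co2"]["tropical"] == pytest.approx(1.0)
        assert fr["co2"]["boreal"] == 0.0

    def test_fractions_partition_unity(self, flux_field, world):
        climate, _, _ = world
        areas = sg.cell_areas(climate["lat"].values, climate["lon"].values)
        annual = sg.monthly_to_annual(flux_field)
        fr = sg.zone_contributions(annual, sg.mean_annual_temperature(climate), areas)
        for gas in fr:
            assert sum(fr[gas].values()) == pytest.approx(1.0, abs=1e-12)

    def test_zone_totals_sum_to_global(self, flux_field, world):
        climate, _, _ = world
        areas = sg.cell_areas(climate["lat"].values, climate["lon"].values)
        annual = sg.monthly_to_annual(flux_field)
        totals = sg.global_total(annual, areas)
        fr = sg.zone_contributions(annual, sg.mean_annual_temperature(climate), areas)
        for gas in totals:
            assert totals[gas] == pytest.approx(totals[gas] * sum(fr[gas].values()), rel=1e-12)


class TestLatMonthMatrix:
    def test_uniform_field_constant_matrix(self):
        lat, lon = [10.25, 10.75], [0.25]
        shape = (12, 2, 1)
        flux = xr.Dataset(
            {g: (("time", "lat", "lon"), np.full(shape, 3.0)) for g in ("co2", "ch4", "n2o")},
            coords={
                "time": np.arange(12),
                "year": ("time", np.repeat(2000, 12)),
                "month": ("time", np.arange(1, 13)),
                "lat": lat,
                "lon": lon,
            },
        )
        areas = sg.cell_areas(np.array(lat), np.array(lon))
        mats = sg.latitudinal_seasonal_matrix(flux, areas, band_width=1.0)
        assert np.allclose(mats["co2"].values, 3.0)

    def test_two_cell_band_weighted_mean(self):
        lat = np.array([10.2, 10.4])
        lon = np.array([0.25])
        vals = np.zeros((12, 2, 1))
        vals[:, 0, 0] = 2.0
        vals[:, 1, 0] = 6.0
        flux = xr.Dataset(
            {g: (("time", "lat", "lon"), vals) for g in ("co2", "ch4", "n2o")},
            coords={
                "time": np.arange(12),
                "year": ("time", np.repeat(2000, 12)),
                "month": ("time", np.arange(1, 13)),
                "lat": lat,
                "lon": lon,
            },
        )
        areas = sg.cell_areas(lat, lon)
        w = areas.values[:, 0]
        expected = (2.0 * w[0] + 6.0 * w[1]) / w.sum()
        mats = sg.latitudinal_seasonal_matrix(flux, areas, band_width=1.0)
        assert mats["n2o"].shape == (1, 12)
        assert np.allclose(mats["n2o"].values, expected)


class TestHistogram:
    def test_single_value_single_bin(self):
        field = xr.DataArray(np.full((3, 3), 320.0), dims=("lat", "lon"))
        counts, edges = sg.flux_histogram(field, DEFAULT_BIN_WIDTH["co2"])
        assert counts.sum() == 9
        idx = np.searchsorted(edges, 320.0, side="right") - 1
        assert counts[idx] == 9

    def test_counts_conserved_under_bin_width(self):
        field = xr.DataArray(np.array([[10.0, 200.0], [np.nan, 431.0]]), dims=("lat", "lon"))
        for width in (50.0, 150.0, 300.0):
            counts, _ = sg.flux_histogram(field, width)
            assert counts.sum() == 3

    def test_hand_binned_toy_field(self):
        field = xr.DataArray(np.array([[100.0, 160.0, 310.0]]), dims=("lat", "lon"))
        counts, edges = sg.flux_histogram(field, 150.0)
        assert list(counts) == [1, 1, 1]
        assert edges[0] == 0.0 and edges[-1] == pytest.approx(450.0)


class TestSiteComparison:
    def _annual_field(self):
        lat = np.array([0.25, 0.75])
        lon = np.array([0.25, 0.75])
        vals = np.array([[100.0, 200.0], [np.nan, 400.0]])
        return xr.DataArray(vals, coords={"lat": lat, "lon": lon}, dims=("lat", "lon"))

    def test_perfect_agreement(self):
        field = self._annual_field()
        sites = pd.DataFrame(
            {"lat": [0.25, 0.25, 0.75], "lon": [0.25, 0.75, 0.75],
             "annual_flux": [100.0, 200.0, 400.0]}
        )
        out = sg.compare_with_sites(field, sites)
        assert out["r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(1.0)
        assert out["intercept"] == pytest.approx(0.0, abs=1e-9)

    def test_masked_cell_site_dropped(self):
        field = self._annual_field()
        sites = pd.DataFrame(
            {"lat": [0.25, 0.75, 0.75], "lon": [0.25, 0.25, 0.75],
             "annual_flux": [100.0, 999.0, 400.0]}
        )
        out = sg.compare_with_sites(field, sites)
        assert out["n"] == 2  # the site at (0.75, 0.25) falls on NaN

    def test_pearson_matches_textbook_formula(self, rng):
        field = self._annual_field()
        sites = pd.DataFrame(
            {"lat": [0.25, 0.25, 0.75, 0.25, 0.75],
             "lon": [0.25, 0.75, 0.75, 0.25, 0.75],
             "annual_flux": [120.0, 180.0, 390.0, 95.0, 410.0]}
        )
        out = sg.compare_with_sites(field, sites)
        x = np.array([100.0, 200.0, 400.0, 100.0, 400.0])
        y = sites["annual_flux"].to_numpy()
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert out["r"] == pytest.approx(r_hand, rel=1e-12)

    def test_empty_intersection_raises(self):
        field = self._annual_field()
        sites = pd.DataFrame({"lat": [50.0], "lon": [50.0], "annual_flux": [1.0]})
        with pytest.raises(ValueError):
            sg.compare_with_sites(field, sites)

    def test_declarative_filters(self):
        from soilghg.grid import filter_site_rows

        df = pd.DataFrame(
            {
                "ecosystem": ["forest", "agriculture", "forest", "forest", "forest"],
                "manipulation": ["none", "none", "warming", "none", "none"],
                "method": ["IRGA", "IRGA", "IRGA", "soda lime", "GC"],
                "quality_flag": ["Q01", "Q02", "Q03", "Q01", "Q10"],
            }
        )
        kept = filter_site_rows(df)
        assert list(kept.index) == [0]
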