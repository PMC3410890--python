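"""Gridded simulation pipeline and aggregation products.

Drives the land-surface and flux submodels over a lat/lon domain and a
span of whole calendar years, then turns the native-rate monthly flux
fields into the reporting products: per-cell annual fluxes, global totals
(Pg C / Tg C / Tg N per year), climate-zone contributions, latitude-month
matrices and per-cell flux histograms.

Grids are :class:`xarray.Dataset` objects.  A climate grid carries
``t_air`` (degC) and ``pre`` (mm per month) on (time, lat, lon) with
integer ``year``/``month`` coordinates along time; a soil grid carries the
0-5 cm properties ``cnr``, ``bd``, ``sand_pct``, ``clay_pct`` plus boolean
surface flags (``flag_ice``, ``flag_water``, ``flag_mangrove``) and an
optional per-cell ``ws0``; a flux field carries ``co2``, ``ch4``, ``n2o``
in their native units on (time, lat, lon).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
import xarray as xr

from . import land
from .fluxes import SoilPhysiochem, f_sp, g_wfps, h_temp, j_ch4
from .land import NOLEAP_MONTH_DAYS, CellState, LandSurfaceParams
from .params import Gas, ParameterSet

__all__ = [
    "EARTH_RADIUS_M",
    "PEAT_BD_THRESHOLD",
    "make_climate_grid",
    "make_soil_grid",
    "build_mask",
    "cell_area",
    "cell_areas",
    "run_cell",
    "run_grid",
    "monthly_to_annual",
    "global_total",
    "mean_annual_temperature",
    "classify_zone",
    "zone_contributions",
    "latitudinal_seasonal_matrix",
    "flux_histogram",
    "filter_site_rows",
    "compare_with_sites",
]

EARTH_RADIUS_M = 6_371_000.0
#: bulk density at or below which a cell is excluded as presumed peat (Mg m-3)
PEAT_BD_THRESHOLD = 0.28

SURFACE_FLAGS = ("flag_ice", "flag_water", "flag_mangrove")
SOIL_PROPS = ("cnr", "bd", "sand_pct", "clay_pct")

_SECONDS = {"co2": 86_400.0}  # CO2 rates are per second; CH4/N2O per hour


# ---------------------------------------------------------------------------
# container constructors


def _check_axis(values, name):
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 1:
        raise ValueError(f"{name} must be a 1-D axis")
    if len(values) > 1 and not (np.all(np.diff(values) > 0) or np.all(np.diff(values) < 0)):
        raise ValueError(f"{name} axis must be strictly monotone")
    return values


def make_climate_grid(lat, lon, years, t_air, pre) -> xr.Dataset:
    """Assemble a climate grid from arrays of shape (nyears*12, nlat, nlon)."""
    lat = _check_axis(lat, "lat")
    lon = _check_axis(lon, "lon")
    years = np.asarray(years, dtype=int)
    t_air = np.asarray(t_air, dtype=float)
    pre = np.asarray(pre, dtype=float)
    ntime = len(years) * 12
    if t_air.shape != (ntime, len(lat), len(lon)) or pre.shape != t_air.shape:
        raise ValueError("t_air and pre must have shape (nyears*12, nlat, nlon)")
    if np.any(pre < 0):
        raise ValueError("precipitation must be non-negative")
    year_coord = np.repeat(years, 12)
    month_coord = np.tile(np.arange(1, 13), len(years))
    return xr.Dataset(
        {
            "t_air": (("time", "lat", "lon"), t_air),
            "pre": (("time", "lat", "lon"), pre),
        },
        coords={
            "time": np.arange(ntime),
            "year": ("time", year_coord),
            "month": ("time", month_coord),
            "lat": lat,
            "lon": lon,
        },
    )


def make_soil_grid(lat, lon, cnr, bd, sand_pct, clay_pct, flags=None, ws0=None) -> xr.Dataset:
    lat = _check_axis(lat, "lat")
    lon = _check_axis(lon, "lon")
    data = {
        "cnr": (("lat", "lon"), np.asarray(cnr, dtype=float)),
        "bd": (("lat", "lon"), np.asarray(bd, dtype=float)),
        "sand_pct": (("lat", "lon"), np.asarray(sand_pct, dtype=float)),
        "clay_pct": (("lat", "lon"), np.asarray(clay_pct, dtype=float)),
    }
    shape = (len(lat), len(lon))
    for name in SURFACE_FLAGS:
        arr = np.zeros(shape, dtype=bool) if flags is None or name not in flags else np.asarray(flags[name], dtype=bool)
        data[name] = (("lat", "lon"), arr)
    if ws0 is not None:
        data["ws0"] = (("lat", "lon"), np.asarray(ws0, dtype=float))
    return xr.Dataset(data, coords={"lat": lat, "lon": lon})


# ---------------------------------------------------------------------------
# masks and areas


def build_mask(soil: xr.Dataset) -> xr.DataArray:
    """Validity mask: True where the cell is simulated.

    A cell is excluded if any surface flag (ice, permanent water,
    mangrove) is set, if the bulk density is at or below the peat
    threshold (0.28 Mg m-3), or if any required soil property is missing.
    """
    valid = xr.ones_like(soil["bd"], dtype=bool)
    for name in SURFACE_FLAGS:
        if name in soil:
            valid = valid & ~soil[name].astype(bool)
    for name in SOIL_PROPS:
        valid = valid & np.isfinite(soil[name])
    valid = valid & (soil["bd"] > PEAT_BD_THRESHOLD)
    return valid.rename("valid")


def cell_area(lat_bounds, lon_bounds) -> float:
    """Area (m^2) of a spherical lat/lon cell: R^2 dlambda (sin p2 - sin p1)."""
    p1, p2 = (float(v) for v in lat_bounds)
    l1, l2 = (float(v) for v in lon_bounds)
    if not (-90.0 <= p1 < p2 <= 90.0) or not (l1 < l2):
        raise ValueError("degenerate or out-of-range cell bounds")
    dlam = np.deg2rad(l2 - l1)
    return float(EARTH_RADIUS_M**2 * dlam * (np.sin(np.deg2rad(p2)) - np.sin(np.deg2rad(p1))))


def cell_areas(lat, lon) -> xr.DataArray:
    """Per-cell areas for a regular grid of cell centres (m^2)."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    dlat = np.abs(np.diff(lat)).mean() if len(lat) > 1 else 0.5
    dlon = np.abs(np.diff(lon)).mean() if len(lon) > 1 else 0.5
    p1 = np.clip(lat - dlat / 2.0, -90.0, 90.0)
    p2 = np.clip(lat + dlat / 2.0, -90.0, 90.0)
    band = EARTH_RADIUS_M**2 * np.deg2rad(dlon) * (np.sin(np.deg2rad(p2)) - np.sin(np.deg2rad(p1)))
    areas = np.broadcast_to(band[:, None], (len(lat), len(lon))).copy()
    return xr.DataArray(areas, coords={"lat": lat, "lon": lon}, dims=("lat", "lon"), name="area")


# ---------------------------------------------------------------------------
# the simulation engine


def _flat_run(
    t_air: np.ndarray,  # (ntime, ncell)
    pre: np.ndarray,
    lat_cell: np.ndarray,  # (ncell,)
    cnr: np.ndarray,
    bd: np.ndarray,
    ws0: np.ndarray,
    params: ParameterSet,
    ch4_ppb: np.ndarray,  # (ntime,)
    spinup_months: int,
) -> dict[str, np.ndarray]:
    """Run the monthly model on flattened cells; returns native-rate fluxes."""
    lp: LandSurfaceParams = params.land()
    ntime, ncell = t_air.shape
    nyears = ntime // 12

    # PET per calendar year from that year's monthly air temperature
    pet = np.empty_like(t_air)
    for y in range(nyears):
        sl = slice(12 * y, 12 * (y + 1))
        pet[sl] = land.thornthwaite_pet(t_air[sl], lat_cell)

    if spinup_months % 12 != 0:
        raise ValueError("spinup_months must be a whole number of years")
    ncycles = spinup_months // 12
    first = slice(0, 12)
    t_all = np.concatenate([np.tile(t_air[first], (ncycles, 1)), t_air], axis=0)
    p_all = np.concatenate([np.tile(pre[first], (ncycles, 1)), pre], axis=0)
    pet_all = np.concatenate([np.tile(pet[first], (ncycles, 1)), pet], axis=0)
    j_all = np.concatenate(
        [np.tile(j_ch4(ch4_ppb[first], params.ch4_reference_ppb), ncycles),
         j_ch4(ch4_ppb, params.ch4_reference_ppb)]
    )

    gp = {gas: params.gas(gas) for gas in Gas}
    # texture only matters through ws0, which is already resolved upstream
    soil_view = SoilPhysiochem(cnr=cnr, bd=bd, sand_pct=np.zeros_like(cnr), clay_pct=np.zeros_like(cnr))
    fsp = {gas: np.asarray(f_sp(gp[gas], soil_view), dtype=float) for gas in Gas}

    state = CellState(
        swe=np.zeros(ncell),
        wfps=ws0.copy(),
        prev_pre=p_all[0].copy(),
        prev_pet=pet_all[0].copy(),
    )
    out = {gas.value: np.empty((ntime, ncell)) for gas in Gas}
    for i in range(spinup_months + ntime):
        ta, pr, pe = t_all[i], p_all[i], pet_all[i]
        snow = land.step_snow(state, ta, pr, lp)
        state.swe = snow.swe
        t_soil = land.soil_temperature(ta, snow.snow_covered, lp)
        r = land.wetness_index(pr, state.prev_pre, pe, state.prev_pet, lp)
        state.wfps = land.step_wfps(state, r, ta, ws0, lp)
        state.prev_pre, state.prev_pet = pr, pe
        if i >= spinup_months:
            k = i - spinup_months
            wet = state.wfps
            for gas in Gas:
                p = gp[gas]
                flux = fsp[gas] * g_wfps(p, wet) * h_temp(p.temp_p, t_soil)
                if gas is Gas.CH4:
                    flux = flux * j_all[i]
                out[gas.value][k] = flux
    return out


def _validate_alignment(climate: xr.Dataset, soil: xr.Dataset) -> None:
    if not np.array_equal(climate["lat"].values, soil["lat"].values) or not np.array_equal(
        climate["lon"].values, soil["lon"].values
    ):
        raise ValueError("climate and soil grids must share identical lat/lon axes")


def run_grid(
    climate: xr.Dataset,
    soil: xr.Dataset,
    params: ParameterSet,
    ch4_ppb,
    spinup_months: int = 24,
) -> xr.Dataset:
    """Simulate every unmasked cell; returns the native-rate flux field.

    ``ch4_ppb`` is the monthly atmospheric CH4 series aligned with the
    climate's time axis.  A spin-up repeating the first year's climate
    (24 months by default) precedes the reporting period so the moisture
    and snow state start near equilibrium.  Masked cells are NaN.
    """
    _validate_alignment(climate, soil)
    ch4_ppb = np.asarray(ch4_ppb, dtype=float)
    ntime = climate.sizes["time"]
    if ch4_ppb.shape != (ntime,):
        raise ValueError("ch4_ppb must align with the climate time axis")
    if ntime % 12 != 0:
        raise ValueError("climate must cover whole years")

    mask = build_mask(soil)
    valid = mask.values.ravel()
    nlat, nlon = mask.shape
    lat_cell = np.broadcast_to(climate["lat"].values[:, None], (nlat, nlon)).ravel()[valid]

    def flat(name):
        return soil[name].values.ravel()[valid].astype(float)

    cnr, bd = flat("cnr"), flat("bd")
    if "ws0" in soil:
        ws0 = flat("ws0")
    else:
        ws0 = np.asarray(land.saxton_ws0(flat("sand_pct"), flat("clay_pct"), bd))

    t_air = climate["t_air"].values.reshape(ntime, -1)[:, valid]
    pre = climate["pre"].values.reshape(ntime, -1)[:, valid]
    flat_fluxes = _flat_run(t_air, pre, lat_cell, cnr, bd, ws0, params, ch4_ppb, spinup_months)

    data = {}
    for gas, flux in flat_fluxes.items():
        full = np.full((ntime, nlat * nlon), np.nan)
        full[:, valid] = flux
        data[gas] = (("time", "lat", "lon"), full.reshape(ntime, nlat, nlon))
    out = xr.Dataset(data, coords=climate.coords)
    out["valid"] = mask
    return out


def run_cell(
    t_air,
    pre,
    lat: float,
    soil: SoilPhysiochem,
    params: ParameterSet,
    ch4_ppb,
    spinup_months: int = 24,
) -> pd.DataFrame:
    """Run one cell from monthly series; returns a DataFrame of native-rate fluxes."""
    t_air = np.asarray(t_air, dtype=float)
    pre = np.asarray(pre, dtype=float)
    ch4_ppb = np.asarray(ch4_ppb, dtype=float)
    if not (t_air.shape == pre.shape == ch4_ppb.shape) or t_air.ndim != 1:
        raise ValueError("t_air, pre and ch4_ppb must be equal-length 1-D series")
    if len(t_air) % 12 != 0:
        raise ValueError("series must cover whole years")
    ws0 = np.atleast_1d(land.saxton_ws0(soil.sand_pct, soil.clay_pct, soil.bd))
    out = _flat_run(
        t_air[:, None],
        pre[:, None],
        np.array([lat], dtype=float),
        np.atleast_1d(float(soil.cnr)),
        np.atleast_1d(float(soil.bd)),
        ws0,
        params,
        ch4_ppb,
        spinup_months,
    )
    return pd.DataFrame({gas: series[:, 0] for gas, series in out.items()})


# ---------------------------------------------------------------------------
# unit aggregation


def monthly_to_annual(flux: xr.Dataset, month_days=None) -> xr.Dataset:
    """Per-cell annual fluxes: g C m-2 yr-1 (CO2, CH4) and g N m-2 yr-1 (N2O).

    CO2 native rates are per second and CH4/N2O per hour; each month
    contributes rate x month-duration, and the microgram-to-gram factor
    is 1e-6.  Month lengths default to the 365-day no-leap calendar.
    """
    if month_days is None:
        month_days = NOLEAP_MONTH_DAYS
    month_days = np.asarray(month_days, dtype=float)
    months = flux["month"].values
    years = flux["year"].values
    for y in np.unique(years):
        if sorted(months[years == y]) != list(range(1, 13)):
            raise ValueError(f"year {y} is incomplete; full years required")
    dur_days = xr.DataArray(month_days[months - 1], coords={"time": flux["time"]}, dims="time")
    out = {}
    for gas in ("co2", "ch4", "n2o"):
        per_month_units = dur_days * (86_400.0 if gas == "co2" else 24.0)
        annual = (flux[gas] * per_month_units * 1e-6).groupby(flux["year"].rename("yr")).sum(
            "time", skipna=False
        )
        out[gas] = annual.rename({"yr": "year"})
    ds = xr.Dataset(out)
    if "valid" in flux:
        ds["valid"] = flux["valid"]
    return ds


_TOTAL_SCALE = {"co2": 1e-15, "ch4": 1e-12, "n2o": 1e-12}  # g -> Pg / Tg / Tg


def global_total(annual: xr.Dataset, areas: xr.DataArray) -> dict[str, float]:
    """Area-weighted global totals of the mean annual field.

    Returns Pg C yr-1 for CO2 and Tg C / Tg N yr-1 for CH4 / N2O,
    summing flux x cell area over unmasked cells.
    """
    mean_annual = annual.mean("year") if "year" in annual.dims else annual
    out = {}
    for gas in ("co2", "ch4", "n2o"):
        field = mean_annual[gas].values
        total_g = np.nansum(field * areas.values)
        out[gas] = float(total_g * _TOTAL_SCALE[gas])
    return out


# ---------------------------------------------------------------------------
# zones, matrices, histograms


def mean_annual_temperature(climate: xr.Dataset) -> xr.DataArray:
    """Mean annual air temperature over the climate's whole span (degC)."""
    return climate["t_air"].mean("time").rename("mat")


def classify_zone(mat) -> np.ndarray:
    """Climate zone from mean annual temperature.

    boreal: T < 2.0 degC; temperate: 2.0 <= T <= 17.0; tropical: T > 17.0.
    """
    mat = np.asarray(mat, dtype=float)
    zone = np.where(mat < 2.0, "boreal", np.where(mat <= 17.0, "temperate", "tropical"))
    return zone if zone.ndim else str(zone)


def zone_contributions(
    annual: xr.Dataset, mat: xr.DataArray, areas: xr.DataArray
) -> dict[str, dict[str, float]]:
    """Fraction of each gas's global total contributed by each climate zone."""
    mean_annual = annual.mean("year") if "year" in annual.dims else annual
    zones = classify_zone(mat.values)
    out: dict[str, dict[str, float]] = {}
    for gas in ("co2", "ch4", "n2o"):
        weighted = mean_annual[gas].values * areas.values
        total = np.nansum(weighted)
        out[gas] = {
            z: float(np.nansum(np.where(zones == z, weighted, 0.0)) / total)
            for z in ("boreal", "temperate", "tropical")
        }
    return out


def latitudinal_seasonal_matrix(
    flux: xr.Dataset, areas: xr.DataArray, band_width: float | None = None
) -> dict[str, pd.DataFrame]:
    """Latitude-band x calendar-month mean flux per gas (native units).

    Area-weighted mean over the cells of each band, averaged across years.
    The band width defaults to the grid's latitude spacing.
    """
    lat = flux["lat"].values
    if band_width is None:
        band_width = float(np.abs(np.diff(lat)).mean()) if len(lat) > 1 else 1.0
    band = np.floor(lat / band_width) * band_width + band_width / 2.0
    out = {}
    for gas in ("co2", "ch4", "n2o"):
        monthly = flux[gas].groupby(flux["month"].rename("mon")).mean("time", skipna=True)
        w = areas.values[None, :, :] * np.isfinite(monthly.values)
        v = np.where(np.isfinite(monthly.values), monthly.values, 0.0)
        rows = []
        for b in np.unique(band):
            sel = band == b
            num = (v[:, sel, :] * w[:, sel, :]).sum(axis=(1, 2))
            den = w[:, sel, :].sum(axis=(1, 2))
            with np.errstate(invalid="ignore"):
                rows.append(np.where(den > 0, num / den, np.nan))
        out[gas] = pd.DataFrame(
            np.array(rows),
            index=pd.Index(np.unique(band), name="lat_band"),
            columns=pd.Index(monthly["mon"].values, name="month"),
        )
    return out


#: default histogram bin widths; the CO2 width reflects per-cell annual
#: fluxes binned in 150 g C m-2 yr-1 classes
DEFAULT_BIN_WIDTH = {"co2": 150.0, "ch4": 0.05, "n2o": 0.01}


def flux_histogram(annual_field: xr.DataArray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-cell mean annual flux over unmasked cells.

    Bins are left-closed right-open, anchored at 0; the counts sum to the
    number of unmasked (finite) cells.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = annual_field.values
    values = values[np.isfinite(values)].ravel()
    if values.size == 0:
        return np.array([], dtype=int), np.array([0.0])
    nbins = int(np.floor(values.max() / bin_width)) + 1
    edges = np.arange(nbins + 1) * bin_width
    idx = np.floor(values / bin_width).astype(int)
    counts = np.bincount(idx, minlength=nbins)
    return counts, edges


# ---------------------------------------------------------------------------
# site comparison


def filter_site_rows(sites: pd.DataFrame) -> pd.DataFrame:
    """Declarative row filters for a site-flux table.

    Keeps non-agricultural ecosystems without experimental manipulation,
    measured by infrared gas analyser or gas chromatography, with quality
    flags restricted to Q01/Q02/Q03.  Columns absent from the table are
    not filtered on.
    """
    keep = pd.Series(True, index=sites.index)
    if "ecosystem" in sites:
        keep &= sites["ecosystem"].str.lower() != "agriculture"
    if "manipulation" in sites:
        keep &= sites["manipulation"].str.lower().isin(["none", ""])
    if "method" in sites:
        keep &= sites["method"].str.upper().isin(["IRGA", "GC"])
    if "quality_flag" in sites:
        keep &= sites["quality_flag"].str.upper().isin(["Q01", "Q02", "Q03"])
    return sites.loc[keep]


def compare_with_sites(annual_field: xr.DataArray, sites: pd.DataFrame) -> dict:
    """Match site observations to grid cells and regress observed on simulated.

    ``sites`` needs ``lat``, ``lon`` and ``annual_flux`` columns (same
    units as the field).  Sites falling in masked (NaN) cells are
    dropped.  Returns the Pearson correlation, least-squares slope and
    intercept of observed vs simulated, the pair count and the pairs.
    """
    lat_ax = annual_field["lat"].values
    lon_ax = annual_field["lon"].values
    dlat = np.abs(np.diff(lat_ax)).mean() if len(lat_ax) > 1 else 0.5
    dlon = np.abs(np.diff(lon_ax)).mean() if len(lon_ax) > 1 else 0.5

    sim, obs = [], []
    for _, row in sites.iterrows():
        i = int(np.argmin(np.abs(lat_ax - row["lat"])))
        j = int(np.argmin(np.abs(lon_ax - row["lon"])))
        if abs(lat_ax[i] - row["lat"]) > dlat / 2 or abs(lon_ax[j] - row["lon"]) > dlon / 2:
            continue  # outside the grid
        v = float(annual_field.values[i, j])
        if np.isfinite(v):
            sim.append(v)
            obs.append(float(row["annual_flux"]))
    if len(sim) < 2:
        raise ValueError("fewer than two sites fall inside simulated cells")
    sim_arr, obs_arr = np.asarray(sim), np.asarray(obs)
    if np.ptp(sim_arr) == 0 or np.ptp(obs_arr) == 0:
        r = 1.0 if np.allclose(sim_arr, obs_arr) else np.nan
    else:
        r = float(scipy.stats.pearsonr(sim_arr, obs_arr).statistic)
    slope, intercept = np.polyfit(sim_arr, obs_arr, 1)
    return {
        "r": r,
        "slope": float(slope),
        "intercept": float(intercept),
        "n": len(sim),
        "pairs": pd.DataFrame({"simulated": sim_arr, "observed": obs_arr}),
    }
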