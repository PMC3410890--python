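"""Synthetic drivers: climate, soils, atmospheric CH4 and site networks.

Emulates the statistical structure of the real inputs the pipeline
consumes -- a gridded monthly climatology whose mean state and
seasonality vary with latitude, spatially heterogeneous topsoil
properties including low-bulk-density (peat-like) cells and flagged
surfaces, a slowly rising atmospheric CH4 series, and a multi-site
monthly chamber-flux network generated through the forward model with
additive observation noise.  The default world spans all three climate
zones (boreal, temperate, tropical), produces snow-covered winters and
freeze-hold months at high latitudes, and exercises the peat mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .calibration import FLUX_COLUMNS, forward_site_predictions
from .grid import make_climate_grid, make_soil_grid
from .params import Gas, ParameterSet

__all__ = ["SyntheticSpec", "synth_climate", "synth_soil", "synth_ch4_series", "synth_site_obs"]


@dataclass
class SyntheticSpec:
    """Configuration of the synthetic world; the seed is mandatory."""

    seed: int
    nlat: int = 20
    nlon: int = 40
    year_start: int = 2000
    n_years: int = 5

    # climate: equator-to-pole gradient, amplitude growth, noise
    mat_equator: float = 28.0  # degC mean annual temperature at the equator
    mat_lapse: float = 0.55  # degC per degree latitude
    seas_amp_base: float = 2.0  # degC seasonal amplitude at the equator
    seas_amp_lapse: float = 0.30  # amplitude growth per degree latitude
    t_noise_sd: float = 0.5  # degC month-to-month noise
    pre_base: float = 40.0  # mm/month baseline precipitation
    pre_tropical: float = 90.0  # extra mm/month at the equator (decays poleward)
    wet_season_frac: float = 0.5  # relative amplitude of the wet season
    pre_noise_sd: float = 8.0  # mm/month noise

    # soils
    cnr_mean: float = 15.0
    cnr_sd: float = 4.0
    cnr_range: tuple[float, float] = (5.0, 35.0)
    bd_mean: float = 1.2
    bd_sd: float = 0.25
    bd_range: tuple[float, float] = (0.35, 1.8)
    sand_range: tuple[float, float] = (20.0, 70.0)
    clay_range: tuple[float, float] = (5.0, 40.0)
    peat_fraction: float = 0.05  # cells given bd <= 0.28
    flag_fraction: float = 0.02  # cells given each surface flag

    # atmospheric CH4
    ch4_start_ppb: float = 1750.0
    ch4_trend_ppb_yr: float = 3.0
    ch4_seas_amp_ppb: float = 15.0

    # site network (mid-latitude forest sites measured monthly)
    n_sites: int = 36
    site_year_start: int = 2002
    site_n_years: int = 3
    n_records: int | None = 768  # non-missing flux records per gas; None = all
    site_lat_range: tuple[float, float] = (31.0, 45.0)
    noise_frac: dict = field(
        default_factory=lambda: {"co2": 0.10, "ch4": 0.10, "n2o": 0.10}
    )  # observation noise sd as a fraction of each gas's flux range


def _admissible_texture(sand, clay):
    """Rescale sampled sand/clay so their sum never exceeds 100 %."""
    total = sand + clay
    over = total > 100.0
    scale = np.where(over, 99.9 / total, 1.0)  # strictly inside the bound
    return sand * scale, clay * scale


def _seasonal_temperature(lat, months, spec: SyntheticSpec, rng=None):
    """T(lat, month): latitude-graded mean plus a hemisphere-phased cycle."""
    lat = np.asarray(lat, dtype=float)
    mat = spec.mat_equator - spec.mat_lapse * np.abs(lat)
    amp = spec.seas_amp_base + spec.seas_amp_lapse * np.abs(lat)
    # warm peak in July north of the equator, January south of it
    peak = np.where(lat >= 0, 7.0, 1.0)
    cyc = np.cos(2.0 * np.pi * (months[:, None] - peak[None, :]) / 12.0)
    t = mat[None, :] + amp[None, :] * cyc
    if rng is not None and spec.t_noise_sd > 0:
        t = t + rng.normal(0.0, spec.t_noise_sd, size=t.shape)
    return t


def _seasonal_precipitation(lat, months, spec: SyntheticSpec, rng=None):
    lat = np.asarray(lat, dtype=float)
    base = spec.pre_base + spec.pre_tropical * np.cos(np.deg2rad(lat)) ** 2
    peak = np.where(lat >= 0, 7.0, 1.0)
    cyc = 1.0 + spec.wet_season_frac * np.cos(2.0 * np.pi * (months[:, None] - peak[None, :]) / 12.0)
    pre = base[None, :] * cyc
    if rng is not None and spec.pre_noise_sd > 0:
        pre = pre + rng.normal(0.0, spec.pre_noise_sd, size=pre.shape)
    return np.maximum(pre, 0.0)


def synth_climate(spec: SyntheticSpec) -> xr.Dataset:
    """Gridded monthly air temperature and precipitation.

    The meridional MAT profile spans boreal (< 2 degC), temperate and
    tropical (> 17 degC) cells; seasonal amplitude grows poleward with
    opposite phase in the two hemispheres; precipitation is positive with
    a wet season in phase with the warm season.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    lat = np.linspace(-90, 90, spec.nlat + 1)[:-1] + 90.0 / spec.nlat
    lon = np.linspace(-180, 180, spec.nlon + 1)[:-1] + 180.0 / spec.nlon
    years = np.arange(spec.year_start, spec.year_start + spec.n_years)
    months = np.tile(np.arange(1, 13), spec.n_years).astype(float)
    t2d = _seasonal_temperature(lat, months, spec, rng)  # (ntime, nlat)
    p2d = _seasonal_precipitation(lat, months, spec, rng)
    ntime = len(months)
    shape = (ntime, spec.nlat, spec.nlon)
    t_air = np.broadcast_to(t2d[:, :, None], shape) + rng.normal(0, spec.t_noise_sd, shape)
    pre = np.maximum(np.broadcast_to(p2d[:, :, None], shape) + rng.normal(0, spec.pre_noise_sd, shape), 0.0)
    return make_climate_grid(lat, lon, years, t_air, pre)


def synth_soil(spec: SyntheticSpec) -> xr.Dataset:
    """Heterogeneous topsoil properties with peat-like cells and surface flags."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    lat = np.linspace(-90, 90, spec.nlat + 1)[:-1] + 90.0 / spec.nlat
    lon = np.linspace(-180, 180, spec.nlon + 1)[:-1] + 180.0 / spec.nlon
    shape = (spec.nlat, spec.nlon)
    cnr = np.clip(rng.normal(spec.cnr_mean, spec.cnr_sd, shape), *spec.cnr_range)
    bd = np.clip(rng.normal(spec.bd_mean, spec.bd_sd, shape), *spec.bd_range)
    peat = rng.random(shape) < spec.peat_fraction
    bd = np.where(peat, rng.uniform(0.05, 0.28, shape), bd)
    sand, clay = _admissible_texture(
        rng.uniform(*spec.sand_range, shape), rng.uniform(*spec.clay_range, shape)
    )
    flags = {
        name: rng.random(shape) < spec.flag_fraction
        for name in ("flag_ice", "flag_water", "flag_mangrove")
    }
    return make_soil_grid(lat, lon, cnr, bd, sand, clay, flags=flags)


def synth_ch4_series(spec: SyntheticSpec, n_years: int | None = None) -> np.ndarray:
    """Monthly atmospheric CH4 (ppb): linear rise plus a seasonal cycle."""
    n_years = spec.n_years if n_years is None else n_years
    t = np.arange(n_years * 12)
    series = (
        spec.ch4_start_ppb
        + spec.ch4_trend_ppb_yr * t / 12.0
        + spec.ch4_seas_amp_ppb * np.sin(2.0 * np.pi * t / 12.0)
    )
    if np.any(series <= 0):
        raise ValueError("CH4 series must stay positive; check trend/amplitude")
    return series


def synth_site_obs(true_params: ParameterSet, spec: SyntheticSpec) -> pd.DataFrame:
    """Monthly chamber observations from a mid-latitude site network.

    Each site gets its own climate series and soil column; fluxes are
    computed through the full forward model at ``true_params`` and
    perturbed with additive Gaussian noise whose sd is the configured
    fraction of that gas's simulated flux range.  Driver rows cover every
    site-month; when ``n_records`` is set, flux values outside a random
    subsample of that size (per gas) are blanked to emulate uneven site
    coverage, so the non-missing count per gas equals ``n_records``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    n = spec.n_sites
    lat = rng.uniform(*spec.site_lat_range, n)
    months = np.tile(np.arange(1, 13), spec.site_n_years).astype(float)
    years = np.repeat(
        np.arange(spec.site_year_start, spec.site_year_start + spec.site_n_years), 12
    )
    t_air = _seasonal_temperature(lat, months, spec, rng)  # (ntime, nsite)
    pre = _seasonal_precipitation(lat, months, spec, rng)
    cnr = np.clip(rng.normal(spec.cnr_mean, spec.cnr_sd, n), *spec.cnr_range)
    bd = np.clip(rng.normal(spec.bd_mean, spec.bd_sd, n), 0.35, 1.8)
    sand, clay = _admissible_texture(
        rng.uniform(*spec.sand_range, n), rng.uniform(*spec.clay_range, n)
    )

    ntime = len(months)
    rows = pd.DataFrame(
        {
            "site_id": np.tile(np.arange(n), ntime),
            "lat": np.tile(lat, ntime),
            "year": np.repeat(years, n),
            "month": np.repeat(np.tile(np.arange(1, 13), spec.site_n_years), n),
            "t_air": t_air.reshape(-1),
            "pre": pre.reshape(-1),
            "cnr": np.tile(cnr, ntime),
            "bd": np.tile(bd, ntime),
            "sand_pct": np.tile(sand, ntime),
            "clay_pct": np.tile(clay, ntime),
        }
    )
    pred = forward_site_predictions(true_params, rows).reindex(rows.index)
    for gas in Gas:
        clean = pred[gas.value].to_numpy()
        sd = spec.noise_frac[gas.value] * float(np.ptp(clean))
        noisy = clean + rng.normal(0.0, sd, size=clean.shape)
        if spec.n_records is not None:
            if spec.n_records > len(noisy):
                raise ValueError("n_records exceeds the number of site-months")
            keep = rng.choice(len(noisy), size=spec.n_records, replace=False)
            blank = np.full(len(noisy), np.nan)
            blank[keep] = noisy[keep]
            noisy = blank
        rows[FLUX_COLUMNS[gas]] = noisy
    return rows
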