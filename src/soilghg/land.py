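"""Monthly land-surface drivers: snow, PET, soil water and soil temperature.

These prognostic pieces turn monthly air temperature and precipitation
into the two drivers the flux equations need -- soil temperature at 5 cm
and water-filled pore space (WFPS) -- via a degree-day snow store, the
Thornthwaite potential evapotranspiration, a Saxton-type water-retention
anchor WS0 (the WFPS at a 30 kPa matric potential) and a wetness-index
bucket update.  Everything is numpy-vectorised over cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .params import LandSurfaceParams

__all__ = [
    "CellState",
    "SnowStep",
    "step_snow",
    "thornthwaite_pet",
    "daylight_hours",
    "saxton_theta_30kpa",
    "saxton_ws0",
    "wetness_index",
    "step_wfps",
    "soil_temperature",
    "NOLEAP_MONTH_DAYS",
]

#: 365-day (no-leap) month lengths, the default calendar
NOLEAP_MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)

#: floor applied to the PET denominator of the wetness index (mm)
PET_FLOOR_MM = 1.0
#: floor applied to the wetness index before taking its logarithm
LN_R_FLOOR = 1e-6


@dataclass
class CellState:
    """Per-cell prognostic state carried month to month."""

    swe: float = 0.0  # snow water equivalent, mm
    wfps: float = 0.5  # water-filled pore space, fraction
    prev_pre: float = 0.0  # last month's precipitation, mm
    prev_pet: float = 0.0  # last month's PET, mm


class SnowStep(NamedTuple):
    swe: float
    snow_covered: bool
    snowfall: float
    melt: float


def step_snow(state: CellState, t_air, pre, p: LandSurfaceParams) -> SnowStep:
    """Advance the snow store by one month.

    Precipitation falls as snow when the air temperature is at or below
    ``t_snow``; melt proceeds at ``s_melt`` mm per degree above ``t_melt``,
    capped by the stock.  Snowfall is accumulated before melt and the
    cover flag reflects the end-of-month store.  Only the presence of
    snow matters downstream (it switches the soil-temperature branch).
    """
    t_air = np.asarray(t_air, dtype=float)
    pre = np.asarray(pre, dtype=float)
    if np.any(pre < 0):
        raise ValueError("precipitation must be non-negative")
    snowfall = np.where(t_air <= p.t_snow, pre, 0.0)
    swe = np.asarray(state.swe, dtype=float) + snowfall
    potential_melt = np.where(t_air > p.t_melt, p.s_melt * (t_air - p.t_melt), 0.0)
    melt = np.minimum(swe, potential_melt)
    swe = swe - melt
    covered = swe > 0
    if swe.ndim == 0:
        return SnowStep(float(swe), bool(covered), float(snowfall), float(melt))
    return SnowStep(swe, covered, snowfall, melt)


def daylight_hours(latitude, day_of_year):
    """Mean day length (hours) from the standard solar-declination formula."""
    lat = np.deg2rad(np.asarray(latitude, dtype=float))
    decl = np.deg2rad(23.45) * np.sin(2.0 * np.pi * (284.0 + np.asarray(day_of_year)) / 365.0)
    cos_omega = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_omega)


def thornthwaite_pet(monthly_t_air, latitude, month_days=None):
    """Thornthwaite potential evapotranspiration for a 12-month year (mm).

    ``monthly_t_air`` has shape (12,) or (12, ncell); ``latitude`` is a
    scalar or (ncell,).  The annual heat index is
    I = sum_m (max(T_m, 0)/5)^1.514, the exponent
    alpha = 6.75e-7 I^3 - 7.71e-5 I^2 + 1.792e-2 I + 0.49239, and the
    unadjusted monthly PET 16 (10 T / I)^alpha mm is scaled by the
    day-length correction (L/12)(N/30) for the month's mid-point at the
    given latitude.  Months at or below freezing give 0; a fully frozen
    year (I = 0) gives 0 everywhere.
    """
    t = np.atleast_1d(np.asarray(monthly_t_air, dtype=float))
    if t.shape[0] != 12:
        raise ValueError("monthly_t_air must have 12 months on the first axis")
    lat = np.asarray(latitude, dtype=float)
    if np.any((lat < -90) | (lat > 90)):
        raise ValueError("latitude must lie in [-90, 90]")
    if month_days is None:
        month_days = NOLEAP_MONTH_DAYS
    month_days = np.asarray(month_days, dtype=float)

    warm = np.maximum(t, 0.0)
    heat_index = np.sum((warm / 5.0) ** 1.514, axis=0)
    alpha = (
        6.75e-7 * heat_index**3
        - 7.71e-5 * heat_index**2
        + 1.792e-2 * heat_index
        + 0.49239
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        pet_unadj = 16.0 * (10.0 * warm / np.where(heat_index > 0, heat_index, np.nan)) ** alpha
    pet_unadj = np.where((t > 0) & (heat_index > 0), pet_unadj, 0.0)

    mid_doy = np.cumsum(month_days) - month_days / 2.0  # (12,)
    # correction has shape (12,) x lat-shape
    L = daylight_hours(lat[..., None] if np.ndim(lat) else lat, mid_doy)
    corr = (L / 12.0) * (month_days / 30.0)
    if np.ndim(lat):
        corr = np.moveaxis(corr, -1, 0)  # -> (12, ncell)
    pet = pet_unadj * corr
    return pet if np.ndim(monthly_t_air) > 1 else np.asarray(pet).reshape(12)


# Saxton et al. (1986) generalized water-retention regression, psi = A * theta^B
# with psi in kPa and theta the volumetric water content; valid in the
# 10-1500 kPa tension range for sand 5-95 % and clay 5-60 %.
SAXTON_A_COEFFS = (-4.396, -0.0715, -4.880e-4, -4.285e-5)
SAXTON_B_COEFFS = (-3.140, -0.00222, -3.484e-5)
PARTICLE_DENSITY = 2.65  # Mg m-3

_SAXTON_SAND_RANGE = (5.0, 95.0)
_SAXTON_CLAY_RANGE = (5.0, 60.0)


def saxton_theta_30kpa(sand_pct, clay_pct):
    """Volumetric water content at 30 kPa tension from sand/clay percentages."""
    sand = np.asarray(sand_pct, dtype=float)
    clay = np.asarray(clay_pct, dtype=float)
    if np.any(sand < _SAXTON_SAND_RANGE[0]) or np.any(sand > _SAXTON_SAND_RANGE[1]) or \
       np.any(clay < _SAXTON_CLAY_RANGE[0]) or np.any(clay > _SAXTON_CLAY_RANGE[1]):
        warnings.warn(
            "texture outside the retention regression's validity range; clamping",
            stacklevel=2,
        )
    sand = np.clip(sand, *_SAXTON_SAND_RANGE)
    clay = np.clip(clay, *_SAXTON_CLAY_RANGE)
    a0, a1, a2, a3 = SAXTON_A_COEFFS
    b0, b1, b2 = SAXTON_B_COEFFS
    A = 100.0 * np.exp(a0 + a1 * clay + a2 * sand**2 + a3 * sand**2 * clay)
    B = b0 + b1 * clay**2 + b2 * sand**2 * clay
    theta = (30.0 / A) ** (1.0 / B)
    return theta if np.ndim(theta) else float(theta)


def saxton_ws0(sand_pct, clay_pct, bd):
    """WFPS at 30 kPa water potential: retention water content over porosity.

    Porosity is 1 - bd/2.65.  The result is clipped into (0, 0.99]; very
    dense fine-textured combinations where the regression's water content
    approaches the pore volume trigger a warning.
    """
    bd = np.asarray(bd, dtype=float)
    if np.any(bd <= 0) or np.any(bd >= PARTICLE_DENSITY):
        raise ValueError(f"bd must lie in (0, {PARTICLE_DENSITY})")
    theta = np.asarray(saxton_theta_30kpa(sand_pct, clay_pct))
    porosity = 1.0 - bd / PARTICLE_DENSITY
    ws0 = theta / porosity
    if np.any(ws0 > 0.99):
        warnings.warn("WS0 at or above porosity for some cells; clipping to 0.99", stacklevel=2)
    ws0 = np.clip(ws0, 1e-6, 0.99)
    return ws0 if np.ndim(ws0) else float(ws0)


def wetness_index(pre_i, pre_prev, pet_i, pet_prev, p: LandSurfaceParams):
    """Monthly wetness index r: weighted precipitation over weighted PET.

    r = (R_pre * PRE_i + (1 - R_pre) * PRE_{i-1})
      / max(R_pet * PET_i + (1 - R_pet) * PET_{i-1}, 1 mm)

    so the month's wetness also remembers the previous month's supply and
    demand; the 1 mm floor keeps frozen or hyper-arid months finite.
    """
    pre_i = np.asarray(pre_i, dtype=float)
    pre_prev = np.asarray(pre_prev, dtype=float)
    pet_i = np.asarray(pet_i, dtype=float)
    pet_prev = np.asarray(pet_prev, dtype=float)
    if np.any(pre_i < 0) or np.any(pre_prev < 0) or np.any(pet_i < 0) or np.any(pet_prev < 0):
        raise ValueError("wetness-index inputs must be non-negative")
    supply = p.r_pre * pre_i + (1.0 - p.r_pre) * pre_prev
    demand = p.r_pet * pet_i + (1.0 - p.r_pet) * pet_prev
    r = supply / np.maximum(demand, PET_FLOOR_MM)
    return r if np.ndim(r) else float(r)


def step_wfps(state: CellState, r, t_air, ws0, p: LandSurfaceParams):
    """Advance WFPS by one month.

    In cold months (t_air < T_W) the moisture is held frozen at last
    month's value.  Otherwise the cell relaxes towards a wetness target
    WS0 + s_lnr * ln(r) -- equal to WS0 in a balanced month (r = 1) --
    keeping a memory fraction of the previous WFPS; the result is clamped
    to [0, 1].
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("wetness index must be non-negative")
    ws0 = np.asarray(ws0, dtype=float)
    if np.any((ws0 <= 0) | (ws0 >= 1)):
        raise ValueError("ws0 must lie in (0, 1)")
    t_air = np.asarray(t_air, dtype=float)
    prev = np.asarray(state.wfps, dtype=float)
    target = ws0 + p.wfps_lnr_slope * np.log(np.maximum(r, LN_R_FLOOR))
    updated = np.clip(p.wfps_memory * prev + (1.0 - p.wfps_memory) * target, 0.0, 1.0)
    out = np.where(t_air < p.t_w, prev, updated)
    return out if np.ndim(out) else float(out)


def soil_temperature(t_air, snow_covered, p: LandSurfaceParams):
    """Soil temperature at 5 cm: linear in air temperature, constant under snow."""
    t_air = np.asarray(t_air, dtype=float)
    out = np.where(np.asarray(snow_covered), p.t_snowsoil, p.s_st * t_air + p.i_st)
    return out if np.ndim(out) else float(out)
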