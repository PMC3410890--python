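"""Gas-flux equations: F = f(SP) * g(WFPS) * h(T), times j([CH4]) for CH4.

Each gas flux is the product of a soil-property factor, a moisture factor
on water-filled pore space (WFPS) and an exponential soil-temperature
factor; the CH4 uptake flux is additionally scaled by the atmospheric CH4
concentration relative to a reference.  All functions are numpy-vectorised:
scalars in, scalar out; arrays in, elementwise arrays out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import Gas, GasFluxParams, NATIVE_UNITS

__all__ = ["SoilPhysiochem", "GasFlux", "f_sp", "g_wfps", "h_temp", "j_ch4", "gas_flux"]


@dataclass(frozen=True)
class SoilPhysiochem:
    """Topsoil (0-5 cm) physiochemical properties of one cell or site."""

    cnr: float  # C/N mass ratio
    bd: float  # bulk density, Mg m-3
    sand_pct: float
    clay_pct: float

    def __post_init__(self) -> None:
        if not np.all(np.asarray(self.cnr) > 0):
            raise ValueError("cnr must be positive")
        if not np.all(np.asarray(self.bd) > 0):
            raise ValueError("bd must be positive")
        sand = np.asarray(self.sand_pct)
        clay = np.asarray(self.clay_pct)
        if np.any(sand < 0) or np.any(clay < 0) or np.any(sand + clay > 100):
            raise ValueError("texture must satisfy sand, clay >= 0 and sand + clay <= 100")


@dataclass(frozen=True)
class GasFlux:
    gas: Gas
    value: float  # native units, non-negative

    @property
    def units(self) -> str:
        return NATIVE_UNITS[self.gas]


def f_sp(params: GasFluxParams, soil: SoilPhysiochem):
    """Soil-property factor.

    Linear in the gas's controlling property: the CO2 factor increases
    with the C/N ratio, the CH4 factor decreases with bulk density, and
    the N2O factor is non-decreasing in the C/N ratio.  Non-negative for
    any admissible soil (enforced at parameter validation).
    """
    if params.gas is Gas.CH4:
        x = np.asarray(soil.bd, dtype=float)
        if np.any(x <= 0):
            raise ValueError("bd must be positive")
    else:
        x = np.asarray(soil.cnr, dtype=float)
        if np.any(x <= 0):
            raise ValueError("cnr must be positive")
    out = params.f_slope * x + params.f_intercept
    if np.any(out < 0):
        raise ValueError(
            f"f(SP) negative for {params.gas.value}: soil outside the admissible range"
        )
    return out if out.ndim else float(out)


def g_wfps(params: GasFluxParams, wfps):
    """Moisture factor in [0, 1].

    A convex bump anchored at g(a) = g(c) = 0 and g(b) = 1 with a unique
    interior maximum at the optimum b; d controls the curvature.  WFPS
    outside [a, c] yields 0 (soils drier than a or wetter than c produce
    no flux).
    """
    w = np.asarray(wfps, dtype=float)
    if np.any((w < 0) | (w > 1)):
        raise ValueError("wfps must lie in [0, 1]")
    a, b, c, d = params.wfps_a, params.wfps_b, params.wfps_c, params.wfps_d
    inside = (w > a) & (w < c)
    ws = np.where(inside, w, b)  # safe values outside [a, c]
    expo = (c - b) / (b - a)
    core = ((ws - a) / (b - a)) * ((c - ws) / (c - b)) ** expo
    out = np.where(inside, core**d, 0.0)
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def h_temp(temp_p: float, t_soil):
    """Exponential temperature factor with h(0 degC) = 1."""
    out = np.exp(temp_p * np.asarray(t_soil, dtype=float))
    return out if out.ndim else float(out)


def j_ch4(conc, ref_conc):
    """Atmospheric-CH4 factor: concentration relative to the reference.

    Equals 1 at the reference concentration and grows linearly, so CH4
    uptake scales with the ambient mixing ratio.
    """
    c = np.asarray(conc, dtype=float)
    r = np.asarray(ref_conc, dtype=float)
    if np.any(c <= 0) or np.any(r <= 0):
        raise ValueError("CH4 concentrations must be positive")
    out = c / r
    return out if out.ndim else float(out)


def gas_flux(
    params: GasFluxParams,
    soil: SoilPhysiochem,
    wfps,
    t_soil,
    ch4_factor: float = 1.0,
) -> GasFlux:
    """Monthly flux of one gas in its native units.

    ``ch4_factor`` (the j factor) only applies to CH4 and is ignored for
    CO2 and N2O.
    """
    value = f_sp(params, soil) * g_wfps(params, wfps) * h_temp(params.temp_p, t_soil)
    if params.gas is Gas.CH4:
        value = value * ch4_factor
    if np.ndim(value):
        return GasFlux(gas=params.gas, value=value)
    return GasFlux(gas=params.gas, value=float(value))
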