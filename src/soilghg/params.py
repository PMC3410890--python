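"""Parameter containers, validation, and the YAML parameter-file format.

The model's tunables live in a single structured file with one block per
gas, a shared land-surface block and an atmosphere block.  Every parameter
carries its value, units and an uncertainty descriptor so that Monte Carlo
ensembles (:mod:`soilghg.uncertainty`) can redraw it:

* ``posterior_sd`` -- normal with the summarised calibration posterior sd;
* ``default_cv``   -- normal with a 10 % coefficient of variation, used for
  parameters that were never calibrated against site data;
* ``fixed``        -- never redrawn.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator

import yaml

__all__ = [
    "Gas",
    "Uncertainty",
    "Parameter",
    "GasFluxParams",
    "LandSurfaceParams",
    "ParameterSet",
    "load_parameters",
    "save_parameters",
    "default_parameters",
    "ADMISSIBLE_CNR",
    "ADMISSIBLE_BD",
]


class Gas(str, Enum):
    """The three gases; native flux units differ per gas."""

    CO2 = "co2"  # ug C m-2 s-1
    CH4 = "ch4"  # ug C m-2 h-1 (uptake magnitude)
    N2O = "n2o"  # ug N m-2 h-1


#: native rate units per gas
NATIVE_UNITS = {
    Gas.CO2: "ug C m-2 s-1",
    Gas.CH4: "ug C m-2 h-1",
    Gas.N2O: "ug N m-2 h-1",
}

#: admissible topsoil ranges used when validating that f(SP) stays non-negative
ADMISSIBLE_CNR = (3.0, 40.0)
ADMISSIBLE_BD = (0.05, 2.0)

_UNCERTAINTY_KINDS = {"posterior_sd", "default_cv", "fixed"}


@dataclass(frozen=True)
class Uncertainty:
    kind: str
    sd: float | None = None
    cv: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _UNCERTAINTY_KINDS:
            raise ValueError(f"unknown uncertainty kind {self.kind!r}")
        if self.kind == "posterior_sd" and (self.sd is None or self.sd < 0):
            raise ValueError("posterior_sd requires sd >= 0")
        if self.kind == "default_cv" and (self.cv is None or self.cv < 0):
            raise ValueError("default_cv requires cv >= 0")

    def scale_for(self, value: float) -> float:
        """Standard deviation of the sampling distribution around *value*."""
        if self.kind == "posterior_sd":
            return float(self.sd)
        if self.kind == "default_cv":
            return float(self.cv) * abs(value)
        return 0.0


@dataclass(frozen=True)
class Parameter:
    name: str
    value: float
    units: str
    uncertainty: Uncertainty
    calibrated: bool = False


@dataclass(frozen=True)
class GasFluxParams:
    """Flux-equation parameters for one gas.

    ``f_slope``/``f_intercept`` define the linear soil-property factor
    f(SP); ``wfps_a``/``b``/``c`` are the minimum, optimum and maximum
    water-filled pore space of the moisture factor g (g(a)=g(c)=0,
    g(b)=1) and ``wfps_d`` its curvature; ``temp_p`` is the exponential
    temperature sensitivity (degC-1, h(0)=1).
    """

    gas: Gas
    f_slope: float
    f_intercept: float
    wfps_a: float
    wfps_b: float
    wfps_c: float
    wfps_d: float
    temp_p: float

    def validate(self) -> None:
        a, b, c = self.wfps_a, self.wfps_b, self.wfps_c
        if not (0.0 <= a < b < c <= 1.0):
            raise ValueError(
                f"{self.gas.value}: require 0 <= a < b < c <= 1, got "
                f"a={a}, b={b}, c={c}"
            )
        # f(SP) must be non-negative over the admissible soil range
        if self.gas is Gas.CH4:
            lo, hi = ADMISSIBLE_BD
        else:
            lo, hi = ADMISSIBLE_CNR
        f_lo = self.f_slope * lo + self.f_intercept
        f_hi = self.f_slope * hi + self.f_intercept
        if min(f_lo, f_hi) < 0.0:
            raise ValueError(
                f"{self.gas.value}: f(SP) negative on the admissible range "
                f"[{lo}, {hi}] (endpoint values {f_lo:.4g}, {f_hi:.4g})"
            )


@dataclass(frozen=True)
class LandSurfaceParams:
    """Shared snow / soil-temperature / soil-water constants."""

    t_snow: float  # degC, max temperature at which precipitation is snow
    t_melt: float  # degC, min temperature at which melt occurs
    s_melt: float  # mm degC-1, melt rate
    s_st: float  # slope of the soil-temperature line
    i_st: float  # degC, intercept of the soil-temperature line
    t_snowsoil: float  # degC, soil temperature under snow cover
    r_pre: float  # weight of current-month precipitation in the wetness index
    r_pet: float  # weight of current-month PET in the wetness index
    t_w: float  # degC, freeze-hold threshold for WFPS
    wfps_memory: float  # weight of last month's WFPS in the moisture update
    wfps_lnr_slope: float  # WFPS shift per unit ln(wetness index)

    def validate(self) -> None:
        if self.s_melt < 0:
            raise ValueError("s_melt must be >= 0")
        for name in ("r_pre", "r_pet", "wfps_memory"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.t_melt < self.t_snow:
            raise ValueError("t_melt must be >= t_snow")


_GAS_FIELDS = ("f_slope", "f_intercept", "wfps_a", "wfps_b", "wfps_c", "wfps_d", "temp_p")
_LAND_FIELDS = (
    "t_snow", "t_melt", "s_melt", "s_st", "i_st", "t_snowsoil",
    "r_pre", "r_pet", "t_w", "wfps_memory", "wfps_lnr_slope",
)
_ATMO_FIELDS = ("ch4_reference_ppb",)


@dataclass
class ParameterSet:
    """The full parameter file: per-gas blocks + shared blocks.

    Stored as :class:`Parameter` objects so uncertainty metadata survives a
    round trip through YAML; typed views (:meth:`gas`, :meth:`land`) feed
    the numerical code.
    """

    gases: dict[Gas, dict[str, Parameter]] = field(default_factory=dict)
    land_surface: dict[str, Parameter] = field(default_factory=dict)
    atmosphere: dict[str, Parameter] = field(default_factory=dict)

    def gas(self, gas: Gas | str) -> GasFluxParams:
        gas = Gas(gas)
        block = self.gases[gas]
        return GasFluxParams(gas=gas, **{f: block[f].value for f in _GAS_FIELDS})

    def land(self) -> LandSurfaceParams:
        return LandSurfaceParams(**{f: self.land_surface[f].value for f in _LAND_FIELDS})

    @property
    def ch4_reference_ppb(self) -> float:
        return self.atmosphere["ch4_reference_ppb"].value

    def validate(self) -> None:
        for gas in Gas:
            if gas not in self.gases:
                raise ValueError(f"missing gas block {gas.value!r}")
            missing = set(_GAS_FIELDS) - set(self.gases[gas])
            if missing:
                raise ValueError(f"{gas.value}: missing parameters {sorted(missing)}")
            self.gas(gas).validate()
        missing = set(_LAND_FIELDS) - set(self.land_surface)
        if missing:
            raise ValueError(f"land_surface: missing parameters {sorted(missing)}")
        self.land().validate()
        for f in _ATMO_FIELDS:
            if f not in self.atmosphere:
                raise ValueError(f"atmosphere: missing parameter {f!r}")
            if self.atmosphere[f].value <= 0:
                raise ValueError(f"{f} must be positive")

    # -- flat addressing ("co2.f_slope", "land.t_w", "atmosphere.ch4_reference_ppb")

    def _resolve(self, name: str) -> tuple[dict[str, Parameter], str]:
        block_name, _, pname = name.partition(".")
        if block_name in Gas._value2member_map_:
            return self.gases[Gas(block_name)], pname
        if block_name in ("land", "land_surface"):
            return self.land_surface, pname
        if block_name == "atmosphere":
            return self.atmosphere, pname
        raise KeyError(f"unknown parameter block in {name!r}")

    def get(self, name: str) -> Parameter:
        block, pname = self._resolve(name)
        return block[pname]

    def with_value(self, name: str, value: float) -> "ParameterSet":
        """Return a copy with one parameter's value replaced."""
        new = self.copy()
        block, pname = new._resolve(name)
        block[pname] = replace(block[pname], value=float(value))
        return new

    def with_values(self, updates: dict[str, float]) -> "ParameterSet":
        new = self.copy()
        for name, value in updates.items():
            block, pname = new._resolve(name)
            block[pname] = replace(block[pname], value=float(value))
        return new

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            gases={g: dict(b) for g, b in self.gases.items()},
            land_surface=dict(self.land_surface),
            atmosphere=dict(self.atmosphere),
        )

    def items(self) -> Iterator[tuple[str, Parameter]]:
        """Iterate (flat name, Parameter) over every parameter."""
        for gas in Gas:
            for pname, p in self.gases[gas].items():
                yield f"{gas.value}.{pname}", p
        for pname, p in self.land_surface.items():
            yield f"land.{pname}", p
        for pname, p in self.atmosphere.items():
            yield f"atmosphere.{pname}", p


# ---------------------------------------------------------------------------
# YAML serialisation


def _parameter_from_dict(name: str, d: dict) -> Parameter:
    allowed = {"value", "units", "uncertainty", "calibrated"}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"parameter {name!r}: unknown keys {sorted(unknown)}")
    unc = d.get("uncertainty")
    if unc is None:
        raise ValueError(f"parameter {name!r}: missing uncertainty descriptor")
    unc_unknown = set(unc) - {"kind", "sd", "cv"}
    if unc_unknown:
        raise ValueError(f"parameter {name!r}: unknown uncertainty keys {sorted(unc_unknown)}")
    return Parameter(
        name=name,
        value=float(d["value"]),
        units=str(d.get("units", "")),
        uncertainty=Uncertainty(**unc),
        calibrated=bool(d.get("calibrated", False)),
    )


def _block_from_dict(block: dict, expected: tuple[str, ...], label: str) -> dict[str, Parameter]:
    unknown = set(block) - set(expected)
    if unknown:
        raise ValueError(f"{label}: unknown parameters {sorted(unknown)}")
    return {name: _parameter_from_dict(name, d) for name, d in block.items()}


def parameters_from_dict(doc: dict) -> ParameterSet:
    unknown = set(doc) - {"schema_version", "gases", "land_surface", "atmosphere"}
    if unknown:
        raise ValueError(f"parameter file: unknown top-level keys {sorted(unknown)}")
    if doc.get("schema_version") != 1:
        raise ValueError("parameter file: schema_version must be 1")
    gases = {}
    for gname, block in doc.get("gases", {}).items():
        if gname not in Gas._value2member_map_:
            raise ValueError(f"unknown gas block {gname!r}")
        gases[Gas(gname)] = _block_from_dict(block, _GAS_FIELDS, gname)
    ps = ParameterSet(
        gases=gases,
        land_surface=_block_from_dict(doc.get("land_surface", {}), _LAND_FIELDS, "land_surface"),
        atmosphere=_block_from_dict(doc.get("atmosphere", {}), _ATMO_FIELDS, "atmosphere"),
    )
    ps.validate()
    return ps


def parameters_to_dict(ps: ParameterSet) -> dict:
    def p_dict(p: Parameter) -> dict:
        unc: dict = {"kind": p.uncertainty.kind}
        if p.uncertainty.sd is not None:
            unc["sd"] = p.uncertainty.sd
        if p.uncertainty.cv is not None:
            unc["cv"] = p.uncertainty.cv
        out = {"value": p.value, "units": p.units, "uncertainty": unc}
        if p.calibrated:
            out["calibrated"] = True
        return out

    return {
        "schema_version": 1,
        "gases": {g.value: {n: p_dict(p) for n, p in b.items()} for g, b in ps.gases.items()},
        "land_surface": {n: p_dict(p) for n, p in ps.land_surface.items()},
        "atmosphere": {n: p_dict(p) for n, p in ps.atmosphere.items()},
    }


def load_parameters(path) -> ParameterSet:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parameters_from_dict(doc)


def save_parameters(ps: ParameterSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(parameters_to_dict(ps), fh, sort_keys=False)


def default_parameters() -> ParameterSet:
    """The shipped default parameter set."""
    text = (
        importlib.resources.files("soilghg.data")
        .joinpath("default_params.yaml")
        .read_text()
    )
    return parameters_from_dict(yaml.safe_load(text))
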