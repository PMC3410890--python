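"""File formats, unit conversions and literature-compilation statistics.

Grids travel as NetCDF (via xarray) or long-format CSV
(lat, lon, year, month, variable, value); site observations and estimate
compilations as CSV; parameters as the YAML format of
:mod:`soilghg.params`.  Element-mass units (Pg C, Tg C, Tg N) are the
canonical internal basis; molecule-mass values exist only at the
presentation boundary via :func:`convert_mass`.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "convert_mass",
    "summarize_estimates",
    "write_grid_netcdf",
    "read_grid_netcdf",
    "write_grid_csv",
    "read_climate_csv",
    "read_soil_csv",
    "write_soil_csv",
    "read_observations_csv",
    "write_observations_csv",
    "read_estimates_csv",
    "write_manifest",
]

#: element-to-molecule molar-mass ratios
_MOLECULE_FACTOR = {"co2": 44.0 / 12.0, "ch4": 16.0 / 12.0, "n2o": 44.0 / 28.0}


def convert_mass(value, gas: str, direction: str = "to_molecule"):
    """Convert between element-mass and molecule-mass bases.

    C -> CO2 multiplies by 44/12, C -> CH4 by 16/12 and N -> N2O by
    44/28; ``direction="to_element"`` inverts.  Round-trips are exact to
    machine precision.
    """
    gas = gas.lower()
    if gas not in _MOLECULE_FACTOR:
        raise ValueError(f"unknown gas {gas!r}")
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise ValueError("mass values must be non-negative")
    if direction == "to_molecule":
        out = value * _MOLECULE_FACTOR[gas]
    elif direction == "to_element":
        out = value / _MOLECULE_FACTOR[gas]
    else:
        raise ValueError("direction must be 'to_molecule' or 'to_element'")
    return out if np.ndim(out) else float(out)


def summarize_estimates(records: pd.DataFrame, exclusions=()) -> dict:
    """Mean, CV (%) and N of a compilation of best estimates.

    *records* needs ``label`` and ``value`` columns; rows whose label is
    in *exclusions* are dropped before the statistics.  CV uses the
    sample standard deviation (n-1).
    """
    if "label" in records.columns and exclusions:
        records = records.loc[~records["label"].isin(set(exclusions))]
    values = records["value"].to_numpy(dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 estimates after exclusion")
    if np.any(values <= 0):
        raise ValueError("estimate values must be positive")
    mean = float(values.mean())
    cv = float(100.0 * values.std(ddof=1) / mean)
    return {"mean": mean, "cv_pct": cv, "n": int(len(values))}


# ---------------------------------------------------------------------------
# gridded data


def write_grid_netcdf(ds: xr.Dataset, path) -> None:
    """NetCDF3 (classic) via the scipy backend; booleans stored as int8."""
    enc = ds.copy()
    for name, var in ds.data_vars.items():
        if var.dtype == bool:
            enc[name] = var.astype("int8")
    enc.to_netcdf(path, engine="scipy")


def read_grid_netcdf(path) -> xr.Dataset:
    ds = xr.load_dataset(path, engine="scipy")
    for name in ("flag_ice", "flag_water", "flag_mangrove", "valid"):
        if name in ds:
            ds[name] = ds[name].astype(bool)
    return ds


def write_grid_csv(ds: xr.Dataset, path) -> None:
    """Long-format CSV: lat, lon, [year, month,] variable, value."""
    frames = []
    for name, var in ds.data_vars.items():
        df = var.to_dataframe(name="value").reset_index()
        df["variable"] = name
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    drop = [c for c in ("time",) if c in out.columns]
    out.drop(columns=drop).to_csv(path, index=False)


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")


def read_climate_csv(path) -> xr.Dataset:
    """Read a long-format climate CSV (variables ``t_air`` and ``pre``)."""
    from .grid import make_climate_grid

    df = pd.read_csv(path)
    _require_columns(df, ("lat", "lon", "year", "month", "variable", "value"), path)
    lat = np.sort(df["lat"].unique())
    lon = np.sort(df["lon"].unique())
    years = np.sort(df["year"].unique())
    shape = (len(years) * 12, len(lat), len(lon))
    fields = {}
    for var in ("t_air", "pre"):
        sub = df.loc[df["variable"] == var].copy()
        if len(sub) != np.prod(shape):
            raise ValueError(f"{path}: variable {var!r} has {len(sub)} rows, expected {np.prod(shape)}")
        sub = sub.sort_values(["year", "month", "lat", "lon"])
        fields[var] = sub["value"].to_numpy(dtype=float).reshape(shape)
    return make_climate_grid(lat, lon, years, fields["t_air"], fields["pre"])


def write_soil_csv(soil: xr.Dataset, path) -> None:
    soil.to_dataframe().reset_index().to_csv(path, index=False)


def read_soil_csv(path) -> xr.Dataset:
    from .grid import SURFACE_FLAGS, make_soil_grid

    df = pd.read_csv(path)
    _require_columns(df, ("lat", "lon", "cnr", "bd", "sand_pct", "clay_pct"), path)
    lat = np.sort(df["lat"].unique())
    lon = np.sort(df["lon"].unique())
    shape = (len(lat), len(lon))
    if len(df) != np.prod(shape):
        raise ValueError(f"{path}: expected one row per lat/lon cell")
    df = df.sort_values(["lat", "lon"])

    def grid(col, dtype=float):
        return df[col].to_numpy(dtype=dtype).reshape(shape)

    flags = {name: grid(name, bool) for name in SURFACE_FLAGS if name in df.columns}
    ws0 = grid("ws0") if "ws0" in df.columns else None
    return make_soil_grid(
        lat, lon, grid("cnr"), grid("bd"), grid("sand_pct"), grid("clay_pct"),
        flags=flags, ws0=ws0,
    )


# ---------------------------------------------------------------------------
# tables


def write_observations_csv(obs: pd.DataFrame, path) -> None:
    obs.to_csv(path, index=False)


def read_observations_csv(path) -> pd.DataFrame:
    from .calibration import OBS_COLUMNS

    df = pd.read_csv(path)
    _require_columns(df, [c for c in OBS_COLUMNS if not c.endswith(("_flux", "_uptake"))], path)
    return df


def read_estimates_csv(path) -> pd.DataFrame:
    """Estimate-compilation table: label, gas, value [, uncertainty columns]."""
    df = pd.read_csv(path)
    _require_columns(df, ("label", "gas", "value"), path)
    bad = df.index[df["value"] <= 0]
    if len(bad):
        raise ValueError(f"{path}: non-positive estimate value at row(s) {list(bad)}")
    if {"bound_low", "bound_high"} <= set(df.columns):
        have = df[["bound_low", "bound_high"]].notna().all(axis=1)
        broken = df.loc[have & ~((df["bound_low"] <= df["value"]) & (df["value"] <= df["bound_high"]))]
        if len(broken):
            raise ValueError(f"{path}: bounds do not bracket value at row(s) {list(broken.index)}")
    return df


def write_manifest(path, command: str, seed: int | None = None, **extra) -> None:
    """Machine-readable run manifest written next to every CLI output."""
    from . import __version__

    doc = {
        "command": command,
        "version": __version__,
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        **extra,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)
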