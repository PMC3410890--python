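"""Bayesian calibration against monthly site chamber observations.

Parameters are estimated by random-walk Metropolis sampling of the
posterior under an independent Gaussian observation-error model with a
per-gas error standard deviation (itself calibrated by default).  Site
water-filled pore space and soil temperature are simulated from the site
climate through the land-surface submodels, not taken as observed; when
no land-surface parameter is being calibrated those drivers are
precomputed once, which makes each likelihood evaluation a set of
vectorised flux-equation calls.

The observation table is one row per site-month with columns
``site_id, lat, year, month, t_air, pre, cnr, bd, sand_pct, clay_pct,
co2_flux, ch4_uptake, n2o_flux`` (fluxes in their native units; blank =
missing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fluxes import SoilPhysiochem, f_sp, g_wfps, h_temp
from .params import Gas, ParameterSet
from . import land

__all__ = [
    "OBS_COLUMNS",
    "FLUX_COLUMNS",
    "rmse",
    "forward_site_predictions",
    "metropolis",
    "bayesian_calibrate",
    "CalibrationResult",
]

OBS_COLUMNS = (
    "site_id", "lat", "year", "month", "t_air", "pre",
    "cnr", "bd", "sand_pct", "clay_pct",
    "co2_flux", "ch4_uptake", "n2o_flux",
)
FLUX_COLUMNS = {Gas.CO2: "co2_flux", Gas.CH4: "ch4_uptake", Gas.N2O: "n2o_flux"}


def rmse(predicted, observed) -> float:
    """Root mean square error, in the units of the flux."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must be paired, equal-length series")
    if predicted.size == 0:
        raise ValueError("rmse of empty series is undefined")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


# ---------------------------------------------------------------------------
# forward predictions for a site table


def _site_driver_arrays(obs: pd.DataFrame):
    """Pivot the observation table into (ntime, nsite) driver matrices."""
    missing = {"site_id", "lat", "year", "month", "t_air", "pre", "cnr", "bd"} - set(obs.columns)
    if missing:
        raise ValueError(f"observation table missing columns {sorted(missing)}")
    obs = obs.sort_values(["year", "month", "site_id"])
    sites = np.sort(obs["site_id"].unique())
    times = obs[["year", "month"]].drop_duplicates().sort_values(["year", "month"])
    ntime, nsite = len(times), len(sites)
    if len(obs) != ntime * nsite:
        raise ValueError("every site must have a driver row for every site-month")
    if ntime % 12 != 0:
        raise ValueError("site series must cover whole years")

    def mat(col):
        return obs[col].to_numpy(dtype=float).reshape(ntime, nsite)

    t_air, pre = mat("t_air"), mat("pre")
    per_site = obs.iloc[:nsite]  # first time slice, sorted by site_id
    lat = per_site["lat"].to_numpy(dtype=float)
    soil = {c: per_site[c].to_numpy(dtype=float) for c in ("cnr", "bd", "sand_pct", "clay_pct")}
    return obs, sites, t_air, pre, lat, soil, ntime, nsite


def _simulate_site_drivers(
    t_air, pre, lat, soil, params: ParameterSet, spinup_months: int = 24
):
    """Monthly WFPS and soil temperature per site via the land-surface submodels."""
    lp = params.land()
    ntime, nsite = t_air.shape
    ws0 = np.asarray(land.saxton_ws0(soil["sand_pct"], soil["clay_pct"], soil["bd"]))
    pet = np.empty_like(t_air)
    for y in range(ntime // 12):
        sl = slice(12 * y, 12 * (y + 1))
        pet[sl] = land.thornthwaite_pet(t_air[sl], lat)
    ncycles = spinup_months // 12
    t_all = np.concatenate([np.tile(t_air[:12], (ncycles, 1)), t_air])
    p_all = np.concatenate([np.tile(pre[:12], (ncycles, 1)), pre])
    pet_all = np.concatenate([np.tile(pet[:12], (ncycles, 1)), pet])
    state = land.CellState(
        swe=np.zeros(nsite), wfps=ws0.copy(), prev_pre=p_all[0].copy(), prev_pet=pet_all[0].copy()
    )
    wfps = np.empty((ntime, nsite))
    t_soil = np.empty((ntime, nsite))
    for i in range(len(t_all)):
        snow = land.step_snow(state, t_all[i], p_all[i], lp)
        state.swe = snow.swe
        ts = land.soil_temperature(t_all[i], snow.snow_covered, lp)
        r = land.wetness_index(p_all[i], state.prev_pre, pet_all[i], state.prev_pet, lp)
        state.wfps = land.step_wfps(state, r, t_all[i], ws0, lp)
        state.prev_pre, state.prev_pet = p_all[i], pet_all[i]
        if i >= spinup_months:
            wfps[i - spinup_months] = state.wfps
            t_soil[i - spinup_months] = ts
    return wfps, t_soil


def forward_site_predictions(params: ParameterSet, obs: pd.DataFrame) -> pd.DataFrame:
    """Predicted monthly fluxes for every row of the observation table.

    Returns a DataFrame aligned with *obs* (after site/time sorting) with
    ``co2``, ``ch4``, ``n2o`` columns in native units.  The atmospheric
    CH4 factor is 1 (the reference concentration is defined as the
    calibration-period mean).
    """
    obs_sorted, _, t_air, pre, lat, soil, ntime, nsite = _site_driver_arrays(obs)
    wfps, t_soil = _simulate_site_drivers(t_air, pre, lat, soil, params)
    soil_view = SoilPhysiochem(
        cnr=soil["cnr"], bd=soil["bd"], sand_pct=soil["sand_pct"], clay_pct=soil["clay_pct"]
    )
    out = {}
    for gas in Gas:
        gp = params.gas(gas)
        flux = f_sp(gp, soil_view)[None, :] * g_wfps(gp, wfps) * h_temp(gp.temp_p, t_soil)
        out[gas.value] = flux.reshape(ntime * nsite)
    return pd.DataFrame(out, index=obs_sorted.index)


# ---------------------------------------------------------------------------
# random-walk Metropolis


def metropolis(
    log_post,
    x0,
    scales,
    n_iter: int,
    seed: int,
    adapt_until: int | None = None,
    target_accept: float = 0.3,
):
    """Gaussian random-walk Metropolis with burn-in proposal-scale adaptation.

    The proposal is N(x, (s*scales)^2).  During the adaptation window the
    global factor s is tuned every 100 iterations towards the target
    acceptance rate, and every 500 iterations the per-parameter scales
    are refreshed from the recent chain's marginal spreads so dimensions
    with tight posteriors get proportionally smaller steps.  Returns
    (chain, acceptance_rate, final_scales).
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    scales = np.asarray(scales, dtype=float).copy()
    ndim = x.size
    if adapt_until is None:
        adapt_until = n_iter // 2
    lp = log_post(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has zero posterior density")
    chain = np.empty((n_iter, ndim))
    s = 1.0
    accepted = 0
    window_accepted = 0
    for i in range(n_iter):
        prop = x + s * scales * rng.standard_normal(ndim)
        lp_prop = log_post(prop)
        if np.log(rng.uniform()) < lp_prop - lp:
            x, lp = prop, lp_prop
            accepted += 1
            window_accepted += 1
        chain[i] = x
        if i < adapt_until and (i + 1) % 100 == 0:
            rate = window_accepted / 100.0
            s *= np.exp(rate - target_accept)
            window_accepted = 0
        if i < adapt_until and (i + 1) % 500 == 0:
            recent_sd = chain[max(0, i - 499) : i + 1].std(axis=0)
            if np.all(recent_sd > 0):
                scales = recent_sd
                s = 2.4 / np.sqrt(ndim)  # classic optimal-scaling restart
    return chain, accepted / n_iter, s * scales


def _gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor per parameter; chains (m, n, ndim)."""
    m, n, _ = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    return np.where(W > 0, rhat, 1.0)


# ---------------------------------------------------------------------------
# the calibration driver


@dataclass
class CalibrationResult:
    """Posterior summary plus sampler diagnostics."""

    summary: pd.DataFrame  # index: parameter; columns mean, sd, ci_low, ci_high, rhat
    acceptance_rates: list[float]
    n_chains: int
    n_iter: int
    seed: int
    chains: np.ndarray | None = None  # (m, kept, ndim) if requested

    def param_means(self) -> dict[str, float]:
        return self.summary["mean"].to_dict()


def _touches_land_surface(names) -> bool:
    return any(n.startswith(("land.", "land_surface.", "atmosphere.")) for n in names)


def bayesian_calibrate(
    observations: pd.DataFrame,
    priors: dict[str, tuple[float, float]],
    base_params: ParameterSet,
    n_chains: int = 4,
    n_iter: int = 20_000,
    burn_fraction: float = 0.5,
    thin: int = 10,
    seed: int = 0,
    error_sd: dict[str, float] | None = None,
    keep_chains: bool = False,
) -> CalibrationResult:
    """Calibrate the parameters named in *priors* against site observations.

    Priors are independent uniforms over the stated (low, high) ranges.
    Keys are flat parameter names (``"co2.f_slope"``, ``"land.t_w"``);
    keys of the form ``"sigma.<gas>"`` calibrate that gas's observation
    error sd.  If *error_sd* is given instead, the per-gas sd's are held
    fixed.  Only gases with a defined error sd enter the likelihood;
    missing flux values contribute nothing, so an all-missing table
    returns the prior.
    """
    if observations.empty:
        raise ValueError("observations must be non-empty")
    names = list(priors)
    model_names = [n for n in names if not n.startswith("sigma.")]
    sigma_names = [n for n in names if n.startswith("sigma.")]
    if error_sd is None and not sigma_names:
        raise ValueError("either calibrate sigma.<gas> parameters or pass fixed error_sd")

    obs_sorted, _, t_air, pre, lat, soil, ntime, nsite = _site_driver_arrays(observations)
    soil_view = SoilPhysiochem(
        cnr=soil["cnr"], bd=soil["bd"], sand_pct=soil["sand_pct"], clay_pct=soil["clay_pct"]
    )
    with_sigma = {n.split(".", 1)[1] for n in sigma_names} | set(error_sd or {})
    observed = {}
    for gas in Gas:
        col = FLUX_COLUMNS[gas]
        if gas.value not in with_sigma or col not in obs_sorted:
            y = np.full(ntime * nsite, np.nan)
        else:
            y = obs_sorted[col].to_numpy(dtype=float)
        observed[gas] = (y, np.isfinite(y))

    fast_path = not _touches_land_surface(model_names)
    if fast_path:
        wfps0, tsoil0 = _simulate_site_drivers(t_air, pre, lat, soil, base_params)

    lo = np.array([priors[n][0] for n in names], dtype=float)
    hi = np.array([priors[n][1] for n in names], dtype=float)
    if np.any(lo >= hi):
        raise ValueError("each prior must satisfy low < high")

    def log_post(x: np.ndarray) -> float:
        if np.any(x < lo) or np.any(x > hi):
            return -np.inf
        candidate = base_params.with_values(dict(zip(model_names, x[: len(model_names)])))
        try:
            candidate.validate()
        except ValueError:
            return -np.inf
        if fast_path:
            wfps, tsoil = wfps0, tsoil0
        else:
            wfps, tsoil = _simulate_site_drivers(t_air, pre, lat, soil, candidate)
        sigmas = dict(error_sd or {})
        for n, v in zip(sigma_names, x[len(model_names):]):
            sigmas[n.split(".", 1)[1]] = v
        ll = 0.0
        for gas in Gas:
            y, have = observed[gas]
            nobs = int(have.sum())
            if nobs == 0:
                continue
            sig = sigmas[gas.value]
            if sig <= 0:
                return -np.inf
            gp = candidate.gas(gas)
            pred = (f_sp(gp, soil_view)[None, :] * g_wfps(gp, wfps)
                    * h_temp(gp.temp_p, tsoil)).reshape(-1)
            ssr = float(np.sum((pred[have] - y[have]) ** 2))
            ll += -nobs * np.log(sig) - ssr / (2.0 * sig**2)
        return ll

    root = np.random.SeedSequence(seed)
    burn = int(n_iter * burn_fraction)
    kept_chains, rates = [], []
    for k, child in enumerate(root.spawn(n_chains)):
        rng = np.random.default_rng(child)
        # overdispersed start inside the prior box
        for _ in range(1000):
            x0 = lo + rng.uniform(0.1, 0.9, size=len(names)) * (hi - lo)
            if np.isfinite(log_post(x0)):
                break
        else:
            raise RuntimeError("could not find a valid starting point inside the prior")
        scales = 0.05 * (hi - lo)
        chain, rate, _ = metropolis(
            log_post, x0, scales, n_iter, seed=int(rng.integers(2**31 - 1)), adapt_until=burn
        )
        if rate == 0.0:
            raise RuntimeError(
                f"chain {k}: zero acceptance after adaptation (proposal scales {scales})"
            )
        kept_chains.append(chain[burn::thin])
        rates.append(rate)
    stacked = np.stack(kept_chains)  # (m, kept, ndim)
    flat = stacked.reshape(-1, len(names))
    summary = pd.DataFrame(
        {
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "ci_low": np.quantile(flat, 0.025, axis=0),
            "ci_high": np.quantile(flat, 0.975, axis=0),
            "rhat": _gelman_rubin(stacked) if n_chains > 1 else np.nan,
        },
        index=pd.Index(names, name="parameter"),
    )
    return CalibrationResult(
        summary=summary,
        acceptance_rates=rates,
        n_chains=n_chains,
        n_iter=n_iter,
        seed=seed,
        chains=stacked if keep_chains else None,
    )
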