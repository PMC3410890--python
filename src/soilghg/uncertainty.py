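"""Monte Carlo propagation of parameter uncertainty to global totals.

Each replicate redraws every parameter from its uncertainty descriptor --
the summarised calibration posterior for calibrated parameters, a normal
with a 10 % coefficient of variation for the rest -- runs the full grid
simulation, and records the three global totals.  Confidence intervals
are empirical percentiles of the replicate totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import cell_areas, global_total, monthly_to_annual, run_grid
from .params import ParameterSet

__all__ = ["ParameterEnsemble", "sample_parameters", "ensemble_global_totals", "percentile_ci"]

_MAX_REDRAWS = 1000


@dataclass
class ParameterEnsemble:
    """n independent draws of the full parameter set."""

    draws: list[ParameterSet]
    seed: int
    rejections: int = 0
    provenance: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.draws)


def _draw_one(base: ParameterSet, rng: np.random.Generator) -> tuple[ParameterSet, int]:
    """One valid draw; invalid draws (broken invariants) are rejected and redrawn."""
    rejections = 0
    for _ in range(_MAX_REDRAWS):
        updates = {}
        for name, p in base.items():
            sd = p.uncertainty.scale_for(p.value)
            updates[name] = p.value if sd == 0 else rng.normal(p.value, sd)
        candidate = base.with_values(updates)
        try:
            candidate.validate()
        except ValueError:
            rejections += 1
            continue
        return candidate, rejections
    raise RuntimeError("could not draw a valid parameter set; uncertainties too wide")


def sample_parameters(base: ParameterSet, n: int, seed: int) -> ParameterEnsemble:
    """Draw *n* parameter sets, independent across parameters and replicates.

    Draws that violate any parameter invariant (e.g. the a < b < c
    moisture ordering, or a soil-property factor going negative on
    admissible soils) are rejected and redrawn, with the rejection count
    recorded.  Reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base.validate()
    root = np.random.SeedSequence(seed)
    draws, total_rej = [], 0
    for child in root.spawn(n):
        ps, rej = _draw_one(base, np.random.default_rng(child))
        draws.append(ps)
        total_rej += rej
    provenance = {
        name: ("posterior" if p.uncertainty.kind == "posterior_sd" else p.uncertainty.kind)
        for name, p in base.items()
    }
    return ParameterEnsemble(draws=draws, seed=seed, rejections=total_rej, provenance=provenance)


def ensemble_global_totals(
    ensemble: ParameterEnsemble,
    climate,
    soil,
    ch4_ppb,
    spinup_months: int = 24,
) -> pd.DataFrame:
    """One full grid simulation per draw; replicate x gas global totals.

    CO2 totals are Pg C yr-1; CH4 and N2O are Tg C / Tg N yr-1.
    """
    areas = cell_areas(climate["lat"].values, climate["lon"].values)
    rows = []
    for ps in ensemble.draws:
        flux = run_grid(climate, soil, ps, ch4_ppb, spinup_months=spinup_months)
        totals = global_total(monthly_to_annual(flux), areas)
        rows.append(totals)
    out = pd.DataFrame(rows)
    out.index.name = "replicate"
    return out


def percentile_ci(samples, level: float = 0.95) -> tuple[float, float]:
    """Empirical central interval: linear-interpolation percentiles."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples for a percentile interval")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [tail, 1.0 - tail], method="linear")
    return float(lo), float(hi)
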