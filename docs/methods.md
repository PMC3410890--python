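# Methods

`soilghg` is a monthly, data-oriented model of three soil greenhouse-gas
fluxes — CO₂ emission (total soil respiration), CH₄ uptake by upland
soils, and background N₂O emission — driven by gridded air temperature,
precipitation and topsoil (0–5 cm) physiochemical properties.  This note
records the model equations, the parameters that matter, the numerical
choices, what the synthetic-data generator does and does not emulate, and
the known limitations.

## The flux model

Each gas flux is the product of three factors,

    F = f(SP) · g(WFPS) · h(T)            (× j([CH₄]) for CH₄ uptake)

evaluated per cell and month, in native units of µg C m⁻² s⁻¹ (CO₂),
µg C m⁻² h⁻¹ (CH₄) and µg N m⁻² h⁻¹ (N₂O).

**Soil-property factor f(SP).**  Linear in the gas's controlling
property: the CO₂ factor increases with the topsoil C/N ratio, the CH₄
factor decreases with bulk density (BD, Mg m⁻³; highly porous Andosol-like
soils take up the most CH₄), and the N₂O factor is non-decreasing in the
C/N ratio.  Slopes and intercepts are configuration
(`soilghg/data/default_params.yaml`); parameter validation rejects any
combination that would make f negative on admissible soils (C/N in
[3, 40], BD in (0.05, 2.0]).

**Moisture factor g(WFPS).**  A convex bump on water-filled pore space
with exact anchors g(a) = g(c) = 0 and g(b) = 1:

    g(w) = [ ((w−a)/(b−a)) · ((c−w)/(c−b))^((c−b)/(b−a)) ]^d,  a ≤ w ≤ c

and g = 0 outside [a, c] (soils drier than the minimum or wetter than the
maximum produce no flux).  The exponent construction places the unique
interior maximum exactly at the optimum b; d controls curvature.  Per-gas
defaults put the CH₄ optimum dry (b = 0.35; gas diffusion limits uptake in
wet soil), CO₂ intermediate (0.55) and N₂O wet (0.80; denitrification).

**Temperature factor h(T).**  h(T) = exp(p·T) with soil temperature T at
5 cm depth, so h(0 °C) = 1 by construction.  Defaults give a Q₁₀ near 2
for CO₂ (p = 0.07 °C⁻¹) and N₂O (0.08), and a weak response for CH₄
(0.02), which is what makes the simulated CH₄ field much less
temperature-patterned than the other two gases.

**Atmospheric CH₄ factor j.**  j = [CH₄]/[CH₄]_ref, the mixing ratio
relative to a reference (default 1790 ppb, representative of the
calibration period, so j ≈ 1 there and calibrated magnitudes are
unchanged).  CH₄ uptake thus scales linearly with the ambient
concentration.

## Land-surface drivers

**Snow.**  A degree-day store in snow water equivalent (mm): precipitation
falls as snow when T_air ≤ T_snow (0 °C, inclusive), melt proceeds at
S_melt (40 mm °C⁻¹ month⁻¹) per degree above T_melt (1 °C, exclusive),
capped by the stock.  Within a month snowfall is accumulated before melt
and the cover flag reflects the end-of-month store — a monthly step has no
sub-month information, and the end-of-month state is what drives the
soil-temperature switch.  Only the presence of snow matters downstream.

**Soil temperature.**  T_soil = S_st·T_air + I_st (defaults 0.92, 1.2 °C)
when snow-free; a constant T_snowsoil (0.5 °C) under snow, reflecting the
insulating snowpack.

**Potential evapotranspiration.**  The Thornthwaite formulation: annual
heat index I = Σ_m (max(T_m,0)/5)^1.514, exponent
α = 6.75·10⁻⁷I³ − 7.71·10⁻⁵I² + 1.792·10⁻²I + 0.49239, monthly
PET = 16(10T/I)^α mm scaled by the day-length correction (L/12)(N/30),
with L from the standard solar-declination formula at the cell's latitude.
Months at or below 0 °C, and fully frozen years (I = 0), give zero.  The
hot-climate (> 26.5 °C) branch of the original method is not applied; at
desk scale the plain formula is adequate and simpler to reason about.

**Water retention anchor WS₀.**  The WFPS at 30 kPa matric potential,
from the generalized Saxton (1986) retention regression ψ = Aθ^B (texture
regressions for A and B), divided by porosity 1 − BD/2.65.  Texture is
clamped to the regression's validity range (sand 5–95 %, clay 5–60 %) with
a warning, and WS₀ is clipped into (0, 0.99] — dense fine-textured
combinations can push the regression's water content to the pore volume.
The regression is itself marginally non-monotone in clay at its low-clay
edge; this is a property of the published coefficients, not of this
implementation.  A per-cell WS₀ column in the soil input bypasses the
regression entirely.

**Wetness index and WFPS update.**  The month's wetness is

    r = (R_pre·PRE_i + (1−R_pre)·PRE_{i−1}) / max(R_pet·PET_i + (1−R_pet)·PET_{i−1}, 1 mm)

so supply and demand both remember the previous month (weights default
0.7); the 1 mm floor keeps frozen and hyper-arid months finite.  WFPS then
relaxes towards a target WS₀ + s_lnr·ln r (s_lnr = 0.15 per ln unit; r is
floored at 10⁻⁶ before the logarithm):

    WFPS_i = m·WFPS_{i−1} + (1−m)·(WS₀ + s_lnr·ln r),   clamped to [0, 1]

with memory m = 0.5, except in cold months (T_air < T_W = 2 °C) where the
moisture is held frozen at last month's value.  A balanced month (r = 1)
has target WS₀ exactly, so sustained balance converges to WS₀ — the
anchor that defines WS₀'s role.

**Initial state and spin-up.**  Cells start snow-free at WFPS = WS₀ with
previous-month terms set to the first month's values; a 24-month spin-up
repeating the first year's climate precedes every reporting period, long
enough for the moisture memory (m = 0.5 → residual 0.5²⁴) and typical
snow stores to equilibrate.

## Grid pipeline

Cells are masked out when any surface flag (ice, permanent water,
mangrove) is set, any property is missing, or BD ≤ 0.28 Mg m⁻³ (presumed
peat; the model has no wetland CH₄-emission pathway, so peat soils are
excluded rather than mis-simulated).  Cell areas are analytic spherical
areas R²Δλ(sin φ₂ − sin φ₁) with R = 6 371 km, which partition the sphere
exactly.  Native-rate monthly fluxes integrate to annual areal fluxes with
a 365-day no-leap calendar by default (month lengths are configurable;
totals are insensitive at reported precision).  Global totals are
Σ flux·area in Pg C yr⁻¹ (CO₂) and Tg C / Tg N yr⁻¹ (CH₄ / N₂O); zone
contributions split the total by mean annual air temperature — boreal
T < 2 °C, temperate 2 ≤ T ≤ 17, tropical T > 17 (air temperature, since
zone labels describe climate); latitude-month matrices are area-weighted
band means averaged over years; histograms bin per-cell mean annual
fluxes left-closed with a 150 g C m⁻² yr⁻¹ default width for CO₂.

## Calibration

Parameters are calibrated against a monthly multi-site chamber network by
random-walk Metropolis sampling, chosen over black-box samplers for
transparency: the posterior is low-dimensional and the adaptive proposal
(global scale tuned to ≈ 0.3 acceptance every 100 iterations; per-parameter
scales refreshed from the recent chain every 500, with a 2.4/√d restart)
mixes well on it.  The likelihood is independent Gaussian per gas with a
per-gas error sd that is itself calibrated by default (uniform prior);
priors on model parameters are uniform boxes.  Parameter draws violating
structural invariants (the a < b < c moisture ordering, non-negative
f(SP) on admissible soils) receive zero posterior density, so the
effective prior is the box intersected with the admissible region —
prior boxes should be chosen inside it when a pure-box prior is intended.
Site WFPS and soil temperature are simulated from site climate through
the land-surface submodels during calibration, not taken as observed;
when no land-surface parameter is in the calibrated set those drivers are
precomputed once and each likelihood evaluation reduces to vectorised
flux-equation calls.  Convergence is summarised by split-chain
Gelman–Rubin factors; defaults are 4 chains × 20 000 iterations, 50 %
burn-in, thinning 10.

The recovery checks in the test suite use 2 chains × 15 000 iterations on
a 36-site network with 768 non-missing records per gas, calibrating nine
gas-side parameters plus the three error sd's; posterior 95 % intervals
cover the generating values for ≥ 90 % of parameters and R̂ < 1.1.

## Monte Carlo uncertainty

Each ensemble replicate redraws every parameter independently: calibrated
parameters from a normal with their posterior sd, uncalibrated ones from
a normal with a 10 % coefficient of variation, fixed ones not at all.
Draws violating invariants are rejected and redrawn (counts recorded).
Each replicate is one full grid simulation; confidence intervals are
empirical 2.5/97.5 linear-interpolation percentiles of the replicate
totals.  The ensemble default is 1000 replicates; randomness uses one
root seed with per-replicate child streams, so results are reproducible
and order-independent.  Correlated resampling from a saved chain is
possible in principle but not the default — posterior correlations are
not part of the stored uncertainty descriptors.

## The synthetic world

The generator emulates the structure, not the geography, of the real
drivers: a meridional mean-temperature profile (28 °C at the equator,
−0.55 °C per degree latitude) spanning all three climate zones, seasonal
amplitude growing poleward with opposite hemispheric phase, positive
precipitation with a warm-season wet peak, topsoil properties drawn from
realistic ranges (C/N ~ N(15, 4) in [5, 35], BD ~ N(1.2, 0.25) in
[0.35, 1.8]) with a 5 % fraction of peat-like cells (BD ≤ 0.28) and 2 %
of each surface flag, a CH₄ series rising 3 ppb yr⁻¹ with a 15 ppb
seasonal cycle, and a 36-site mid-latitude (31–45°) network measured
monthly over three years, thinned to 768 non-missing records per gas to
emulate uneven site coverage.  Observation noise is additive Gaussian
(matching the calibration likelihood) with sd equal to 10 % of each gas's
simulated flux range.  The default grid is 20 × 40 cells over 5 years —
small enough that the full pipeline and a 1000-member ensemble run in
about a minute.

What the generator does **not** emulate: real continents and oceans (every
unmasked cell is land, so synthetic "global" totals refer to a much larger
soil area than Earth's and are not comparable to observation-based global
budgets), spatial autocorrelation of soils, interannual climate trends,
and flux extremes beyond what the smooth model surface produces.  Passing
tests therefore demonstrate the correctness and internal consistency of
the machinery — unit handling, masking, aggregation, calibration and
uncertainty propagation — not agreement with measured global fluxes.

## Numerical choices and degenerate inputs

- PET denominator of the wetness index floored at 1 mm; r floored at 10⁻⁶
  before ln; WFPS clamped to [0, 1]; WS₀ clipped into (0, 0.99].
- A fully frozen year gives PET = 0 (not an error); an all-missing
  observation table returns the prior (not an error); an empty RMSE or a
  one-sample percentile interval is an error.
- Grid axes must be strictly monotone and climate/soil axes identical; no
  regridding is performed.
- Boundary conventions: snow at T_air ≤ T_snow, melt at T_air > T_melt,
  peat exclusion at BD ≤ 0.28 (inclusive), temperate zone closed on both
  ends ([2, 17] °C).

## Limitations

- The exponential temperature response understates the higher cold-region
  temperature sensitivity of soil CO₂ flux; the moisture response has no
  hysteresis; no snow energy balance, sublimation, soil layering or
  runoff.
- No wetland CH₄ emission and no fertilizer-driven N₂O — only background
  emissions; agricultural and forested cells are not distinguished.
- Parameter uncertainty only: climate/soil input error and model-structure
  error are not propagated.
- The shipped default parameter values are plausible magnitudes chosen to
  produce realistic flux ranges; any quantitative application should
  recalibrate them against the user's own site network via
  `bayesian_calibrate`.
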