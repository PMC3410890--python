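# soilghg

Monthly, data-oriented modelling of three soil greenhouse-gas fluxes on
gridded domains: **CO₂ emission** (total soil respiration), **CH₄ uptake**
by upland soils, and background **N₂O emission**.  The package is aimed at
soil-biogeochemistry and carbon-cycle researchers who want a transparent,
calibratable alternative to heavyweight process models: every flux is the
product of three empirical factors, every parameter is exposed in one
config file with an uncertainty descriptor, and calibration and
uncertainty propagation are first-class operations rather than
afterthoughts.

## The model

For each gas, the monthly flux in native units (CO₂ µg C m⁻² s⁻¹;
CH₄ µg C m⁻² h⁻¹; N₂O µg N m⁻² h⁻¹) is

```
F = f(SP) · g(WFPS) · h(T)          (CH₄ additionally × j([CH₄]))
```

- **f(SP)** — linear soil-property factor: increasing in the topsoil C/N
  ratio for CO₂ and N₂O, decreasing in bulk density for CH₄.
- **g(WFPS)** — a convex moisture response on water-filled pore space
  with exact anchors g(a) = g(c) = 0 and g(b) = 1 and curvature d.
- **h(T)** — exponential soil-temperature response, h(T) = e^{pT}, with
  h(0 °C) = 1.
- **j([CH₄])** — atmospheric CH₄ mixing ratio relative to a reference.

Soil temperature and WFPS are generated from monthly air temperature and
precipitation by simple land-surface submodels: a degree-day snow store
(snow presence switches soil temperature to a constant), a linear
air-to-soil temperature map, Thornthwaite potential evapotranspiration, a
Saxton-type retention anchor WS₀ (WFPS at 30 kPa), and a bucket update
that relaxes WFPS towards WS₀ + s·ln r, where r is a two-month wetness
index of precipitation over PET.  Cells of ice, permanent water, mangrove
or peat (bulk density ≤ 0.28 Mg m⁻³) are masked.  Parameters can be
calibrated against monthly site chamber data by random-walk Metropolis
sampling, and parameter uncertainty is propagated to global totals by a
Monte Carlo ensemble.  See `docs/methods.md` for the full account.

## Worked example

Build a synthetic planet (20 × 40 cells, 5 years), run the model, and
aggregate:

```python
import soilghg as sg

spec = sg.SyntheticSpec(seed=7)
climate = sg.synth_climate(spec)          # monthly T (°C), precip (mm)
soil = sg.synth_soil(spec)                # C/N, bulk density, texture, flags
ch4 = sg.synth_ch4_series(spec)           # rising ppb series

params = sg.default_parameters()
flux = sg.run_grid(climate, soil, params, ch4)        # native-rate fields
annual = sg.monthly_to_annual(flux)                   # g C (g N) m⁻² yr⁻¹
areas = sg.cell_areas(climate["lat"].values, climate["lon"].values)

print(sg.global_total(annual, areas))
print(sg.zone_contributions(annual, sg.mean_annual_temperature(climate), areas))
```

This prints (values rounded here):

```
{'co2': 129.4, 'ch4': 104.8, 'n2o': 15.6}
{'co2': {'boreal': 0.14, 'temperate': 0.33, 'tropical': 0.53},
 'ch4': {'boreal': 0.28, 'temperate': 0.32, 'tropical': 0.40},
 'n2o': {'boreal': 0.11, 'temperate': 0.39, 'tropical': 0.50}}
```

The totals are Pg C yr⁻¹ for CO₂ and Tg C / Tg N yr⁻¹ for CH₄ / N₂O,
summed over the 729 unmasked cells; the zone dictionaries give each
climate zone's share of the global total (boreal: mean annual temperature
< 2 °C; temperate: 2–17 °C; tropical: > 17 °C).  The tropics dominate all
three gases, most strongly CO₂ and N₂O, whose temperature sensitivities
are high; the CH₄ pattern is flatter because its temperature response is
weak and its soil-property control (bulk density) has no latitudinal
structure.  Note the synthetic planet is all land — these totals describe
a soil area ~4.6× Earth's actual soil area and are internal-consistency
numbers, not Earth estimates.

The same pipeline is scriptable from the shell:

```sh
soilghg synth --kind climate --seed 7 --out climate.nc
soilghg synth --kind soil    --seed 7 --out soil.nc
soilghg synth --kind ch4     --seed 7 --out ch4.csv
soilghg simulate --climate climate.nc --soil soil.nc --ch4 ch4.csv --out flux.nc
soilghg summarize --flux flux.nc --climate climate.nc --zones --histogram --out summary.yaml
soilghg ensemble --climate climate.nc --soil soil.nc --ch4 ch4.csv --n 1000 --seed 7 --out totals.csv
```

`soilghg calibrate` fits parameters to a site observation CSV (one row
per site-month) given a YAML file of uniform prior ranges, and
`soilghg estimates` computes mean / CV / N statistics of a user-supplied
compilation of published global estimates.

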