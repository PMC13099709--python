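# cutaway — after-use planning and climate impact of cutaway peatlands

When industrial peat extraction ends, the cutaway field — a thin layer of
highly decomposed residual peat over mineral subsoil — must be given a new
land use: afforestation, peatland restoration, open-water wetland creation,
agriculture, or at minimum a vegetated surface. These after-uses differ
sharply in their greenhouse-gas balance, and the site itself constrains
which of them are feasible where: cells near the outflow-ditch bottom
cannot be kept dry without pumping, cells above the border embankments
cannot be rewetted without flooding the surroundings, thick (> 100 cm)
residual peat keeps tree roots from the subsoil, and thin (< 40 cm) peat
over coarse till rules out cultivation.

`cutaway` is a pipeline for planners and researchers who want to quantify
those trade-offs: from site rasters (surface elevation, peat thickness,
subsoil category) through rewetting-potential classification, land-use
suitability, objective-driven allocation scenarios, and finally the
site-level climate impact of each scenario. A synthetic-site generator
emulates the survey data (drone elevation models, ground-penetrating-radar
peat surveys) of boreal extraction fields so the whole chain is testable
and reproducible without proprietary geodata.

## The model

**Suitability.** Each cell with elevation $z$ is classified against the
main outflow-ditch bottom level $z_d$ and the maximum water level $z_w$
tolerated by the border embankments:

- constrained wet (open-water-likely): $z \le z_d + 0.5\,\mathrm{m}$
- flexible (wet or dry by ditch/dam design): $z_d + 0.5 < z \le z_w$
- constrained dry: $z > z_w$

Dry uses are excluded from constrained-wet cells and wet uses from
constrained-dry cells; peat-thickness classes (< 40, 40–100, > 100 cm) and
subsoil gate afforestation and agriculture. D8 flow-accumulation and
catchment utilities support judging the water available for rewetting.

**Scenarios.** Five priority orderings (climate regulation, ecological
restoration, food production, timber production, peat-replacing biomass)
assign each cell its first feasible use; all place open-water wetlands in
the lowest depressions.

**Climate impact.** Each land use carries a piecewise-constant per-gas
emission trajectory $E_g(t)$ (t gas ha⁻¹ yr⁻¹; CO₂, CH₄, N₂O, with DOC
booked as CO₂ in the year of loss). Agricultural uses mine the residual
peat: their carbon fluxes stop after the depletion time
$t_{dep} = 100\,d\,\rho\,f_C / L$ (depth $d$ in cm, bulk density
$\rho = 0.18$ g cm⁻³, carbon fraction $f_C = 0.523$, annual C loss $L$).
Atmospheric burdens follow impulse-response functions
$\mathrm{IRF}_g(t) = \sum_i a_i e^{-t/\tau_i}$ (multi-exponential with a
permanent fraction for CO₂; single lifetimes 11.8 / 109 yr for CH₄ / N₂O),
and marginal radiative efficiencies are evaluated on the SSP2-4.5
background (log-linearized for CO₂, so the efficiency falls as the
background rises; CH₄ carries an indirect-effects multiplier). The result
is reported as the **constant CO₂-equivalent emission** over horizon $H$:

$$E^* = \frac{\int_0^H F_{\text{trajectory}}(t)\,dt}{\int_0^H F_{\text{1 t CO}_2/\text{yr}}(t)\,dt}
\quad (H = 16 \text{ or } 100 \text{ yr, from } 2020),$$

the steady CO₂ emission with the same time-integrated radiative forcing.
Scenario totals are $\sum_{\text{uses}} A_u \cdot E^*_u$ with min/max from
re-running the emission-factor band endpoints through the forcing model.

## Worked example

```python
from cutaway import (generate_site, kampinneva_like_config,
                     run_pipeline, reports_frame)

site = generate_site(kampinneva_like_config(rng_seed=0))  # 123.00 ha
reports = run_pipeline(site)          # 5 scenarios x horizons (16, 100)
print(reports_frame(reports).round(2).to_string(index=False))
```

```
              scenario  horizon_yr  total_t_co2eq_yr  per_ha_t_co2eq_yr  min_t_co2eq_yr  max_t_co2eq_yr
    climate_regulation          16            100.63               0.82         -390.87          991.21
    climate_regulation         100             62.65               0.51         -412.14          871.11
ecological_restoration          16            817.42               6.65          359.58         1852.63
ecological_restoration         100            598.55               4.87          241.96         1242.12
       food_production          16           2283.99              18.57         1040.02         3613.47
       food_production         100           2292.85              18.64         1064.95         3398.26
     timber_production          16            444.31               3.61         -258.02         1428.57
     timber_production         100            486.01               3.95         -238.05         1485.28
peat_replacing_biomass          16            715.92               5.82          255.71         1259.77
peat_replacing_biomass         100            693.40               5.64          235.28         1185.69
```

Totals are t CO₂-eq yr⁻¹ for the whole 123-ha site; per-ha values divide
by site area. Prioritizing short-rotation birch with restoration and open
water in the wet parts (climate regulation) is near climate-neutral over a
century (0.5 t CO₂-eq ha⁻¹ yr⁻¹), while prioritizing forage grass (food
production) warms ~35× more (18.6); the min/max columns propagate the
emission-factor uncertainty bands end to end.

The numbered drivers under `analysis/` run the same chain step by step
(site generation → hydrological classes → suitability → allocation →
per-land-use impacts → scenario impacts) and write their tables under
`results/`. A thin CLI mirrors them (`cutaway generate|classify|
suitability|allocate|run-all`).

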