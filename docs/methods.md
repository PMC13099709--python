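# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what the synthetic data can and cannot show.

## Synthetic site generator

The generator emulates a boreal peat-extraction field, not any particular
real site. Surface elevation is a base level plus a gentle regional slope,
a smoothed Gaussian random field for micro-topography, a few
Gaussian-shaped depressions (deeper-extracted pockets that collect water),
and a raised border rim: extraction digs the field below the surrounding
land, and the remaining rim is what allows the interior to be flooded
without affecting the surroundings. Without the rim essentially no cell
can be rewetted, which contradicts how these fields behave; its default
height (0.6–0.8 m) was chosen from that qualitative consideration.

Residual peat thickness is a clipped, spatially autocorrelated field
(mean 60 cm, SD 45 cm, clipped to 0–330 cm in the reference preset),
giving mostly sub-100-cm peat with scattered thick pockets. Subsoil
categories are obtained by quantile-thresholding a smoothed field, so
realized areal fractions converge to the configured targets (sand 0.22,
sandy till 0.56, silt/clay 0.15, gyttja 0.04, bedrock 0.01, fine till
0.02 in the reference preset) while forming contiguous patches. The
autocorrelation length (6 cells) is a free parameter: no within-site
variograms are available, so it is a plausibility choice, not a claim
about real sites.

The reference preset uses 123 rows × 100 cols of 10 m cells, i.e. exactly
123.00 ha (0.01 ha per cell), so hectare totals are representable.
The ditch bottom sits 0.2 m below the site's minimum surface; the maximum
water level is the lowest perimeter elevation minus an optional freeboard
margin.

What passing tests on synthetic sites show: the classification,
allocation and accounting machinery is correct under controlled marginal
statistics. What they do not show: performance on real survey rasters with
anisotropic structure, survey noise, no-data gaps from GPR line spacing,
or ditch networks more complex than a single outflow level.

## Hydrological classification and flow routing

Classification uses two scalars per site. A cell is constrained to wet
uses (and likely open water) if its surface is at or below 0.5 m above
the main outflow-ditch bottom — such cells cannot be kept dry without
pumping. A cell is constrained to dry uses if it lies above the maximum
water level the border embankments allow without flooding surrounding
land. Cells between can be made wet or dry by ditch and dam design. The
embankment constraint is deliberately reduced to one interpretable scalar
per site rather than a flood-extent simulation; the boundary values (cell
exactly at ditch + 0.5 m) classify as wet.

Flow accumulation is single-direction D8: each cell drains to its
steepest-descent neighbour; among equally steep neighbours the first in
fixed N, NE, E, SE, S, SW, W, NW order wins. Flat cells drain toward the
nearest already-resolved equal-elevation neighbour by breadth-first
search; closed plateaus and pits are terminal, and edge cells may drain
off-grid. These tie-breaks exist for determinism (the reference GIS
implementations do not document theirs). Catchment utilities are
informational; water-balance sufficiency for rewetting is not modelled.

## Suitability rules

Peat thickness classes are < 40 cm, 40–100 cm and > 100 cm, with both
boundary values assigned to the middle class; the thresholds live in one
constant table. Dry uses (pine and short-rotation birch afforestation,
vegetated surface, forage grass, drained reed canary grass) are feasible
on dry-capable cells; wet uses (restoration, open-water wetland) on
wet-capable cells; open water only on the open-water-likely cells.
Afforestation is excluded on thick peat (roots cannot reach the mineral
subsoil without repeated fertilization); agriculture is excluded where
thin peat overlies sandy or boulder-rich till, and wherever stones are
flagged (the stone mask is an optional layer, empty by default). Gyttja
and bedrock subsoils are not excluded from agriculture — the rule set
covers only the coarse tills — but bedrock cells are worth flagging in
reports. The vegetated surface is feasible on all dry-capable cells
regardless of peat and subsoil, as the permit-mandated minimum option.

## Scenario allocation

Each scenario is an ordered priority list; each cell receives the first
feasible use. Open-water wetland leads every list, so all five scenarios
share the same open-water extent (the lowest depressions). In the
climate-regulation scenario birch precedes restoration in the list so
that flexible cells are afforested and restoration covers only the
wet-constrained remainder — the allocation the objective implies.
Cells feasible for none of the listed uses fall back to restoration if
wet-capable, else to the vegetated surface (the only wet alternative to
open water, and the mandated minimum, respectively); fallback area is
recorded per allocation so it can be audited. Areas are exact multiples
of the cell area and are rounded only at presentation.

## Emission-factor registry

The registry is a CSV of piecewise-constant phases per (land use, gas):
carbon species (CO₂, CH₄, DOC) in t C ha⁻¹ yr⁻¹, N₂O in t N₂O-N ha⁻¹
yr⁻¹, each with a central value and a low/high band (range across
studies or 95% CI, recorded in `uncertainty_kind`), and a source tag so
users can substitute their own compilation. Growing-season-only studies
are annualized by adding a winter CO₂ emission of 15% of growing-season
ecosystem respiration (`annualize_growing_season`); central estimates use
the median when study values are not normally distributed
(`central_estimate`).

Bundled defaults give 100-yr mean net C balances of −0.5 (pine), −0.2
(short-rotation birch), −0.5 (restoration), +0.2 (wetland), +5.7 (forage
grass), +1.3 (drained reed canary grass) and +1.5 (vegetated surface)
t C ha⁻¹ yr⁻¹. The grass figures follow the IPCC drained boreal grassland
factors (CO₂-C 5.39, DOC 0.31, N₂O-N 0.0095 with their CIs); the
restoration chronosequence has a first-year straw-decomposition pulse
(+3.0 t C), an establishment phase to year 15, then a developing moss
sink, with rewetted-peatland CH₄ throughout; the open-water wetland emits
littoral CH₄ at 0.14 t CH₄-C ha⁻¹ yr⁻¹ from year 10 onward (matching the
standard pond emission factor). Afforestation rows are net stand + soil
balances, not a forest-growth model; rotation-end harvest is out of
scope. Reference-only rows (`reference_*`, fluxes from former
agricultural peatlands) are never allocatable.

Two accounting rules: DOC counts toward the carbon balance and peat
depletion but is booked as CO₂ released in the year of loss for forcing —
a conservative choice where the literature is silent. And for the
peat-mining uses (grass, drained reed canary grass) all carbon species
stop at depletion, with the depletion year scaled by its fractional
remainder so cumulative emitted carbon equals the initial stock
(100 · depth · 0.18 g cm⁻³ · 0.523); N₂O phases continue, since the rule
set ties only the carbon species to the peat stock. Endpoint runs
('low'/'high') use their own loss rate for the depletion time.

## Forcing model and CO₂ equivalence

The published analysis used a proprietary climate-impact model whose
internal constants are not public; this package implements the standard
computation class with assessment-report constants in a provenance-tagged
data file: the Joos et al. (2013) multi-model CO₂ impulse response
(fractions 0.2173/0.2240/0.2824/0.2763; time constants ∞/394.4/36.54/4.304
yr), single lifetimes 11.8 yr (CH₄) and 109 yr (N₂O), radiative
efficiencies 3.88 × 10⁻⁴ (CH₄) and 3.0 × 10⁻³ (N₂O) W m⁻² ppb⁻¹, a CH₄
indirect-effects multiplier of 1.65, and CO₂ efficiency from linearizing
5.35 ln(C/C₀) at each year's SSP2-4.5 background concentration (decadal
table, linearly interpolated, 2020–2120). Agreement with the published
per-hectare impacts is an approximation target (±25%), not an identity;
in practice the central values land within ~20% (grass 26.5 vs 26,
vegetated 5.5 vs 6, restoration 2.7 vs 3, wetland 10.7 vs 9 t CO₂-eq
ha⁻¹ yr⁻¹ at 100 yr).

Numerics: annual time step, emissions as mid-year pulses, integration
window half-open `[2020, 2020 + H)`. The equivalence is a ratio of
integrated forcings, so it is exactly linear in the trajectory and a
constant-CO₂-only trajectory maps to its own rate identically. Note that
sustained-source equivalence weights CH₄ more heavily than the familiar
pulse GWP (≈60 vs ≈30 per tonne over 100 yr here): CH₄ forcing from a
constant source saturates within a few lifetimes, while CO₂ forcing keeps
accruing, and the falling marginal CO₂ efficiency along SSP2-4.5 raises
the ratio further. Step vs trapezoidal integration agrees within 2% on
smooth trajectories.

## Pipeline aggregation

Per-hectare impacts of the peat-mining uses depend on local peat depth
through depletion, so their allocated cells are binned by depth (10 cm
bins by default, configurable) and a trajectory is built at each bin's
mean depth; the per-use impact is the cell-count-weighted mean. Other
uses are depth-independent. Min/max scenario bounds re-run every
trajectory at its band endpoints through the full forcing model — no
Monte Carlo by default. Reports satisfy, by construction and by test:
breakdown areas sum to site area, total = Σ area × per-ha impact,
min ≤ central ≤ max, and end-to-end determinism for fixed seed and
inputs.

The per-land-use summary figures (and the reconciliation checks) are
computed at 200 cm peat so no depletion occurs inside the century;
depletion enters at scenario level through cell depths, mirroring how
the site analysis used surveyed depth data.

## Problem sizes

The reference analyses run on the 123 × 100-cell preset (12,300 cells),
chosen to make the hectare bookkeeping exact; property suites use grids
from 1 × 5 to 200 × 200 and 50 random 15 × 12 sites. The whole test suite
and the acceptance script each complete in a few seconds on one CPU.

## Known limitations

- The embankment constraint is a single scalar; terraced or
  compartmentalized rewetting designs are not modelled.
- No hydraulic or water-balance modelling: catchment sufficiency for
  rewetting is reported, not verified.
- Afforestation carbon is a constant net balance, not an age-dependent
  growth curve; harvest and rotation dynamics are out of scope.
- The uncertainty propagation treats band endpoints as perfectly
  correlated across gases and phases within a land use; it brackets
  rather than quantifies the distribution.
- Background-concentration feedbacks from site emissions are ignored
  (hectare-scale fluxes are infinitesimal against the global background).
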