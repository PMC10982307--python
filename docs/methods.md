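# Methods

## Model overview

The simulator is a deliberately transparent proxy for an ensemble crop
model: a single thermal-time phenology driver with a photoperiod
modifier, an expolinear canopy / radiation-use-efficiency growth model,
and a one-bucket soil water balance.  It is intended to reproduce the
*relative* geography of soybean feasibility — which climates allow a
cycle to complete, how water limitation separates rainfed from potential
yield — not to predict absolute yields at any real location.

### Phenology

Daily thermal time: `GDU = max(0, (clamp(Tmin,10,30) + clamp(Tmax,10,30))/2 − 10)`,
so a single day contributes 0–20 °C·d.  Planting is adaptive: the first
day at or after March 1 whose trailing 7-day mean GDU strictly exceeds
4.4.  The window is trailing (the 7 days ending today) because the rule
is a causal farm decision; the first evaluable day is the 7th of the
series.  The rule needs a cutoff to terminate: after June 30 the season
is declared unplanted.  Emergence follows 70 GDU accumulated from the day
after planting — at the planting threshold rate this is 70/4.4 ≈ 15.9
days of thermal time, i.e. planting only happens where emergence is
reachable within about 16 days.

R1/R5/R7 are reached at cumulative modified GDU targets accumulated from
emergence.  The per-maturity-group targets (R7 from 880 °C·d for group
0000 to 1300 °C·d for group III, R1/R5 scaled accordingly) and the
photoperiod slopes (0 to 0.024 h⁻¹ beyond a 13.5-h critical daylength)
are package defaults shipped as editable configuration.  They are chosen
to be agronomically plausible and to produce the qualitative
success/yield ordering across the packaged climate archetypes; they are
*not* calibrated to any trial dataset, and the model's adequacy is judged
by its ordering properties (stage ordering, monotonicity in maturity
group, warming never delaying stages), not by stage-date error.
Daylength uses the standard solar-declination formula (civil daylength,
sun centre at the horizon).

### Growth and water balance

LAI follows `min(LAI_max, (c/r)·ln(1+e^{r(t−t_b)}))` with defaults
c = 0.12 d⁻¹, r = 0.15 d⁻¹, t_b = 18 d, LAI_max = 6.  Fractional
interception is `1 − e^{−k·LAI}` (k = 0.65); biomass grows at
RUE = 0.85 g MJ⁻¹ of intercepted solar radiation, multiplied by the water
stress factor; 55% of daily biomass becomes grain between R5 and R7.
Yields are reported at 13% grain moisture (the source tables state no
moisture basis; this is the trade convention).  RUE and the fill fraction
were fixed once with `scripts/tune_growth.py` so the continental
archetype's best-group potential yield lands in a 3–5 t/ha window.

Evaporative demand is Priestley–Taylor (α = 1.26, net radiation taken as
0.5 × incoming solar) scaled by fractional interception; no named ET
scheme is prescribed by the source description, so this is a package
choice.  The bucket update evaluates stress on the pre-update store,
`stress = min(1, PAW/(2·h·capacity))` with half-point h = 0.5 (i.e.
stress is linear in relative available water), takes
`ET = demand × stress` (never more than the water present), and spills
inflow above capacity as runoff.  Conservation
`ΔPAW = P − runoff − ET` holds to machine precision and is asserted in
tests.  Initial rainfed water is
`(sm_mean + offset·sm_sd − wilting_point) × 1 m × 1000`, clamped to
[0, capacity], with offset −1/0/+1 for the three ensemble members.

### Failure rules and the factorial

A season fails if it never plants, if any day between emergence and R7
(inclusive) has daily mean temperature (Tmin+Tmax)/2 below 0 °C, or if
planting→R7 exceeds 170 days (strictly).  "Mean temperature" is not
defined in the source; the midrange of Tmin/Tmax is used.  A season that
plants but never reaches R7 within the calendar year is classed
*overlong*: with planting bounded by June 30 the remaining window always
exceeds 170 days, so the label is accurate rather than a fourth rule.
The potential configuration obeys the same failure rules (frost and
cycle length are not water phenomena).  Failed yields are exactly 0;
successful yields are capped at 7 t/ha, applied per season before any
averaging.

## Synthetic inputs

The weather generator is monthly climatology (first annual Fourier
harmonic through 12 monthly means) + a shared AR(1) daily temperature
anomaly (ρ = 0.7, innovation sd 1.5 °C) + a per-year offset + a jittered
diurnal range kept in (0, 25] °C, with Bernoulli-gamma precipitation
(shape 0.75, wet-day probability per archetype, monthly means preserved
in expectation) and a sinusoidal radiation cycle damped 25% on wet days.
Four archetypes (maritime, continental, mediterranean, subarctic) are
parameterised so that annual thermal time orders
mediterranean > continental > maritime > subarctic, the subarctic July
mean maximum stays below 15 °C (no season both plants and matures), the
mediterranean summer is dry (rainfed ≪ potential), and the maritime
climate supports only the earliest maturity groups at modest yield.

What the generator does **not** emulate: spatial correlation between
sites (each site is drawn independently; the real gridded inputs are
smooth in space), weather trends, heat waves beyond AR(1) persistence,
and any covariance between radiation and temperature anomalies.
Passing tests therefore demonstrate the pipeline's internal correctness
and qualitative climate responses, not skill against observed European
weather.  Soils are drawn uniformly within plausible texture bounds
(wilting point 0.08–0.16, porosity 0.40–0.52), giving plant-available
capacities of roughly 110–290 mm over the 1-m root zone.

Yield series for the trend module are linear trend + Gaussian noise,
floored at zero, over 29 years (1992–2020 analog).

## Regionalization

Fifteen statistics per site — mean rainfed yield per maturity group
(years × 3 rainfed members, failures as zeros), success rate per group
(fraction of non-failed years), and mean planting day — are min–max
normalized (constant variables dropped with a warning; a never-planting
site's planting day is absent-coded as 0 after normalization).  Spatial
weights are binary within a 75-km great-circle band (haversine, mean
radius 6371 km).  Ward agglomeration runs with merges restricted to the
adjacency graph.  When the graph is disconnected, clusters are allocated
to components proportionally to size (each at least one) and Ward runs
within components, so every cluster is spatially connected by
construction; if components outnumber the requested clusters, each
component becomes its own cluster and a warning is emitted.  The cluster
table reports, per cluster, the maturity group with the largest median
per-site yield (ties toward the earlier, lower-risk group), that group's
pooled mean ± sd over sites, and the median success rate.  Pooling
spatial and temporal spread into a single sd is a documented choice; the
source is ambiguous about how the two are combined.

## Scenario accounting

Defaults: set-aside ratio 6.1% (half used), eligibility 3 t/ha,
wheat conversion 10%, wheat yield 7.1 t/ha, European mean soy yield
3.2 t/ha, Brazil 5 t/ha, import intensity 1.39 kg CO₂e/kg, sequestration
3.6 t C/ha/yr.  Two interpretation points are worth flagging:

* **Sequestration units.**  The 3.6 is read as tonnes of *carbon* and
  converted by 44/12 to 13.2 t CO₂e/ha/yr.  Only this reading reproduces
  the published COC pairs (1.8 Mha → 24, 6.5 → 86, 15 → 198 Mt CO₂e);
  the factor is overridable in configuration.
* **"Current yields".**  The wheat-replacement current-yield scenario
  produces at the 3.2 t/ha European mean rather than at cluster rainfed
  yields; only that choice approaches the published production.  The
  set-aside scenarios use cluster yields (rainfed or potential).  The
  two published set-aside productions (9 and 13 Mt) cannot both be
  reproduced from the cluster table under any single yield reading
  (cluster-rainfed weighting gives ≈ 12.7 Mt, potential ≈ 24.5 Mt); both
  yield choices are exposed and the ledger reports what it computes.

Net cropland for the wheat scenarios is compensatory wheat area
(displaced wheat ÷ 7.1) minus Brazilian area spared (production ÷ 5) —
for the current-yield variant these nearly cancel, leaving ≈ +1.3 Mha.
The diet scenarios split half the production into equal thirds of
chicken, pork and milk (1:1 protein substitution for meat via protein
contents; 7 kg milk per kg soy), then look avoided feed, land,
fertiliser-N and production GHG up in a registry
(`eurosoy/data/feed_coefficients.yaml`).  The registry values are
synthetic placeholders in the style of an LCA feed inventory — the real
coefficients are not printed in the source — so the diet scenarios'
absolute feed/N/GHG rows are configuration-dependent and are tested for
structure, sign conventions and nesting (Sc-5/6 grow exactly Sc-3/4's
soybean), not for numeric agreement with any published row.  Product GHG
intensities in the registry exclude the soy-feed share, which is
accounted on the import route, avoiding double counting.

Ledger sign convention: savings negative, burdens positive.  Full
precision is carried internally; `format_ledger` rounds only for display
(integer Mt, one-decimal Mha).

## Trends and validation

Yield trends are ordinary least squares of yield on year
(scipy linregress, cross-checked in tests against a normal-equations
oracle).  Percent-per-year uses the fitted value at the series' first
year as base (configurable to the series mean); the source states no
base.  The yield gap may be negative when observations exceed the
simulated ceiling and is returned as computed.  MBE is unit-agnostic;
MAPE requires strictly positive observations; Pearson r is reported as
NaN for constant vectors.

## Problem sizes and numerical notes

The test suite and acceptance script run reduced designs chosen as
adequate for the properties they check: single-site 10-year factorials
per archetype (280 simulations each), a 2-site × 2-year factorial for
exact-count checks, a 3 × 3-site 2-year end-to-end pipeline, a 200-site
planted-structure clustering benchmark (20 seeds), and 500-draw
Monte-Carlo recovery for the trend fit.  The full 2,260,160-run design
is represented by count arithmetic plus exact Cartesian-product checks on
the reduced grids.  All generators are pure functions of their seed;
the factorial engine and pipeline are deterministic given their inputs
(rerun manifests hash-identical).  Degenerate inputs are defined
explicitly: empty buckets yield zero stress and zero ET, constant
clustering variables are dropped, a cluster of all-failed sites reports
0 ± 0 yields with maturity group "na".

## Known limitations

No nitrogen budget, pests, weeds, CO₂ fertilization or double-cropping;
no spatial correlation in synthetic weather; phenology is a single-model
proxy rather than an ensemble; absolute yields depend on uncalibrated
defaults; diet-scenario absolute rows depend on the placeholder feed
registry; no cartography or data-service clients.
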