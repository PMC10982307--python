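# eurosoy

Tools for assessing where soybean could be grown across Europe and what an
expansion would mean for land use and greenhouse-gas emissions.  The package
simulates soybean phenology and water-limited growth on gridded sites, groups
sites into spatially contiguous agroclimatic clusters, and converts cluster
areas and yields into production / land / fertiliser-N / GHG ledgers for six
cultivation-and-diet scenarios.

## What it computes

**Phenology.**  Daily thermal time is accumulated as growing degree units,
`GDU = max(0, (clamp(T_min, 10, 30) + clamp(T_max, 10, 30))/2 − 10)` °C·d.
Planting occurs on the first day from March 1 whose trailing 7-day mean GDU
exceeds 4.4; emergence after 70 GDU; flowering (R1), begin seed fill (R5) and
physiological maturity (R7) at maturity-group-specific cumulative GDU targets,
with post-emergence development slowed multiplicatively under daylengths
beyond a critical value.  Maturity groups span 0000 (earliest) to III.

**Growth and water.**  Canopy leaf area follows an expolinear curve
`LAI(t) = min(LAI_max, (c/r)·ln(1 + e^{r(t − t_b)}))`; biomass accumulates as
RUE × intercepted radiation × water stress; a fraction of daily biomass goes
to grain between R5 and R7.  The root zone is a single bucket: Priestley–
Taylor demand scaled by canopy cover, linear soil-water stress, overflow as
runoff, exact water conservation every step.  A *potential* configuration
(stress ≡ 1) and three rainfed members (initial soil moisture at −1/0/+1
ensemble standard deviations) mirror the study design of
4036 sites × 20 years × 7 maturity groups × 4 configurations = 2,260,160
simulations (560 per site).  Seasons fail on any frost day (mean temperature
< 0 °C between emergence and R7), cycles longer than 170 days, or no
planting; failed yields are 0 and successful yields are capped at 7 t/ha.

**Regionalization.**  Fifteen per-site statistics (rainfed yield and success
rate per maturity group, mean planting day) are min–max normalized and
clustered with Ward agglomeration constrained to a 75-km great-circle
distance-band graph, so clusters are spatially contiguous.

**Scenarios.**  From a cluster table (the published 16-cluster summary ships
as a fixture), six ledgers: soy on 50% of a 6.1% set-aside ratio (Sc-1/2),
10% of wheat area converted to soy where yields reach 3 t/ha (Sc-3/4), and
the same with half the soy displacing chicken/pork/milk (Sc-5/6).  European
soy replaces Brazilian imports (1.39 kg CO₂e/kg; 5 t/ha), displaced wheat is
costed at 7.1 t/ha, and net spared land earns a carbon opportunity cost of
3.6 t C/ha/yr × 44/12 ≈ 13.2 t CO₂e/ha/yr.

**Trends.**  OLS national yield trends (slope, %/yr, p), yield gaps
`100·(Y_wl − Y_obs)/Y_wl`, trade seed-equivalents (oil/0.178 + cake/0.792),
and validation metrics (Pearson r, mean bias error, MAPE).

## Worked example

```python
import eurosoy as es

table = es.load_table1_fixture()
coeffs = es.ScenarioCoefficients()
area, prod, wheat = es.scenario_wheat_replacement(table, coeffs, "rainfed")
print(f"{area:.1f} Mha soy, {prod:.1f} Mt soy, {wheat:.0f} Mt wheat displaced")
```

prints

```
3.6 Mha soy, 11.5 Mt soy, 26 Mt wheat displaced
```

i.e. converting 10% of the wheat area in the clusters whose rainfed soybean
yield reaches 3 t/ha (clusters E, F, G, I) plants 3.6 Mha of soybean,
produces 11.5 Mt of beans at the 3.2 t/ha European mean yield, and displaces
26 Mt of wheat.  Feeding that production into
`es.import_substitution(prod, coeffs)` gives −16 Mt CO₂e/yr of avoided
import emissions.  The `examples/` directory has one narrative script per
capability (single-season simulation, factorial + clustering, scenario
ledgers, trends/validation); each prints its numbers with a line on what
they mean.  A thin CLI mirrors the stages:
`eurosoy simulate|cluster|scenarios|trends|demo|all`.

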