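"""Simulate one soybean season at a continental site.

Generates a year of synthetic daily weather, applies the adaptive
planting rule (first day from March 1 whose trailing 7-day mean GDU
exceeds 4.4), predicts the phenological stages for maturity group 0, and
grows the crop under the potential and rainfed water configurations.
"""

import eurosoy as es

LAT = 47.0

weather = es.gen_weather(es.DEFAULT_ARCHETYPES["continental"], n_years=1,
                         seed=3, lat=LAT)
planting = es.decide_planting(weather)
stages = es.predict_stages(weather, planting, mg="0", lat=LAT)
print(f"planting day of year: {planting}")
print(f"stages: emergence={stages.emergence}  R1={stages.r1}  "
      f"R5={stages.r5}  R7={stages.r7}")

soil, moisture = es.gen_soil(seed=2)
y_pot, _ = es.simulate_season(weather, stages, soil, moisture,
                              es.SimConfiguration("potential"))
y_rf, state = es.simulate_season(weather, stages, soil, moisture,
                                 es.SimConfiguration("rainfed", 0))
print(f"potential yield: {y_pot:.2f} t/ha   rainfed yield: {y_rf:.2f} t/ha")
print(f"season water: {state.precip_cum_mm:.0f} mm rain, "
      f"{state.et_cum_mm:.0f} mm ET, {state.runoff_cum_mm:.0f} mm runoff")
# The gap between potential and rainfed yield is the water limitation at
# this site; stage day-of-year values drive the frost/overlong failure rules.
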