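"""Yield trends, yield gaps, trade seed-equivalents and validation metrics.

Fits a linear trend to a synthetic FAO-style national yield series,
expresses the slope as percent per year, computes the water-limited yield
gap, converts traded oil/cake back to bean equivalents, and scores a
simulated-vs-observed comparison.
"""

import eurosoy as es

series = es.gen_yield_series(1992, 29, intercept=2.0, slope=0.05,
                             noise_sd=0.3, seed=11, country="demo")
fit = es.fit_yield_trend(series)
print(f"fitted slope: {fit.slope_t_ha_yr:.3f} t/ha/yr "
      f"({fit.pct_per_year:.1f} %/yr, p={fit.p_value:.1e})")

gap = es.yield_gap(water_limited_t_ha=3.6,
                   observed_t_ha=series["yield_t_ha"].iloc[-1])
print(f"yield gap vs a 3.6 t/ha water-limited ceiling: {gap:.0f} %")

beans = es.seed_equivalents(seed_mt=1.0, oil_mt=0.5, cake_mt=2.0)
print(f"1.0 Mt beans + 0.5 Mt oil + 2.0 Mt cake = {beans:.2f} Mt seed equivalent")

metrics = es.validation_metrics([2.1, 2.8, 3.4, 1.9], [2.5, 3.1, 3.6, 2.6])
print(f"validation: r={metrics.pearson_r:.2f}  MBE={metrics.mbe:.2f} t/ha  "
      f"MAPE={metrics.mape_pct:.0f} %")
# A negative MBE means the simulations sit below the observations; MAPE
# summarises relative error irrespective of sign.
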