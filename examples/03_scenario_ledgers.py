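"""Compute the six environmental-savings scenario ledgers.

Uses the packaged cluster table (arable areas, wheat fractions, rainfed
and potential yields per cluster) and the default coefficient registry to
convert each scenario's geometry into production, displaced crops, land,
fertiliser-N, GHG and carbon-opportunity-cost terms.  Savings are
negative, new burdens positive; display rounding follows the published
ledger precision.
"""

import pandas as pd

import eurosoy as es

pd.set_option("display.width", 200)

table = es.load_table1_fixture()
coeffs = es.ScenarioCoefficients()

elig_rf = es.eligible_clusters(table, "rainfed", coeffs=coeffs)
elig_pot = es.eligible_clusters(table, "potential", coeffs=coeffs)
print("clusters eligible at >= 3 t/ha rainfed:  ", sorted(elig_rf["cluster"]))
print("clusters eligible at >= 3 t/ha potential:", sorted(elig_pot["cluster"]))

area, prod, wheat = es.scenario_wheat_replacement(table, coeffs, "rainfed")
print(f"\nwheat replacement at current yields: {area:.1f} Mha soy, "
      f"{prod:.1f} Mt soy, {wheat:.0f} Mt wheat displaced")

ledger = es.run_scenarios(table, coeffs)
print("\n", es.format_ledger(ledger).to_string(index=False))
# Sc-1/2: set-aside planting; Sc-3/4: 10% wheat replacement; Sc-5/6: the
# same with half the soy displacing chicken/pork/milk.  Units: Mt/yr for
# masses, Mha for land, Mt CO2e/yr for GHG and carbon opportunity cost.
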