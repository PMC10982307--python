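"""Six environmental-savings scenarios built on a cluster table.

Sc-1/Sc-2: soybean on 50% of a 6.1% set-aside ratio of arable land in
eligible clusters (yield >= 3 t/ha), at the clusters' rainfed ("current")
or potential yields.  Sc-3/Sc-4: 10% of wheat area in eligible clusters
converted to soybean, produced at the European mean yield (3.2 t/ha,
current) or at cluster potential yields; the displaced wheat is costed at
7.1 t/ha.  Sc-5/Sc-6 derive from Sc-3/Sc-4 with half of the soybean
displacing animal protein (chicken, pork, milk in equal thirds; 1:1 on
protein for meat, 7 kg milk per kg soybean), which avoids feed crops,
land, fertiliser-N and production GHG through a configurable inventory
registry.  European soybean replaces Brazilian imports (1.39 kg CO2e per
kg bean; 5 t/ha land intensity), and net spared land earns a carbon
opportunity cost credit of 3.6 t C/ha/yr converted by 44/12.

Sign convention mirrors the study ledger: savings are negative,
new burdens positive.  Full precision is kept internally; rounding
happens only at serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScenarioCoefficients",
    "load_feed_registry",
    "eligible_clusters",
    "scenario_setaside",
    "scenario_wheat_replacement",
    "import_substitution",
    "carbon_opportunity_cost",
    "animal_substitution",
    "assemble_ledger",
    "run_scenarios",
    "format_ledger",
    "SCENARIOS",
]

C_TO_CO2 = 44.0 / 12.0
FEED_CROPS = ("wheat", "barley", "maize", "soybean", "rapeseed", "sunflower")
SCENARIOS = ("Sc-1", "Sc-2", "Sc-3", "Sc-4", "Sc-5", "Sc-6")

LEDGER_COLUMNS = [
    "scenario", "european_soybean_mt", "imported_soybean_mt",
    "displaced_wheat_mt", "barley_feed_mt", "maize_feed_mt",
    "rapeseed_feed_mt", "sunflower_feed_mt", "cropland_area_mha",
    "fertiliser_n_mt", "production_ghg_mt_co2e",
    "carbon_opportunity_cost_mt_co2e",
]


def load_feed_registry() -> dict:
    """Packaged default feed / crop-intensity registry (synthetic
    LCA-style placeholder coefficients; see the YAML header)."""
    path = resources.files("eurosoy.data").joinpath("feed_coefficients.yaml")
    with path.open() as fh:
        return yaml.safe_load(fh)


@dataclass
class ScenarioCoefficients:
    setaside_ratio: float = 0.061       # fraction of arable land set aside
    setaside_use: float = 0.5           # fraction of set-aside planted to soy
    eligibility_yield_t_ha: float = 3.0
    wheat_replacement: float = 0.10     # fraction of wheat area converted
    wheat_yield_t_ha: float = 7.1
    europe_mean_soy_yield_t_ha: float = 3.2
    brazil_soy_yield_t_ha: float = 5.0
    import_ghg_kg_co2e_per_kg: float = 1.39
    sequestration_t_c_ha_yr: float = 3.6
    milk_substitution_kg_per_kg: float = 7.0
    protein_substitution_ratio: float = 1.0
    substitution_fraction: float = 0.5  # share of new soy displacing animal protein
    feed_inventory: dict = field(default_factory=dict)
    crop_land_n_intensity: dict = field(default_factory=dict)
    protein_content: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("setaside_ratio", "setaside_use", "wheat_replacement",
                     "substitution_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("eligibility_yield_t_ha", "wheat_yield_t_ha",
                     "europe_mean_soy_yield_t_ha", "brazil_soy_yield_t_ha",
                     "import_ghg_kg_co2e_per_kg", "sequestration_t_c_ha_yr",
                     "milk_substitution_kg_per_kg", "protein_substitution_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.feed_inventory:
            reg = load_feed_registry()
            self.feed_inventory = reg["feed_inventory"]
            self.crop_land_n_intensity = reg["crop_land_n_intensity"]
            self.protein_content = reg["protein_content"]

    @property
    def coc_t_co2e_ha_yr(self) -> float:
        """Carbon opportunity cost per hectare-year (13.2 at defaults)."""
        return self.sequestration_t_c_ha_yr * C_TO_CO2


def eligible_clusters(
    table: pd.DataFrame,
    yield_column: str,
    threshold: float | None = None,
    coeffs: ScenarioCoefficients | None = None,
) -> pd.DataFrame:
    """Clusters whose chosen yield meets the threshold and whose crop
    success is nonzero.  ``yield_column`` is 'rainfed' or 'potential'."""
    if len(table) == 0:
        raise ValueError("cluster table is empty")
    if yield_column not in ("rainfed", "potential"):
        raise KeyError(f"unknown yield column {yield_column!r}")
    coeffs = coeffs or ScenarioCoefficients()
    thr = coeffs.eligibility_yield_t_ha if threshold is None else threshold
    col = f"yield_{yield_column}_mean"
    return table[(table[col] >= thr) & (table["success_pct"] > 0)]


def scenario_setaside(
    table: pd.DataFrame,
    coeffs: ScenarioCoefficients | None = None,
    yield_column: str = "rainfed",
) -> tuple[float, float]:
    """Set-aside scenario geometry: (area Mha, production Mt).

    Area is setaside_ratio * setaside_use of the arable area summed over
    eligible clusters; production weights the same areas by each
    cluster's own yield (rainfed or potential as selected).
    """
    coeffs = coeffs or ScenarioCoefficients()
    elig = eligible_clusters(table, yield_column, coeffs=coeffs)
    frac = coeffs.setaside_ratio * coeffs.setaside_use
    if len(elig) == 0:
        import warnings
        warnings.warn("no eligible clusters; set-aside scenario is empty")
        return 0.0, 0.0
    area_ha = frac * elig["arable_ha"].sum()
    production_t = frac * (elig["arable_ha"]
                           * elig[f"yield_{yield_column}_mean"]).sum()
    return area_ha / 1e6, production_t / 1e6


def scenario_wheat_replacement(
    table: pd.DataFrame,
    coeffs: ScenarioCoefficients | None = None,
    yield_column: str = "rainfed",
) -> tuple[float, float, float]:
    """Wheat-replacement geometry: (soy area Mha, production Mt, displaced
    wheat Mt).

    10% of the wheat area in eligible clusters goes to soybean.  The
    current-yield variant (eligibility on rainfed yields) produces at the
    European mean soybean yield; the potential variant (eligibility on
    potential yields) produces at each cluster's potential yield.
    Displaced wheat is the converted area times the wheat yield.
    """
    coeffs = coeffs or ScenarioCoefficients()
    if "wheat_frac" not in table.columns or table["wheat_frac"].isna().any():
        raise ValueError("wheat fractions are required for every cluster")
    elig = eligible_clusters(table, yield_column, coeffs=coeffs)
    wheat_area_ha = (elig["wheat_frac"] * elig["arable_ha"])
    area_ha = coeffs.wheat_replacement * wheat_area_ha.sum()
    if yield_column == "rainfed":
        production_t = area_ha * coeffs.europe_mean_soy_yield_t_ha
    else:
        production_t = coeffs.wheat_replacement * (
            wheat_area_ha * elig["yield_potential_mean"]
        ).sum()
    displaced_t = area_ha * coeffs.wheat_yield_t_ha
    return area_ha / 1e6, production_t / 1e6, displaced_t / 1e6


def import_substitution(production_mt: float,
                        coeffs: ScenarioCoefficients | None = None) -> dict:
    """Effects of European soybean replacing Brazilian imports.

    Returns imported_soybean_mt (negative), production_ghg_mt_co2e
    (negative) and brazil_land_spared_mha (positive).
    """
    if production_mt < 0:
        raise ValueError("production must be >= 0")
    coeffs = coeffs or ScenarioCoefficients()
    return {
        "imported_soybean_mt": -production_mt,
        "production_ghg_mt_co2e": -production_mt * coeffs.import_ghg_kg_co2e_per_kg,
        "brazil_land_spared_mha": production_mt / coeffs.brazil_soy_yield_t_ha,
    }


def carbon_opportunity_cost(net_spared_land_mha: float,
                            coeffs: ScenarioCoefficients | None = None) -> float:
    """COC in Mt CO2e: negative (a saving) for spared land, positive for a
    net cropland expansion."""
    coeffs = coeffs or ScenarioCoefficients()
    return -net_spared_land_mha * coeffs.coc_t_co2e_ha_yr


def animal_substitution(soy_for_diet_mt: float,
                        coeffs: ScenarioCoefficients | None = None) -> dict:
    """Avoided animal products, feed crops, land, fertiliser-N and GHG when
    ``soy_for_diet_mt`` of soybean displaces animal protein in equal
    thirds of chicken, pork and milk.

    Chicken and pork substitute 1:1 on protein (via protein contents);
    milk substitutes at a fixed kg-milk-per-kg-soy ratio.  Feed, land, N
    and GHG are taken from the registry; soybean feed is reported
    separately (it follows the import route).
    """
    if soy_for_diet_mt < 0:
        raise ValueError("soy_for_diet must be >= 0")
    coeffs = coeffs or ScenarioCoefficients()
    inv = coeffs.feed_inventory
    intens = coeffs.crop_land_n_intensity
    prot = coeffs.protein_content
    for key in ("chicken", "pork", "milk"):
        if key not in inv:
            raise KeyError(f"feed inventory missing product {key!r}")
    for key in ("soybean", "chicken", "pork"):
        if key not in prot:
            raise KeyError(f"protein_content registry missing {key!r}")

    third = soy_for_diet_mt / 3.0
    r = coeffs.protein_substitution_ratio
    products = {
        "chicken": r * third * prot["soybean"] / prot["chicken"],
        "pork": r * third * prot["soybean"] / prot["pork"],
        "milk": coeffs.milk_substitution_kg_per_kg * third,
    }
    feed = {crop: 0.0 for crop in FEED_CROPS}
    n_mt = 0.0
    ghg_mt = 0.0
    for prod, mass in products.items():
        entry = inv[prod]
        for crop in FEED_CROPS:
            if crop not in entry:
                raise KeyError(f"feed inventory for {prod!r} missing crop {crop!r}")
            feed[crop] += mass * entry[crop]
        n_mt += mass * entry["fertiliser_n"]
        ghg_mt += mass * entry["ghg_co2e"]

    land_mha = 0.0
    for crop, mt in feed.items():
        if crop == "soybean":
            continue
        if crop not in intens:
            raise KeyError(f"crop_land_n_intensity registry missing {crop!r}")
        land_mha += mt * intens[crop]["ha_per_t"]
        n_mt += mt * intens[crop]["n_kg_per_t"] / 1000.0
    return {
        "products_mt": products,
        "feed_mt": feed,
        "spared_land_mha": land_mha,
        "fertiliser_n_mt": n_mt,
        "animal_ghg_mt_co2e": ghg_mt,
    }


def _zero_ledger(scenario: str) -> dict:
    row = {c: 0.0 for c in LEDGER_COLUMNS if c != "scenario"}
    row["scenario"] = scenario
    return row


def assemble_ledger(
    scenario: str,
    soy_area_mha: float,
    production_mt: float,
    displaced_wheat_mt: float = 0.0,
    counts_new_cropland: bool = False,
    diet_shift: bool = False,
    coeffs: ScenarioCoefficients | None = None,
) -> dict:
    """One ledger row from a scenario's geometry.

    ``counts_new_cropland`` is True for the wheat-replacement scenarios,
    where the displaced wheat must be regrown elsewhere (at the wheat
    yield); set-aside scenarios occupy idle arable land instead.  With
    ``diet_shift`` half of the production displaces animal protein and
    the registry-driven avoided feed/land/N/GHG terms apply.
    """
    coeffs = coeffs or ScenarioCoefficients()
    row = _zero_ledger(scenario)
    row["european_soybean_mt"] = production_mt
    row["displaced_wheat_mt"] = displaced_wheat_mt

    if diet_shift:
        soy_to_diet = coeffs.substitution_fraction * production_mt
        soy_to_imports = production_mt - soy_to_diet
        sub = animal_substitution(soy_to_diet, coeffs)
        # feed soybean no longer needed also comes off the import bill
        soy_import_cut = soy_to_imports + sub["feed_mt"]["soybean"]
        row["displaced_wheat_mt"] = displaced_wheat_mt - sub["feed_mt"]["wheat"]
        for crop in ("barley", "maize", "rapeseed", "sunflower"):
            row[f"{crop}_feed_mt"] = -sub["feed_mt"][crop]
        imp = import_substitution(soy_import_cut, coeffs)
        row["imported_soybean_mt"] = imp["imported_soybean_mt"]
        row["fertiliser_n_mt"] = -sub["fertiliser_n_mt"]
        row["production_ghg_mt_co2e"] = (imp["production_ghg_mt_co2e"]
                                         - sub["animal_ghg_mt_co2e"])
        compensatory_wheat_mha = max(0.0, row["displaced_wheat_mt"]) \
            / coeffs.wheat_yield_t_ha
        row["cropland_area_mha"] = (compensatory_wheat_mha
                                    - imp["brazil_land_spared_mha"]
                                    - sub["spared_land_mha"])
    else:
        imp = import_substitution(production_mt, coeffs)
        row["imported_soybean_mt"] = imp["imported_soybean_mt"]
        row["production_ghg_mt_co2e"] = imp["production_ghg_mt_co2e"]
        compensatory_wheat_mha = (displaced_wheat_mt / coeffs.wheat_yield_t_ha
                                  if counts_new_cropland else 0.0)
        row["cropland_area_mha"] = (compensatory_wheat_mha
                                    - imp["brazil_land_spared_mha"])

    row["carbon_opportunity_cost_mt_co2e"] = carbon_opportunity_cost(
        -row["cropland_area_mha"], coeffs
    )
    return row


def run_scenarios(table: pd.DataFrame,
                  coeffs: ScenarioCoefficients | None = None) -> pd.DataFrame:
    """All six ledger rows from a cluster table."""
    coeffs = coeffs or ScenarioCoefficients()
    rows = []

    for scenario, column in (("Sc-1", "rainfed"), ("Sc-2", "potential")):
        area, prod = scenario_setaside(table, coeffs, column)
        rows.append(assemble_ledger(scenario, area, prod, coeffs=coeffs))

    geometry = {}
    for scenario, column in (("Sc-3", "rainfed"), ("Sc-4", "potential")):
        area, prod, wheat = scenario_wheat_replacement(table, coeffs, column)
        geometry[column] = (area, prod, wheat)
        rows.append(assemble_ledger(scenario, area, prod, wheat,
                                    counts_new_cropland=True, coeffs=coeffs))

    for scenario, column in (("Sc-5", "rainfed"), ("Sc-6", "potential")):
        area, prod, wheat = geometry[column]
        rows.append(assemble_ledger(scenario, area, prod, wheat,
                                    counts_new_cropland=True, diet_shift=True,
                                    coeffs=coeffs))
    return pd.DataFrame(rows)[LEDGER_COLUMNS]


def format_ledger(ledger: pd.DataFrame) -> pd.DataFrame:
    """Display rounding only: integer Mt / Mt CO2e, one decimal Mha."""
    out = ledger.copy()
    for col in out.columns:
        if col == "scenario":
            continue
        if col.endswith("_mha"):
            out[col] = out[col].round(1)
        else:
            out[col] = out[col].round(0)
    return out


def coefficient_provenance(coeffs: ScenarioCoefficients) -> dict:
    """Serializable record of every coefficient used in a scenario run."""
    return asdict(coeffs)
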