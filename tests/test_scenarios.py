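import numpy as np
import pandas as pd
import pytest

import eurosoy as es
from eurosoy.scenarios import (LEDGER_COLUMNS, ScenarioCoefficients,
                               load_feed_registry)


class TestEligibleClusters:
    def test_rainfed_eligibility(self, table1, coeffs):
        got = set(es.eligible_clusters(table1, "rainfed", coeffs=coeffs)["cluster"])
        assert got == {"E", "F", "G", "I"}

    def test_potential_eligibility(self, table1, coeffs):
        got = set(es.eligible_clusters(table1, "potential", coeffs=coeffs)["cluster"])
        assert got == {"D", "E", "F", "G", "H", "I", "J", "K"}

    def test_unreachable_threshold_empty(self, table1):
        assert len(es.eligible_clusters(table1, "rainfed", threshold=100.0)) == 0
        assert len(es.eligible_clusters(table1, "potential", threshold=100.0)) == 0

    def test_unknown_column_rejected(self, table1):
        with pytest.raises(KeyError):
            es.eligible_clusters(table1, "irrigated")

    def test_raising_threshold_never_grows_area(self, table1, coeffs):
        prev_area = np.inf
        for thr in (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0):
            elig = es.eligible_clusters(table1, "rainfed", threshold=thr)
            area = elig["arable_ha"].sum()
            assert area <= prev_area
            prev_area = area


class TestSetAside:
    def test_rainfed_geometry_from_fixture(self, table1, coeffs):
        area, prod = es.scenario_setaside(table1, coeffs, "rainfed")
        assert area == pytest.approx(3.65, abs=0.01)
        assert prod == pytest.approx(12.73, abs=0.01)

    def test_zero_use_is_zero(self, table1):
        co = ScenarioCoefficients(setaside_use=0.0)
        area, prod = es.scenario_setaside(table1, co, "rainfed")
        assert area == 0.0 and prod == 0.0

    def test_single_cluster_hand_arithmetic(self, coeffs):
        tab = pd.DataFrame({
            "cluster": ["Z"], "arable_ha": [10e6], "wheat_frac": [0.3],
            "yield_rainfed_mean": [4.0], "yield_potential_mean": [5.0],
            "success_pct": [90.0],
        })
        area, prod = es.scenario_setaside(tab, coeffs, "rainfed")
        assert area == pytest.approx(0.305)
        assert prod == pytest.approx(1.22)


class TestWheatReplacement:
    def test_current_yield_geometry(self, table1, coeffs):
        area, prod, wheat = es.scenario_wheat_replacement(table1, coeffs, "rainfed")
        assert area == pytest.approx(3.602, abs=0.001)
        assert prod == pytest.approx(area * 3.2)
        assert wheat == pytest.approx(area * 7.1)

    def test_potential_yield_geometry(self, table1, coeffs):
        area, prod, wheat = es.scenario_wheat_replacement(table1, coeffs,
                                                          "potential")
        assert area == pytest.approx(4.811, abs=0.001)
        assert wheat == pytest.approx(area * 7.1)
        assert prod > area * 3.2  # potential yields exceed the current mean

    def test_missing_wheat_fraction_rejected(self, table1, coeffs):
        broken = table1.drop(columns=["wheat_frac"])
        with pytest.raises(ValueError, match="wheat"):
            es.scenario_wheat_replacement(broken, coeffs, "rainfed")


class TestImportSubstitution:
    def test_zero_production(self, coeffs):
        out = es.import_substitution(0.0, coeffs)
        assert all(v == 0.0 for v in out.values())

    def test_ghg_is_exactly_intensity_times_production(self, coeffs):
        out = es.import_substitution(11.5, coeffs)
        assert out["production_ghg_mt_co2e"] == pytest.approx(-11.5 * 1.39)
        assert out["imported_soybean_mt"] == -11.5

    def test_brazil_land_spared(self, coeffs):
        out = es.import_substitution(9.0, coeffs)
        assert out["brazil_land_spared_mha"] == pytest.approx(1.8)


class TestCarbonOpportunityCost:
    @pytest.mark.parametrize("spared,expected", [
        (1.8, -23.76), (6.5, -85.8), (15.0, -198.0), (0.0, 0.0),
    ])
    def test_sequestration_conversion(self, spared, expected, coeffs):
        assert es.carbon_opportunity_cost(spared, coeffs) == pytest.approx(expected)

    def test_sign_flips_for_expansion(self, coeffs):
        assert es.carbon_opportunity_cost(-1.0, coeffs) == pytest.approx(13.2)


class TestAnimalSubstitution:
    def test_zero_soy_all_zero(self, coeffs):
        out = es.animal_substitution(0.0, coeffs)
        assert all(v == 0.0 for v in out["products_mt"].values())
        assert all(v == 0.0 for v in out["feed_mt"].values())

    def test_milk_displacement_ratio(self, coeffs):
        out = es.animal_substitution(1.0, coeffs)
        assert out["products_mt"]["milk"] == pytest.approx(7.0 / 3.0)

    def test_protein_rule_for_chicken(self):
        co = ScenarioCoefficients()
        third = 1.0 / 3.0
        out = es.animal_substitution(1.0, co)
        expect = third * co.protein_content["soybean"] / co.protein_content["chicken"]
        assert out["products_mt"]["chicken"] == pytest.approx(expect)

    def test_missing_registry_entry_named(self, coeffs):
        co = ScenarioCoefficients()
        co.protein_content = {"soybean": 36.0, "chicken": 20.0}  # pork missing
        with pytest.raises(KeyError, match="pork"):
            es.animal_substitution(1.0, co)

    def test_registry_loads_and_is_complete(self):
        reg = load_feed_registry()
        for prod in ("chicken", "pork", "milk"):
            entry = reg["feed_inventory"][prod]
            for crop in ("wheat", "barley", "maize", "soybean", "rapeseed",
                         "sunflower"):
                assert entry[crop] >= 0
            assert entry["fertiliser_n"] >= 0 and entry["ghg_co2e"] > 0


@pytest.fixture(scope="module")
def ledger(table1, coeffs):
    return es.run_scenarios(table1, coeffs).set_index("scenario")


class TestLedger:
    def test_six_rows_all_columns(self, ledger):
        assert list(ledger.index) == ["Sc-1", "Sc-2", "Sc-3", "Sc-4", "Sc-5",
                                      "Sc-6"]
        assert set(ledger.columns) == set(LEDGER_COLUMNS) - {"scenario"}

    def test_sign_conventions(self, ledger):
        assert (ledger["european_soybean_mt"] > 0).all()
        assert (ledger["imported_soybean_mt"] < 0).all()
        assert (ledger["production_ghg_mt_co2e"] < 0).all()

    def test_wheat_mass_consistency(self, ledger, coeffs, table1):
        area, _, wheat = es.scenario_wheat_replacement(table1, coeffs, "rainfed")
        assert ledger.loc["Sc-3", "displaced_wheat_mt"] == pytest.approx(
            area * coeffs.wheat_yield_t_ha)

    def test_import_ghg_consistency(self, ledger, coeffs):
        for sc in ("Sc-1", "Sc-2", "Sc-3", "Sc-4"):
            assert ledger.loc[sc, "production_ghg_mt_co2e"] == pytest.approx(
                ledger.loc[sc, "imported_soybean_mt"]
                * coeffs.import_ghg_kg_co2e_per_kg)

    def test_diet_scenarios_nest_in_wheat_scenarios(self, ledger):
        """Sc-5/Sc-6 grow the same soybean as Sc-3/Sc-4; only the
        disposition of half the production changes."""
        assert ledger.loc["Sc-5", "european_soybean_mt"] == pytest.approx(
            ledger.loc["Sc-3", "european_soybean_mt"])
        assert ledger.loc["Sc-6", "european_soybean_mt"] == pytest.approx(
            ledger.loc["Sc-4", "european_soybean_mt"])
        # diet shift only increases the import saving and reduces wheat burden
        assert ledger.loc["Sc-5", "displaced_wheat_mt"] \
            <= ledger.loc["Sc-3", "displaced_wheat_mt"]
        assert ledger.loc["Sc-5", "fertiliser_n_mt"] < 0
        assert ledger.loc["Sc-6", "fertiliser_n_mt"] < 0

    def test_coc_follows_net_cropland(self, ledger, coeffs):
        for sc in ledger.index:
            assert ledger.loc[sc, "carbon_opportunity_cost_mt_co2e"] == \
                pytest.approx(ledger.loc[sc, "cropland_area_mha"]
                              * coeffs.coc_t_co2e_ha_yr)

    def test_format_rounds_for_display_only(self, ledger, table1, coeffs):
        raw = es.run_scenarios(table1, coeffs)
        shown = es.format_ledger(raw)
        assert shown["cropland_area_mha"].equals(
            raw["cropland_area_mha"].round(1))
        assert shown["european_soybean_mt"].equals(
            raw["european_soybean_mt"].round(0))


class TestCoefficientValidation:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            ScenarioCoefficients(setaside_ratio=1.5)

    def test_positive_yields(self):
        with pytest.raises(ValueError):
            ScenarioCoefficients(wheat_yield_t_ha=0.0)

    def test_coc_rate_at_defaults(self, coeffs):
        assert coeffs.coc_t_co2e_ha_yr == pytest.approx(13.2)
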