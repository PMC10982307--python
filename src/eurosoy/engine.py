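"""Factorial orchestration: site x year x maturity group x configuration.

For every site-year the adaptive planting rule runs once (it is shared
across maturity groups); phenology is predicted per maturity group; the
failure rules are applied; and each surviving season is grown under the
four water configurations (one potential, three rainfed initial-moisture
members).  Failed seasons carry a yield of exactly 0; successful yields
are capped at a maximum plausible attainable value (7 t/ha by default).

All stochasticity lives in the synthetic generators: given identical
inputs the factorial run is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import GrowthConfig, SimConfiguration, simulate_season
from .phenology import (MATURITY_GROUPS, PhenologyConfig, StageDates,
                        decide_planting, predict_stages)
from .synthetic import MoistureInit, SoilProfile

__all__ = [
    "FailureRules",
    "DEFAULT_CONFIGURATIONS",
    "apply_failure_rules",
    "cap_yield",
    "design_size",
    "run_factorial",
]


@dataclass(frozen=True)
class FailureRules:
    frost_threshold_c: float = 0.0   # daily mean temp below this kills the season
    max_cycle_days: int = 170        # planting -> R7 longer than this fails
    cap_yield_t_ha: float = 7.0      # maximum plausible attainable yield

    def __post_init__(self):
        if self.max_cycle_days <= 0:
            raise ValueError("max_cycle_days must be > 0")
        if self.cap_yield_t_ha <= 0:
            raise ValueError("cap_yield_t_ha must be > 0")


#: the study's four water configurations
DEFAULT_CONFIGURATIONS = (
    SimConfiguration("potential", 0),
    SimConfiguration("rainfed", -1),
    SimConfiguration("rainfed", 0),
    SimConfiguration("rainfed", 1),
)


def apply_failure_rules(
    series: pd.DataFrame,
    stages: StageDates | None,
    rules: FailureRules | None = None,
) -> str:
    """Classify one site-season: 'no_planting', 'frost', 'overlong' or 'none'.

    no_planting takes precedence.  A season that plants but never reaches
    R7 within the series is classed overlong (with planting bounded by
    mid-year, the remaining window already exceeds the cycle limit).
    Frost is any day between emergence and R7 (inclusive) with daily mean
    temperature, (tmin+tmax)/2, below the threshold; overlong is a
    planting-to-R7 duration strictly greater than ``max_cycle_days``.
    """
    rules = rules or FailureRules()
    if stages is None or stages.planting is None:
        return "no_planting"
    if not stages.reached_r7:
        return "overlong"
    doy = pd.DatetimeIndex(series["date"]).dayofyear.to_numpy()
    tmean = (series["tmin_c"].to_numpy() + series["tmax_c"].to_numpy()) / 2.0
    window = (doy >= stages.emergence) & (doy <= stages.r7)
    if np.any(tmean[window] < rules.frost_threshold_c):
        return "frost"
    if stages.r7 - stages.planting > rules.max_cycle_days:
        return "overlong"
    return "none"


def cap_yield(raw_t_ha: float, rules: FailureRules | None = None) -> float:
    rules = rules or FailureRules()
    if raw_t_ha < 0:
        raise ValueError("yield must be >= 0")
    return min(raw_t_ha, rules.cap_yield_t_ha)


def design_size(n_sites: int, n_years: int, n_mgs: int = 7, n_configs: int = 4) -> int:
    """Total simulations in the full factorial design."""
    return n_sites * n_years * n_mgs * n_configs


def _year_slices(series: pd.DataFrame):
    years = np.asarray(pd.DatetimeIndex(series["date"]).year)
    for y in np.unique(years):
        yield int(y), series.loc[years == y].reset_index(drop=True)


def run_factorial(
    grid: pd.DataFrame,
    weather: dict,
    soils: dict,
    mgs: tuple = MATURITY_GROUPS,
    configurations: tuple = DEFAULT_CONFIGURATIONS,
    rules: FailureRules | None = None,
    phen_cfg: PhenologyConfig | None = None,
    growth_cfg: GrowthConfig | None = None,
) -> pd.DataFrame:
    """Run the full factorial and return one long-format row per simulation.

    ``weather`` maps site_id to a multi-year daily DataFrame; ``soils``
    maps site_id to a (SoilProfile, MoistureInit) pair.  The result has
    exactly n_sites * n_years * len(mgs) * len(configurations) rows.
    """
    rules = rules or FailureRules()
    phen_cfg = phen_cfg or PhenologyConfig()
    growth_cfg = growth_cfg or GrowthConfig()

    missing = [s for s in grid["site_id"] if s not in weather or s not in soils]
    if missing:
        raise KeyError(f"sites without weather or soil data: {missing}")

    rows = []
    for site_id, lat in zip(grid["site_id"], grid["lat"]):
        soil, init = soils[site_id]
        for year, season in _year_slices(weather[site_id]):
            season.attrs["lat"] = float(lat)
            planting = decide_planting(season, phen_cfg)
            for mg in mgs:
                if planting is None:
                    stages, reason = None, "no_planting"
                else:
                    stages = predict_stages(season, planting, mg, phen_cfg, lat=lat)
                    reason = apply_failure_rules(season, stages, rules)
                for sim in configurations:
                    if reason == "none":
                        raw, _ = simulate_season(season, stages, soil, init,
                                                 sim, growth_cfg)
                        y = cap_yield(raw, rules)
                    else:
                        y = 0.0
                    rows.append({
                        "site_id": site_id,
                        "year": year,
                        "maturity_group": mg,
                        "config": sim.label,
                        "planting_doy": None if stages is None else stages.planting,
                        "emergence_doy": None if stages is None else stages.emergence,
                        "r1_doy": None if stages is None else stages.r1,
                        "r5_doy": None if stages is None else stages.r5,
                        "r7_doy": None if stages is None else stages.r7,
                        "yield_t_ha": y,
                        "failed": reason != "none",
                        "failure_reason": reason,
                    })
    return pd.DataFrame(rows)
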