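"""Expolinear canopy growth, radiation-use-efficiency biomass accumulation
and a single-bucket root-zone water balance.

The canopy expands along an expolinear leaf-area-index curve; intercepted
radiation is converted to biomass at a fixed radiation-use efficiency
(RUE); a fraction of daily biomass is partitioned to grain between R5 and
R7.  In rainfed mode evapotranspiration demand follows Priestley-Taylor
scaled by fractional interception, actual ET is demand times a linear
soil-water stress factor, and the same stress factor multiplies daily
growth.  Potential mode sets stress to 1 everywhere, so it depends only
on temperature (through phenology) and radiation.

Yields are reported at 13% grain moisture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phenology import StageDates
from .synthetic import MoistureInit, SoilProfile

__all__ = [
    "GrowthConfig",
    "WaterState",
    "SimConfiguration",
    "RAINFED_OFFSETS",
    "expolinear_lai",
    "priestley_taylor_et",
    "water_balance_step",
    "initial_paw",
    "simulate_season",
]

GRAIN_MOISTURE = 0.13  # reporting basis: fraction water in grain
_LAMBDA = 2.45         # MJ kg-1, latent heat of vaporisation
_GAMMA = 0.066         # kPa K-1, psychrometric constant


@dataclass(frozen=True)
class GrowthConfig:
    rue: float = 0.85               # g biomass per MJ intercepted solar
    k_ext: float = 0.65             # canopy extinction coefficient
    lai_c: float = 0.12             # expolinear linear-phase rate, LAI d-1
    lai_r: float = 0.15             # expolinear exponential-phase rate, d-1
    lai_t_offset: float = 18.0      # inflection offset t_b, days after emergence
    lai_max: float = 6.0
    seed_fill_fraction: float = 0.55  # partitioning to grain between R5 and R7
    et_alpha: float = 1.26          # Priestley-Taylor coefficient
    net_radiation_fraction: float = 0.5  # Rn as a fraction of incoming solar
    stress_half_point: float = 0.5  # fraction of capacity where stress = 0.5

    def __post_init__(self):
        for name in ("rue", "k_ext", "lai_c", "lai_r", "lai_max",
                     "et_alpha", "net_radiation_fraction", "stress_half_point"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.lai_max > 10:
            raise ValueError("lai_max must be <= 10")
        if not 0 < self.seed_fill_fraction <= 1:
            raise ValueError("seed_fill_fraction must lie in (0, 1]")


@dataclass
class WaterState:
    paw_mm: float
    runoff_cum_mm: float = 0.0
    et_cum_mm: float = 0.0
    precip_cum_mm: float = 0.0

    def __post_init__(self):
        if self.paw_mm < 0:
            raise ValueError("paw_mm must be >= 0")


@dataclass(frozen=True)
class SimConfiguration:
    """potential mode (no water limitation) or rainfed with an initial
    soil-moisture offset of -1/0/+1 ensemble standard deviations."""

    mode: str = "rainfed"
    init_offset: int = 0

    def __post_init__(self):
        if self.mode not in ("potential", "rainfed"):
            raise ValueError("mode must be 'potential' or 'rainfed'")
        if self.mode == "rainfed" and self.init_offset not in (-1, 0, 1):
            raise ValueError("init_offset must be -1, 0 or +1")

    @property
    def label(self) -> str:
        if self.mode == "potential":
            return "potential"
        return {-1: "rainfed_lo", 0: "rainfed_mid", 1: "rainfed_hi"}[self.init_offset]


RAINFED_OFFSETS = (-1, 0, 1)


def expolinear_lai(days_since_emergence: float, cfg: GrowthConfig) -> float:
    """Expolinear LAI: (c/r) * ln(1 + exp(r*(t - t_b))), capped at lai_max.

    Exponential expansion early, approaching a linear phase of slope
    ``lai_c``; non-decreasing in t.
    """
    t = np.asarray(days_since_emergence, float)
    if np.any(t < 0):
        raise ValueError("days_since_emergence must be >= 0")
    z = cfg.lai_r * (t - cfg.lai_t_offset)
    lai = (cfg.lai_c / cfg.lai_r) * np.logaddexp(0.0, z)
    return np.minimum(lai, cfg.lai_max)


def priestley_taylor_et(srad_mj_m2: float, tmean_c: float, cfg: GrowthConfig) -> float:
    """Priestley-Taylor evaporative demand (mm d-1) from solar radiation
    and mean air temperature."""
    es = 0.6108 * np.exp(17.27 * tmean_c / (tmean_c + 237.3))
    delta = 4098.0 * es / (tmean_c + 237.3) ** 2
    rn = cfg.net_radiation_fraction * srad_mj_m2
    return np.maximum(0.0, cfg.et_alpha * delta / (delta + _GAMMA) * rn / _LAMBDA)


def water_balance_step(
    state: WaterState,
    precip_mm: float,
    et_demand_mm: float,
    soil: SoilProfile,
    cfg: GrowthConfig,
) -> tuple[WaterState, float]:
    """One daily bucket update; returns (new state, stress factor).

    stress is evaluated on the pre-update store:
    min(1, paw / (2 * stress_half_point * capacity)); actual ET is demand
    times stress (never more than the water present); inflow above
    capacity runs off.  Water is conserved exactly:
    paw' - paw = precip - runoff - et_actual.
    """
    if precip_mm < 0 or et_demand_mm < 0:
        raise ValueError("precip and ET demand must be >= 0")
    cap = soil.paw_capacity_mm
    stress = min(1.0, state.paw_mm / (2.0 * cfg.stress_half_point * cap))
    et_actual = min(et_demand_mm * stress, state.paw_mm + precip_mm)
    stored = state.paw_mm + precip_mm - et_actual
    runoff = max(0.0, stored - cap)
    new = WaterState(
        paw_mm=stored - runoff,
        runoff_cum_mm=state.runoff_cum_mm + runoff,
        et_cum_mm=state.et_cum_mm + et_actual,
        precip_cum_mm=state.precip_cum_mm + precip_mm,
    )
    return new, stress


def initial_paw(soil: SoilProfile, init: MoistureInit, offset: int) -> float:
    """Initial plant-available water (mm) from root-zone soil moisture at
    mean + offset * ensemble sd, above the wilting point, clamped to the
    bucket capacity."""
    sm = init.sm_mean + offset * init.sm_ensemble_sd
    paw = (sm - soil.wilting_point) * soil.rootzone_depth_m * 1000.0
    return float(np.clip(paw, 0.0, soil.paw_capacity_mm))


def simulate_season(
    series: pd.DataFrame,
    stages: StageDates,
    soil: SoilProfile,
    init: MoistureInit,
    simcfg: SimConfiguration,
    cfg: GrowthConfig | None = None,
) -> tuple[float, WaterState]:
    """Run the daily growth loop from emergence to R7 for one season.

    Returns (grain yield in t/ha at 13% moisture, final water state).
    Requires a completed phenology (stages.reached_r7); failed seasons are
    handled upstream by the simulation engine.
    """
    cfg = cfg or GrowthConfig()
    if not stages.reached_r7:
        raise ValueError("simulate_season requires a season that reached R7")

    doy = pd.DatetimeIndex(series["date"]).dayofyear.to_numpy()
    e = int(np.flatnonzero(doy == stages.emergence)[0])
    r5 = int(np.flatnonzero(doy == stages.r5)[0])
    r7 = int(np.flatnonzero(doy == stages.r7)[0])

    srad = series["srad_mj_m2"].to_numpy()
    precip = series["precip_mm"].to_numpy()
    tmean = (series["tmin_c"].to_numpy() + series["tmax_c"].to_numpy()) / 2.0

    rainfed = simcfg.mode == "rainfed"
    state = WaterState(paw_mm=initial_paw(soil, init, simcfg.init_offset)
                       if rainfed else 0.0)

    grain = 0.0  # g dry matter m-2
    for i in range(e + 1, r7 + 1):
        lai = float(expolinear_lai(i - e, cfg))
        fint = 1.0 - np.exp(-cfg.k_ext * lai)
        if rainfed:
            demand = float(priestley_taylor_et(srad[i], tmean[i], cfg)) * fint
            state, stress = water_balance_step(state, float(precip[i]), demand,
                                               soil, cfg)
        else:
            stress = 1.0
        growth = cfg.rue * srad[i] * fint * stress
        if i > r5:
            grain += cfg.seed_fill_fraction * growth

    yield_t_ha = grain * 0.01 / (1.0 - GRAIN_MOISTURE)
    return yield_t_ha, state
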