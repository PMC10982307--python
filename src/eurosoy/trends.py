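"""National yield-trend regression, yield gaps, trade seed-equivalents and
model-validation metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TradeRatios",
    "TrendFit",
    "ValidationMetrics",
    "fit_yield_trend",
    "yield_gap",
    "seed_equivalents",
    "validation_metrics",
]


@dataclass(frozen=True)
class TradeRatios:
    """Extraction ratios converting traded oil/cake mass back to whole-bean
    ("seed equivalent") mass."""

    oil_to_seed: float = 0.178
    cake_to_seed: float = 0.792

    def __post_init__(self):
        if not (0 < self.oil_to_seed < 1 and 0 < self.cake_to_seed < 1):
            raise ValueError("extraction ratios must lie in (0, 1)")


@dataclass(frozen=True)
class TrendFit:
    slope_t_ha_yr: float
    intercept_t_ha: float
    pct_per_year: float
    p_value: float
    r_value: float


@dataclass(frozen=True)
class ValidationMetrics:
    pearson_r: float   # NaN when either vector is constant
    mbe: float         # mean(simulated - observed); negative = underestimation
    mape_pct: float


def fit_yield_trend(series: pd.DataFrame, pct_base: str = "first_year") -> TrendFit:
    """Ordinary least squares of yield on year.

    ``pct_per_year`` expresses the slope as a percentage of the fitted
    value at the series' first year (or of the series mean with
    ``pct_base='mean'``).
    """
    if len(series) < 3:
        raise ValueError("need at least 3 years to fit a trend")
    if pct_base not in ("first_year", "mean"):
        raise ValueError("pct_base must be 'first_year' or 'mean'")
    years = series["year"].to_numpy(float)
    y = series["yield_t_ha"].to_numpy(float)
    res = stats.linregress(years, y)
    base = (res.intercept + res.slope * years.min() if pct_base == "first_year"
            else y.mean())
    pct = 100.0 * res.slope / base if base != 0 else np.nan
    return TrendFit(
        slope_t_ha_yr=float(res.slope),
        intercept_t_ha=float(res.intercept),
        pct_per_year=float(pct),
        p_value=float(res.pvalue),
        r_value=float(res.rvalue),
    )


def yield_gap(water_limited_t_ha: float, observed_t_ha: float) -> float:
    """Percent yield gap: 100 * (water-limited - observed) / water-limited.

    Negative (observed above the simulated ceiling) is returned as-is; the
    caller decides how to annotate out-of-range gaps.
    """
    if water_limited_t_ha <= 0:
        raise ValueError("water-limited yield must be > 0")
    if observed_t_ha < 0:
        raise ValueError("observed yield must be >= 0")
    return 100.0 * (water_limited_t_ha - observed_t_ha) / water_limited_t_ha


def seed_equivalents(seed_mt: float, oil_mt: float, cake_mt: float,
                     ratios: TradeRatios | None = None) -> float:
    """Whole-bean mass equivalent of traded seed + oil + cake."""
    ratios = ratios or TradeRatios()
    if seed_mt < 0 or oil_mt < 0 or cake_mt < 0:
        raise ValueError("trade masses must be >= 0")
    return seed_mt + oil_mt / ratios.oil_to_seed + cake_mt / ratios.cake_to_seed


def validation_metrics(simulated, observed) -> ValidationMetrics:
    """Pearson r, mean bias error and mean absolute percentage error of
    simulated vs observed yields."""
    sim = np.asarray(simulated, float)
    obs = np.asarray(observed, float)
    if sim.shape != obs.shape or sim.size < 2:
        raise ValueError("need equal-length vectors of size >= 2")
    if np.any(obs <= 0):
        raise ValueError("observed values must be > 0 for MAPE")
    if np.ptp(sim) == 0 or np.ptp(obs) == 0:
        r = float("nan")  # correlation undefined for a constant vector
    else:
        r = float(stats.pearsonr(sim, obs).statistic)
    return ValidationMetrics(
        pearson_r=r,
        mbe=float(np.mean(sim - obs)),
        mape_pct=float(100.0 * np.mean(np.abs(sim - obs) / obs)),
    )
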