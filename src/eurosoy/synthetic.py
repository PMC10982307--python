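"""Seeded synthetic generators for weather, soils, site grids and yield series.

Every downstream stage of the pipeline (phenology, growth, clustering,
trend analysis) is exercised on data from this module, so the generators
are first-class, deterministic functions of their arguments including the
seed.  The weather model is deliberately simple: a monthly climatology
interpolated with a single annual harmonic, AR(1) daily temperature
anomalies shared between tmin and tmax, Bernoulli-gamma precipitation and
a sinusoidal clear-sky radiation cycle damped on wet days.  It reproduces
the seasonality and dry-spell structure the crop model responds to, not
reanalysis-grade weather.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClimateArchetype",
    "SoilProfile",
    "MoistureInit",
    "DEFAULT_ARCHETYPES",
    "default_archetypes",
    "gen_weather",
    "gen_soil",
    "gen_site_grid",
    "gen_yield_series",
    "haversine_km",
    "DEFAULT_BBOX",
]

#: study bounding box (lat_min, lat_max, lon_min, lon_max) in decimal degrees
DEFAULT_BBOX = (35.8, 61.2, -10.5, 48.9)

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (mean Earth radius 6371 km). Vectorised."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class ClimateArchetype:
    """Monthly climatology parameters for one climate type.

    Temperatures in degC, precipitation in mm per calendar month, radiation
    peak in MJ m-2 d-1.  ``interannual_sd`` is the standard deviation of a
    whole-year temperature offset.
    """

    name: str
    monthly_tmin_mean: tuple
    monthly_tmax_mean: tuple
    monthly_precip_mean: tuple
    precip_wet_day_prob: float
    srad_annual_peak: float
    interannual_sd: float

    def __post_init__(self):
        tmin = np.asarray(self.monthly_tmin_mean, float)
        tmax = np.asarray(self.monthly_tmax_mean, float)
        pr = np.asarray(self.monthly_precip_mean, float)
        if tmin.shape != (12,) or tmax.shape != (12,) or pr.shape != (12,):
            raise ValueError("monthly parameters must have 12 entries")
        if not np.all(tmax > tmin):
            raise ValueError(f"{self.name}: tmax_mean must exceed tmin_mean every month")
        if np.any(pr < 0):
            raise ValueError(f"{self.name}: monthly precipitation must be >= 0")
        if not 0.0 <= self.precip_wet_day_prob <= 1.0:
            raise ValueError(f"{self.name}: wet-day probability must lie in [0, 1]")
        if self.srad_annual_peak <= 0 or self.interannual_sd < 0:
            raise ValueError(f"{self.name}: radiation peak must be > 0 and sd >= 0")


@dataclass(frozen=True)
class SoilProfile:
    """Root-zone water properties: plant-available capacity and texture bounds."""

    paw_capacity_mm: float
    wilting_point: float
    porosity: float
    rootzone_depth_m: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.wilting_point < self.porosity < 1.0:
            raise ValueError("require 0 < wilting_point < porosity < 1")
        if self.paw_capacity_mm <= 0:
            raise ValueError("paw_capacity_mm must be > 0")
        if self.rootzone_depth_m <= 0:
            raise ValueError("rootzone_depth_m must be > 0")


@dataclass(frozen=True)
class MoistureInit:
    """Satellite-style root-zone soil moisture mean and ensemble spread."""

    sm_mean: float
    sm_ensemble_sd: float

    def __post_init__(self):
        if self.sm_ensemble_sd < 0:
            raise ValueError("sm_ensemble_sd must be >= 0")
        if self.sm_mean < 0:
            raise ValueError("sm_mean must be >= 0")


def _sine12(lo, hi, peak_month=7):
    """12 monthly values on a sinusoid between lo and hi peaking at peak_month."""
    m = np.arange(1, 13)
    mid = (lo + hi) / 2.0
    amp = (hi - lo) / 2.0
    return tuple(np.round(mid + amp * np.cos(2 * np.pi * (m - peak_month) / 12.0), 1))


def default_archetypes() -> dict:
    """The four packaged climate archetypes.

    Named after the qualitative climates of the study's cluster exemplars
    (maritime ~ A/C, continental ~ F, mediterranean ~ I, sub-arctic ~ L);
    the parameters are synthetic, chosen so the simulator reproduces the
    qualitative success pattern (sub-arctic cannot complete a cycle), and
    are not calibrated to any observational record.
    """
    return {
        "maritime": ClimateArchetype(
            name="maritime",
            monthly_tmin_mean=_sine12(3.0, 13.0),
            monthly_tmax_mean=_sine12(8.0, 22.0),
            monthly_precip_mean=(65, 50, 55, 50, 55, 55, 50, 60, 60, 70, 75, 70),
            precip_wet_day_prob=0.45,
            srad_annual_peak=18.0,
            interannual_sd=0.8,
        ),
        "continental": ClimateArchetype(
            name="continental",
            monthly_tmin_mean=_sine12(-8.0, 16.0),
            monthly_tmax_mean=_sine12(0.0, 28.0),
            monthly_precip_mean=(35, 30, 35, 45, 60, 70, 70, 60, 45, 40, 40, 40),
            precip_wet_day_prob=0.35,
            srad_annual_peak=22.0,
            interannual_sd=1.0,
        ),
        "mediterranean": ClimateArchetype(
            name="mediterranean",
            monthly_tmin_mean=_sine12(4.0, 19.0),
            monthly_tmax_mean=_sine12(12.0, 32.0),
            monthly_precip_mean=(60, 50, 45, 45, 35, 20, 10, 15, 35, 60, 70, 65),
            precip_wet_day_prob=0.30,
            srad_annual_peak=26.0,
            interannual_sd=0.8,
        ),
        "subarctic": ClimateArchetype(
            name="subarctic",
            monthly_tmin_mean=_sine12(-14.0, 7.0),
            monthly_tmax_mean=_sine12(-6.0, 14.0),
            monthly_precip_mean=(30, 25, 30, 30, 40, 50, 60, 55, 50, 45, 40, 35),
            precip_wet_day_prob=0.40,
            srad_annual_peak=16.0,
            interannual_sd=1.2,
        ),
    }


DEFAULT_ARCHETYPES = default_archetypes()

_MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], float)


def _annual_harmonic(monthly, frac_of_year):
    """Mean + first Fourier harmonic through 12 monthly values.

    ``frac_of_year`` is the fraction of the year elapsed at each day
    (0..1); monthly values are anchored at month midpoints.
    """
    m = np.asarray(monthly, float)
    phase = 2 * np.pi * (np.arange(12) + 0.5) / 12.0
    a0 = m.mean()
    a1 = 2.0 * np.mean(m * np.cos(phase))
    b1 = 2.0 * np.mean(m * np.sin(phase))
    t = 2 * np.pi * frac_of_year
    return a0 + a1 * np.cos(t) + b1 * np.sin(t)


def gen_weather(
    archetype: ClimateArchetype,
    n_years: int,
    seed: int,
    start_year: int = 2000,
    lat: float = 48.0,
    site_id: int | str | None = None,
) -> pd.DataFrame:
    """Generate a daily weather series for ``n_years`` calendar years.

    Returns a DataFrame with columns date, tmin_c, tmax_c, precip_mm,
    srad_mj_m2; the site latitude and id are stored in ``df.attrs``.
    Guarantees tmax > tmin every day with a diurnal range in (0, 25] degC,
    non-negative precipitation and strictly positive radiation.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)

    dates = pd.date_range(
        f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31", freq="D"
    )
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    year = dates.year.to_numpy()
    month = dates.month.to_numpy()
    days_in_year = np.where(dates.is_leap_year, 366.0, 365.0)
    frac = (doy - 0.5) / days_in_year

    clim_tmin = _annual_harmonic(archetype.monthly_tmin_mean, frac)
    clim_tmax = _annual_harmonic(archetype.monthly_tmax_mean, frac)
    clim_mid = (clim_tmin + clim_tmax) / 2.0
    half_range = (clim_tmax - clim_tmin) / 2.0

    # year offset + AR(1) daily anomaly shared between tmin and tmax
    year_ids = year - year.min()
    year_offsets = rng.normal(0.0, archetype.interannual_sd, size=year_ids.max() + 1)
    eps = rng.normal(0.0, 1.5, size=n)
    anom = np.empty(n)
    acc = 0.0
    for i in range(n):  # AR(1) recursion
        acc = 0.70 * acc + eps[i]
        anom[i] = acc
    tmean = clim_mid + year_offsets[year_ids] + anom

    # jittered diurnal half-range, kept in (0.5, 12.4] so range <= 24.8 < 25
    half = np.clip(half_range * (1.0 + 0.15 * rng.normal(size=n)), 0.5, 12.4)
    tmin = tmean - half
    tmax = tmean + half

    # Bernoulli-gamma precipitation from monthly means
    p_wet = archetype.precip_wet_day_prob
    monthly = np.asarray(archetype.monthly_precip_mean, float)
    precip = np.zeros(n)
    if p_wet > 0:
        wet = rng.random(n) < p_wet
        mean_wet = monthly[month - 1] / (_MONTH_DAYS[month - 1] * p_wet)
        shape = 0.75
        amounts = rng.gamma(shape, 1.0, size=n) * (mean_wet / shape)
        precip = np.where(wet & (monthly[month - 1] > 0), amounts, 0.0)

    # radiation: annual sinusoid peaking near the solstice, damped on wet days
    srad = archetype.srad_annual_peak * (
        0.52 + 0.48 * np.cos(2 * np.pi * (doy - 172) / days_in_year)
    )
    srad = srad * np.where(precip > 0, 0.75, 1.0)
    srad = srad * np.clip(1.0 + 0.10 * rng.normal(size=n), 0.6, 1.4)
    srad = np.maximum(srad, 0.3)

    df = pd.DataFrame(
        {
            "date": dates,
            "tmin_c": tmin,
            "tmax_c": tmax,
            "precip_mm": precip,
            "srad_mj_m2": srad,
        }
    )
    df.attrs["lat"] = float(lat)
    if site_id is not None:
        df.attrs["site_id"] = site_id
    return df


def gen_soil(seed: int) -> tuple[SoilProfile, MoistureInit]:
    """Draw a root-zone soil profile and an initial-moisture description."""
    rng = np.random.default_rng(seed)
    wp = rng.uniform(0.08, 0.16)
    porosity = rng.uniform(0.40, 0.52)
    field_cap = wp + (porosity - wp) * rng.uniform(0.45, 0.65)
    depth = 1.0
    soil = SoilProfile(
        paw_capacity_mm=(field_cap - wp) * depth * 1000.0,
        wilting_point=wp,
        porosity=porosity,
        rootzone_depth_m=depth,
    )
    sm_mean = rng.uniform(wp + 0.02, field_cap)
    init = MoistureInit(sm_mean=sm_mean, sm_ensemble_sd=rng.uniform(0.01, 0.04))
    return soil, init


def gen_site_grid(
    n_lat: int,
    n_lon: int,
    resolution: float = 0.5,
    bbox: tuple = DEFAULT_BBOX,
) -> pd.DataFrame:
    """Regular grid of site centroids inside the bounding box.

    Sites are numbered row-major from the south-west corner; spacing equals
    ``resolution`` in both coordinates.
    """
    if n_lat < 1 or n_lon < 1:
        raise ValueError("grid dimensions must be >= 1")
    lat_min, lat_max, lon_min, lon_max = bbox
    lats = lat_min + resolution * (np.arange(n_lat) + 0.5)
    lons = lon_min + resolution * (np.arange(n_lon) + 0.5)
    if lats[-1] > lat_max or lons[-1] > lon_max:
        raise ValueError("grid does not fit inside the bounding box")
    lon_g, lat_g = np.meshgrid(lons, lats)
    return pd.DataFrame(
        {
            "site_id": np.arange(n_lat * n_lon),
            "lat": lat_g.ravel(),
            "lon": lon_g.ravel(),
        }
    )


def gen_yield_series(
    start_year: int,
    n_years: int,
    intercept: float,
    slope: float,
    noise_sd: float,
    seed: int,
    country: str = "synthetic",
    area_ha: float = 100_000.0,
) -> pd.DataFrame:
    """Linear-trend-plus-noise national yield series (FAO-style).

    yield(t) = intercept + slope * (year - start_year) + N(0, noise_sd),
    floored at zero.  Needs at least 3 years so a trend is fittable.
    """
    if n_years < 3:
        raise ValueError("n_years must be >= 3 to support a trend fit")
    if intercept <= 0:
        raise ValueError("intercept must be > 0")
    rng = np.random.default_rng(seed)
    years = start_year + np.arange(n_years)
    y = intercept + slope * (years - start_year)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_years)
    y = np.maximum(y, 0.0)
    return pd.DataFrame(
        {
            "country": country,
            "year": years,
            "area_ha": area_ha,
            "production_t": y * area_ha,
            "yield_t_ha": y,
        }
    )
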