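"""Thermal-time soybean phenology with an adaptive planting rule.

Development is driven by growing degree units (GDU): the mean of daily
tmin/tmax, each clamped to the [10, 30] degC cardinal range, minus the
10 degC base.  Planting occurs on the first day from March 1 whose
trailing 7-day mean GDU exceeds 4.4; emergence after 70 GDU accumulated
from planting; the reproductive stages R1 (first flower), R5 (begin seed
fill) and R7 (physiological maturity) at maturity-group-specific
cumulative thermal-time targets accumulated from emergence.  Post-
emergence development is slowed multiplicatively under daylengths longer
than a critical value, with a sensitivity that increases from the
earliest maturity group (0000) to the latest (III).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MATURITY_GROUPS",
    "MaturityTargets",
    "PhenologyConfig",
    "StageDates",
    "daily_gdu",
    "gdu_series",
    "daylength_hours",
    "decide_planting",
    "predict_stages",
]

#: maturity groups from earliest to latest adaptation class
MATURITY_GROUPS = ("0000", "000", "00", "0", "I", "II", "III")


@dataclass(frozen=True)
class MaturityTargets:
    """Cumulative GDU from emergence to each reproductive stage, plus the
    photoperiod sensitivity slope (development-rate loss per hour of
    daylength beyond the critical daylength)."""

    r1: float
    r5: float
    r7: float
    photoperiod_slope: float = 0.0

    def __post_init__(self):
        if not 0 < self.r1 < self.r5 < self.r7:
            raise ValueError("require 0 < r1 < r5 < r7 thermal targets")
        if self.photoperiod_slope < 0:
            raise ValueError("photoperiod_slope must be >= 0")


def _default_mg_targets() -> dict:
    # Later maturity groups require more thermal time and are more
    # photoperiod sensitive; R7 strictly increasing with later group.
    return {
        "0000": MaturityTargets(280.0, 560.0, 880.0, 0.000),
        "000": MaturityTargets(310.0, 610.0, 950.0, 0.004),
        "00": MaturityTargets(340.0, 660.0, 1020.0, 0.008),
        "0": MaturityTargets(370.0, 710.0, 1090.0, 0.012),
        "I": MaturityTargets(400.0, 760.0, 1160.0, 0.016),
        "II": MaturityTargets(430.0, 810.0, 1230.0, 0.020),
        "III": MaturityTargets(460.0, 860.0, 1300.0, 0.024),
    }


@dataclass
class PhenologyConfig:
    gdu_base: float = 10.0
    gdu_max: float = 30.0
    planting_window: int = 7
    planting_threshold: float = 4.4
    earliest_planting: tuple = (3, 1)   # (month, day): March 1
    latest_planting: tuple = (6, 30)    # after this, "never planted"
    emergence_gdu: float = 70.0
    critical_daylength_h: float = 13.5
    mg_targets: dict = field(default_factory=_default_mg_targets)

    def __post_init__(self):
        if self.gdu_base >= self.gdu_max:
            raise ValueError("gdu_base must be < gdu_max")
        if self.planting_threshold <= 0 or self.emergence_gdu <= 0:
            raise ValueError("thermal thresholds must be > 0")
        if self.planting_window < 1:
            raise ValueError("planting_window must be >= 1")
        r7_prev = 0.0
        for mg in self.mg_targets:
            t = self.mg_targets[mg]
            if t.r7 <= r7_prev:
                raise ValueError("R7 target must increase with later maturity group")
            r7_prev = t.r7


@dataclass
class StageDates:
    """Stage day-of-year values for one site-year; None where never reached."""

    planting: int | None = None
    emergence: int | None = None
    r1: int | None = None
    r5: int | None = None
    r7: int | None = None
    reached_r7: bool = False

    def __post_init__(self):
        if (self.planting is not None and self.emergence is not None
                and self.emergence < self.planting):
            raise ValueError("emergence cannot precede planting")
        seq = [d for d in (self.emergence, self.r1, self.r5, self.r7) if d is not None]
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise ValueError("reproductive stage dates must be strictly increasing")


def daily_gdu(tmin: float, tmax: float, cfg: PhenologyConfig | None = None) -> float:
    """Daily growing degree units with clamped cardinal temperatures."""
    cfg = cfg or PhenologyConfig()
    if np.any(np.asarray(tmax) < np.asarray(tmin)):
        raise ValueError("tmax must be >= tmin")
    lo, hi = cfg.gdu_base, cfg.gdu_max
    tmin_c = np.clip(tmin, lo, hi)
    tmax_c = np.clip(tmax, lo, hi)
    return np.maximum(0.0, (tmin_c + tmax_c) / 2.0 - lo)


def gdu_series(series: pd.DataFrame, cfg: PhenologyConfig | None = None) -> np.ndarray:
    return np.asarray(daily_gdu(series["tmin_c"].to_numpy(),
                                series["tmax_c"].to_numpy(), cfg))


def daylength_hours(lat_deg: float, doy) -> np.ndarray:
    """Civil daylength (sun centre at the horizon) from the standard
    solar-declination formula."""
    doy = np.asarray(doy, float)
    decl = np.radians(-23.44 * np.cos(2 * np.pi * (doy + 10.0) / 365.25))
    lat = math.radians(lat_deg)
    cos_h = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    return 2.0 * np.degrees(np.arccos(cos_h)) / 15.0


def _doy(dates: pd.Series) -> np.ndarray:
    return pd.DatetimeIndex(dates).dayofyear.to_numpy()


def decide_planting(series: pd.DataFrame, cfg: PhenologyConfig | None = None) -> int | None:
    """Adaptive planting date for a single-year daily series.

    Returns the day-of-year of the first day at or after the earliest
    planting date whose trailing ``planting_window``-day mean GDU strictly
    exceeds the threshold, or None if no day up to the latest planting
    date qualifies.  The window is trailing (causal): the first evaluable
    day is the window-th day of the series.
    """
    cfg = cfg or PhenologyConfig()
    if len(series) < cfg.planting_window:
        raise ValueError("series shorter than the planting window")
    gdu = gdu_series(series, cfg)
    roll = pd.Series(gdu).rolling(cfg.planting_window).mean().to_numpy()
    dates = pd.DatetimeIndex(series["date"])
    year = dates[0].year
    earliest = pd.Timestamp(year, *cfg.earliest_planting).dayofyear
    latest = pd.Timestamp(year, *cfg.latest_planting).dayofyear
    doy = dates.dayofyear.to_numpy()
    ok = (roll > cfg.planting_threshold) & (doy >= earliest) & (doy <= latest)
    idx = np.flatnonzero(ok & ~np.isnan(roll))
    if idx.size == 0:
        return None
    return int(doy[idx[0]])


def predict_stages(
    series: pd.DataFrame,
    planting_doy: int,
    mg: str,
    cfg: PhenologyConfig | None = None,
    lat: float | None = None,
) -> StageDates:
    """Emergence and R1/R5/R7 day-of-year values for one maturity group.

    Emergence is the first day whose cumulative post-planting GDU reaches
    ``emergence_gdu``.  Reproductive stages accumulate photoperiod-modified
    GDU from the day after emergence: each day's contribution is
    gdu * (1 - slope * max(0, daylength - critical)).  ``lat`` defaults to
    the latitude stored in ``series.attrs``; with no latitude available the
    photoperiod modifier is 1 (pure thermal time).
    """
    cfg = cfg or PhenologyConfig()
    if mg not in cfg.mg_targets:
        raise KeyError(f"unknown maturity group {mg!r}")
    doy = _doy(series["date"])
    pos = np.flatnonzero(doy == planting_doy)
    if pos.size == 0:
        raise ValueError("planting day not inside the series")
    p = int(pos[0])

    gdu = gdu_series(series, cfg)
    if lat is None:
        lat = series.attrs.get("lat")

    # emergence: cumulative GDU from the day after planting
    cum = np.cumsum(gdu[p + 1:])
    hit = np.flatnonzero(cum >= cfg.emergence_gdu)
    if hit.size == 0:
        return StageDates(planting=int(planting_doy))
    e = p + 1 + int(hit[0])

    targets = cfg.mg_targets[mg]
    dev = gdu[e + 1:].astype(float).copy()
    if lat is not None and targets.photoperiod_slope > 0:
        dl = daylength_hours(float(lat), doy[e + 1:])
        modifier = 1.0 - targets.photoperiod_slope * np.maximum(
            0.0, dl - cfg.critical_daylength_h
        )
        dev *= np.clip(modifier, 0.0, 1.0)
    cum_dev = np.cumsum(dev)

    def stage(target: float) -> int | None:
        hit = np.flatnonzero(cum_dev >= target)
        return e + 1 + int(hit[0]) if hit.size else None

    r1, r5, r7 = stage(targets.r1), stage(targets.r5), stage(targets.r7)
    return StageDates(
        planting=int(planting_doy),
        emergence=int(doy[e]),
        r1=None if r1 is None else int(doy[r1]),
        r5=None if r5 is None else int(doy[r5]),
        r7=None if r7 is None else int(doy[r7]),
        reached_r7=r7 is not None,
    )
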