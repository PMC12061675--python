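"""Thermal time: degree days above a base temperature.

Heat accumulation is computed on a daily time step from maximum and minimum
air temperature, above a base of 10 °C by default.  Two standard estimators
are provided:

* ``average`` — max(0, (Tmax + Tmin)/2 − Tbase); the default.
* ``single_sine`` — the Baskerville–Emin single-sine estimator, which models
  the diurnal course as a sine wave through Tmin and Tmax and integrates the
  part of the wave above the base.  It credits days whose mean is below base
  but whose maximum is above, so it is never smaller than the average method
  on such days.

No upper (cutoff) threshold is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import CoverageError, WeatherGapError
from .fitting import StemSeries
from .richards import Domain

__all__ = [
    "WeatherDay",
    "daily_degree_days",
    "accumulate_thermal_time",
    "reexpress_series",
]

DEFAULT_BASE_C = 10.0


@dataclass(frozen=True)
class WeatherDay:
    """One day of weather: day of year (1-based), Tmax and Tmin in °C."""

    day: int
    tmax: float
    tmin: float

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise ValueError(f"day {self.day}: tmax ({self.tmax}) < tmin ({self.tmin})")


def daily_degree_days(
    tmax: float, tmin: float, t_base: float = DEFAULT_BASE_C, method: str = "average"
) -> float:
    """Degree days (°Cd) accumulated in one day above ``t_base``."""
    if tmax < tmin:
        raise ValueError(f"tmax ({tmax}) < tmin ({tmin})")
    if method == "average":
        return max(0.0, 0.5 * (tmax + tmin) - t_base)
    if method == "single_sine":
        m = 0.5 * (tmax + tmin)
        w = 0.5 * (tmax - tmin)
        if tmin >= t_base:
            return m - t_base
        if tmax <= t_base:
            return 0.0
        theta = math.asin((t_base - m) / w)
        return ((m - t_base) * (0.5 * math.pi - theta) + w * math.cos(theta)) / math.pi
    raise ValueError(f"unknown degree-day method {method!r}")


def accumulate_thermal_time(
    weather, t_base: float = DEFAULT_BASE_C, method: str = "average"
) -> pd.DataFrame:
    """Daily and cumulative degree days for a consecutive run of days.

    Parameters
    ----------
    weather : sequence of WeatherDay or DataFrame with day/tmax_c/tmin_c
    t_base : base temperature (°C)
    method : "average" or "single_sine"

    Returns
    -------
    DataFrame with columns day, daily_dd, cumulative_dd.  A gap in the day
    sequence raises :class:`WeatherGapError`; no silent interpolation.
    """
    if isinstance(weather, pd.DataFrame):
        days = weather["day"].to_numpy(int)
        tmax = weather["tmax_c"].to_numpy(float)
        tmin = weather["tmin_c"].to_numpy(float)
    else:
        weather = list(weather)
        days = np.array([w.day for w in weather], int)
        tmax = np.array([w.tmax for w in weather], float)
        tmin = np.array([w.tmin for w in weather], float)
    if len(days) == 0:
        return pd.DataFrame(columns=["day", "daily_dd", "cumulative_dd"])
    gaps = np.flatnonzero(np.diff(days) != 1)
    if len(gaps):
        raise WeatherGapError(
            f"weather record has a gap after day {days[gaps[0]]} (next is {days[gaps[0] + 1]})"
        )
    daily = np.array([daily_degree_days(hi, lo, t_base, method) for hi, lo in zip(tmax, tmin)])
    return pd.DataFrame({"day": days, "daily_dd": daily, "cumulative_dd": np.cumsum(daily)})


def reexpress_series(series: StemSeries, thermal: pd.DataFrame) -> StemSeries:
    """Re-express a day-of-year stem series on the thermal-time axis.

    Each measurement day's x becomes the cumulative °Cd at that day.  Every
    measurement day must be covered by the thermal series
    (:class:`CoverageError` otherwise).  Because cumulative degree days can
    stall at 0 before the season starts, two pre-season measurements would
    collapse to the same x; that degenerate case is rejected.
    """
    if series.domain != Domain.julian_day:
        raise ValueError("series is already on a thermal-time axis")
    lookup = dict(zip(thermal["day"].astype(int), thermal["cumulative_dd"].astype(float)))
    new_x = []
    for day in series.x:
        d = int(day)
        if d not in lookup:
            raise CoverageError(f"measurement day {d} not covered by the weather record")
        new_x.append(lookup[d])
    new_x = np.asarray(new_x)
    if np.any(np.diff(new_x) <= 0):
        raise ValueError(
            "cumulative degree days are tied across measurement days "
            "(pre-season visits); trim the series before re-expressing"
        )
    return StemSeries(series.plant_id, series.year, new_x, series.length, Domain.thermal_time)
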