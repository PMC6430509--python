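"""Season-scale weather indices from daily records.

Three agronomic indices summarize a daily series of rainfall (mm) and mean
temperature (deg C):

* ``PPT``  cumulative precipitation, sum of daily rainfall (mm);
* ``SDI``  Shannon diversity of rainfall: entropy of the daily rainfall
  proportions normalized by ln(n). 1 when rain falls evenly over the period,
  0 when the whole period's rain falls on a single day;
* ``GDD``  growing degree-days at a 7 deg C base, accumulated as the sum of the
  daily mean temperature on days at or above the base (days below the base
  contribute nothing). A ``conventional`` switch accumulates the excess over
  the base, sum of (Tm - 7)+, instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidWeatherError, UndefinedIndexError

__all__ = [
    "DailyWeatherSeries",
    "cumulative_precipitation",
    "rainfall_sdi",
    "growing_degree_days",
    "weather_indices",
    "weather_indices_by_field",
]

GDD_BASE_C = 7.0


@dataclass(frozen=True)
class DailyWeatherSeries:
    """A contiguous daily record of rainfall and mean temperature for one field.

    ``dates`` must be strictly increasing consecutive calendar days; rainfall
    is in mm/day (non-negative), mean temperature in deg C/day.
    """

    dates: pd.DatetimeIndex
    rainfall: np.ndarray
    mean_temperature: np.ndarray

    def __post_init__(self):
        dates = pd.DatetimeIndex(self.dates)
        rain = np.asarray(self.rainfall, dtype=float)
        temp = np.asarray(self.mean_temperature, dtype=float)
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "rainfall", rain)
        object.__setattr__(self, "mean_temperature", temp)
        n = len(dates)
        if n < 2:
            raise InvalidWeatherError("need at least 2 days")
        if len(rain) != n or len(temp) != n:
            raise InvalidWeatherError("dates, rainfall and temperature lengths differ")
        if not np.all(np.isfinite(rain)) or not np.all(np.isfinite(temp)):
            raise InvalidWeatherError("non-finite weather value")
        if np.any(rain < 0):
            day = dates[int(np.argwhere(rain < 0)[0][0])].date()
            raise InvalidWeatherError(f"negative rainfall on {day}")
        deltas = np.diff(dates.to_numpy()).astype("timedelta64[D]").astype(int)
        if np.any(deltas != 1):
            raise InvalidWeatherError("dates must be strictly increasing, contiguous days")

    def window(self, start=None, end=None) -> "DailyWeatherSeries":
        """Restrict the series to [start, end] (inclusive, ISO dates or timestamps)."""
        mask = np.ones(len(self.dates), dtype=bool)
        if start is not None:
            mask &= self.dates >= pd.Timestamp(start)
        if end is not None:
            mask &= self.dates <= pd.Timestamp(end)
        return DailyWeatherSeries(self.dates[mask], self.rainfall[mask], self.mean_temperature[mask])

    @property
    def n_days(self) -> int:
        return len(self.dates)


def cumulative_precipitation(series: DailyWeatherSeries) -> float:
    """PPT: total rainfall over the series, in mm."""
    return float(series.rainfall.sum())


def rainfall_sdi(series: DailyWeatherSeries) -> float:
    """Rainfall Shannon diversity: -sum(Pi ln Pi)/ln(n), Pi = daily share of PPT.

    Uses the 0*ln(0) = 0 convention, so a series with all rain on one day
    scores exactly 0 and perfectly even rain scores exactly 1. Undefined
    (raises) when the series is completely dry.
    """
    ppt = cumulative_precipitation(series)
    if ppt <= 0:
        raise UndefinedIndexError("SDI undefined: total precipitation is zero")
    p = series.rainfall / ppt
    nz = p > 0
    entropy = -np.sum(p[nz] * np.log(p[nz]))
    return float(entropy / np.log(series.n_days)) + 0.0  # normalize -0.0


def growing_degree_days(series: DailyWeatherSeries, conventional: bool = False) -> float:
    """GDD at a 7 deg C base.

    Default accumulation adds the full daily mean temperature on days at or
    above the base; ``conventional=True`` adds only the excess over the base.
    """
    tm = series.mean_temperature
    warm = tm >= GDD_BASE_C
    if conventional:
        return float(np.sum(tm[warm] - GDD_BASE_C))
    return float(np.sum(tm[warm]))


def weather_indices(series: DailyWeatherSeries, start=None, end=None,
                    conventional_gdd: bool = False) -> dict:
    """PPT, SDI and GDD for one series, optionally over a date window."""
    if start is not None or end is not None:
        series = series.window(start, end)
    return {
        "PPT": cumulative_precipitation(series),
        "SDI": rainfall_sdi(series),
        "GDD": growing_degree_days(series, conventional=conventional_gdd),
    }


def weather_indices_by_field(daily: pd.DataFrame, start=None, end=None,
                             conventional_gdd: bool = False) -> pd.DataFrame:
    """Compute the three indices per field from a long-format daily table.

    Parameters
    ----------
    daily
        Columns ``field_id``, ``date`` (ISO 8601), ``rain_mm``, ``tmean_c``.

    Returns
    -------
    pandas.DataFrame
        One row per field, columns PPT, SDI, GDD, indexed by field_id.
    """
    required = {"field_id", "date", "rain_mm", "tmean_c"}
    missing = required - set(daily.columns)
    if missing:
        raise InvalidWeatherError(f"daily weather table missing columns {sorted(missing)}")
    rows = {}
    for field_id, grp in daily.groupby("field_id", sort=True):
        grp = grp.sort_values("date")
        series = DailyWeatherSeries(
            pd.DatetimeIndex(pd.to_datetime(grp["date"])),
            grp["rain_mm"].to_numpy(),
            grp["tmean_c"].to_numpy(),
        )
        rows[field_id] = weather_indices(series, start, end, conventional_gdd)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "field_id"
    return out
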