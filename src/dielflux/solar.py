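"""Sunrise/sunset computation and day/night labelling of hourly flux series.

Sunrise and sunset come from the NOAA solar-position equations (fractional-year
Fourier expansions for the equation of time and solar declination, zenith
90.833 deg to include standard atmospheric refraction and the solar radius).
At forest latitudes these agree with ephemeris-based times to well under a
minute, far below the hourly resolution of chamber data.

Conventions
-----------
* All clock times are site *standard* time (no DST), i.e. UTC + ``utc_offset``.
* An hourly record stamped ``h`` covers ``[h, h+1)``; it is daytime iff its
  midpoint ``h + 30 min`` falls in ``[sunrise, sunset)``.
* A "night of date d" spans sunset(d) -> sunrise(d+1): night hours after
  sunset keep ``diel_date = d``, night hours before sunrise get ``d - 1``.
  This makes (daytime of d, following night) the pairing unit for diel tests.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DayWindow",
    "PolarDayError",
    "sun_times",
    "day_length_hours",
    "label_hours",
    "season_filter",
    "SEASONS",
]

#: zenith angle of the sun's centre at rise/set: 90 deg + 34' refraction + 16' radius
ZENITH_DEG = 90.833

SEASONS = ("spring", "summer", "autumn", "winter")

# calendar months per season in the Northern Hemisphere; the Southern
# Hemisphere swaps by six months (summer = DJF etc.)
_SEASON_MONTHS_N = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
    "winter": (12, 1, 2),
}


class PolarDayError(ValueError):
    """The sun does not rise or set on the requested date at this latitude."""


@dataclass(frozen=True)
class DayWindow:
    """Sunrise/sunset of one calendar date in site standard time."""

    date: dt.date
    sunrise_local: dt.time
    sunset_local: dt.time
    day_length: float  # hours

    @property
    def sunrise_hours(self) -> float:
        t = self.sunrise_local
        return t.hour + t.minute / 60.0 + t.second / 3600.0

    @property
    def sunset_hours(self) -> float:
        t = self.sunset_local
        return t.hour + t.minute / 60.0 + t.second / 3600.0


def _fractional_year(doy: np.ndarray, hour: float = 12.0) -> np.ndarray:
    return 2.0 * np.pi / 365.0 * (doy - 1 + (hour - 12.0) / 24.0)

def _equation_of_time_min(g: np.ndarray) -> np.ndarray:
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )

def _declination_rad(g: np.ndarray) -> np.ndarray:
    return (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )


def solar_declination(dates) -> np.ndarray:
    """Solar declination (radians) at local noon for one date or an array."""
    doy = np.atleast_1d(pd.to_datetime(dates).dayofyear if hasattr(dates, "__iter__")
                        else pd.Timestamp(dates).dayofyear).astype(float)
    return _declination_rad(_fractional_year(doy))


def _rise_set_minutes(lat: float, lon: float, utc_offset: float,
                      doy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sunrise/sunset in minutes after local-standard midnight (vectorised)."""
    g = _fractional_year(doy)
    eqtime = _equation_of_time_min(g)
    decl = _declination_rad(g)
    lat_r = np.deg2rad(lat)
    cos_ha = (np.cos(np.deg2rad(ZENITH_DEG)) / (np.cos(lat_r) * np.cos(decl))
              - np.tan(lat_r) * np.tan(decl))
    # |cos_ha| > 1: polar day (< -1) or polar night (> 1); caller decides
    with np.errstate(invalid="ignore"):
        ha_deg = np.rad2deg(np.arccos(cos_ha))
    sunrise_utc = 720.0 - 4.0 * (lon + ha_deg) - eqtime
    sunset_utc = 720.0 - 4.0 * (lon - ha_deg) - eqtime
    off = 60.0 * utc_offset
    return sunrise_utc + off, sunset_utc + off


def sun_times(lat: float, lon: float, utc_offset: float, date: dt.date) -> DayWindow:
    """Sunrise/sunset for one site-date, in site standard time.

    Raises :class:`PolarDayError` on dates with no sunrise or no sunset
    (only possible poleward of the polar circles).
    """
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude {lat} out of range")
    date = pd.Timestamp(date).date()
    doy = np.array([float(pd.Timestamp(date).dayofyear)])
    rise, setm = _rise_set_minutes(lat, lon, utc_offset, doy)
    if not (np.isfinite(rise[0]) and np.isfinite(setm[0])):
        raise PolarDayError(
            f"no sunrise/sunset at lat={lat} on {date.isoformat()} (polar day or night)"
        )
    def _to_time(minutes: float) -> dt.time:
        m = minutes % 1440.0
        h = int(m // 60)
        mi = int(m % 60)
        s = int(round((m - h * 60 - mi) * 60))
        if s == 60:
            s = 0
            mi += 1
        if mi == 60:
            mi = 0
            h = (h + 1) % 24
        return dt.time(h, mi, s)

    day_len = (setm[0] - rise[0]) / 60.0
    return DayWindow(date=date, sunrise_local=_to_time(rise[0]),
                     sunset_local=_to_time(setm[0]), day_length=day_len)


def day_length_hours(lat: float, date: dt.date) -> float:
    """Astronomical day length (hours); longitude-independent."""
    return sun_times(lat, 0.0, 0.0, date).day_length


def label_hours(series: pd.DataFrame, meta) -> pd.DataFrame:
    """Label each hourly row ``day``/``night`` and assign its ``diel_date``.

    ``series`` needs a ``timestamp`` column in site standard time. Returns a
    copy with ``period`` (category: day/night) and ``diel_date`` columns.
    Propagates :class:`PolarDayError` from :func:`sun_times`.
    """
    if series.empty:
        out = series.copy()
        out["period"] = pd.Series(dtype="object")
        out["diel_date"] = pd.Series(dtype="object")
        return out
    out = series.copy()
    ts = pd.to_datetime(out["timestamp"])
    dates = ts.dt.normalize()
    uniq = dates.unique()
    doy = pd.DatetimeIndex(uniq).dayofyear.to_numpy(dtype=float)
    rise, setm = _rise_set_minutes(meta.lat, meta.lon, meta.utc_offset, doy)
    bad = ~(np.isfinite(rise) & np.isfinite(setm))
    if bad.any():
        first = pd.Timestamp(uniq[np.argmax(bad)]).date()
        raise PolarDayError(
            f"no sunrise/sunset at lat={meta.lat} on {first.isoformat()}"
        )
    rise_map = dict(zip(uniq, rise))
    set_map = dict(zip(uniq, setm))
    mid_min = (ts - dates).dt.total_seconds().to_numpy() / 60.0 + 30.0
    rise_arr = dates.map(rise_map).to_numpy(dtype=float)
    set_arr = dates.map(set_map).to_numpy(dtype=float)
    is_day = (mid_min >= rise_arr) & (mid_min < set_arr)
    out["period"] = np.where(is_day, "day", "night")
    # pre-dawn night hours belong to the previous date's night
    pre_dawn = (~is_day) & (mid_min < rise_arr)
    diel = dates.dt.date.to_numpy(dtype=object)
    diel[pre_dawn] = (dates[pre_dawn] - pd.Timedelta(days=1)).dt.date.to_numpy(dtype=object)
    out["diel_date"] = diel
    return out


def season_filter(series: pd.DataFrame, meta, season: str = "summer") -> pd.DataFrame:
    """Select rows whose ``diel_date`` falls in the given climatic season.

    Summer is June-August in the Northern Hemisphere and December-February in
    the Southern Hemisphere; the other seasons shift accordingly.
    """
    if season not in SEASONS:
        raise ValueError(f"season must be one of {SEASONS}, got {season!r}")
    months = _SEASON_MONTHS_N[season]
    if getattr(meta, "hemisphere", "N") == "S":
        months = tuple((m + 6 - 1) % 12 + 1 for m in months)
    col = "diel_date" if "diel_date" in series.columns else "timestamp"
    month = pd.to_datetime(series[col]).dt.month
    return series.loc[month.isin(months)].copy()
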