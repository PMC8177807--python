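"""Solar and lunar ephemeris: day length, night windows, and moonlit hours.

Sunrise/sunset follow the NOAA solar-position algorithm (the spreadsheet
formulation of Meeus' series), with the conventional -0.833 deg solar
altitude at rise/set.  Lunar altitude uses the Astronomical Almanac
low-precision series (~0.3 deg, valid 1900-2100); moon-up intervals within a
night are found on a one-minute altitude grid.  All timestamps are naive UTC.

An injected moonrise/moonset table (CSV: date, moonrise, moonset) can replace
the algorithmic lunar path; it is the reference path in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as _date
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "SolarDay",
    "NightWindow",
    "solar_events",
    "sun_altitude",
    "moon_altitude",
    "moon_intervals",
    "moonlit_hours",
    "night_window",
    "assign_day_night",
    "load_moon_table",
]

_J2000 = 2451545.0
SUN_RISESET_ALTITUDE_DEG = -0.833  # refraction + semidiameter convention


@dataclass(frozen=True)
class SolarDay:
    """Sunrise/sunset for one date at one location (UTC)."""

    date: _date
    lat: float
    lon: float
    sunrise: datetime | None
    sunset: datetime | None
    day_length_h: float
    polar_day: bool = False
    polar_night: bool = False


@dataclass
class NightWindow:
    """One night: sunset of ``date`` to the next sunrise.

    ``moonlit_intervals`` are [start, end) pairs clipped to the window.
    """

    date: _date
    start: datetime
    end: datetime
    moonlit_intervals: list[tuple[datetime, datetime]] = field(default_factory=list)

    @property
    def length_h(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0

    @property
    def moonlit_hours(self) -> float:
        return moonlit_hours(self)


def _julian_day(dt: datetime) -> float:
    y, m = dt.year, dt.month
    d = dt.day + (dt.hour + dt.minute / 60.0 + dt.second / 3600.0) / 24.0
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def _sun_geometry(jd: float) -> tuple[float, float]:
    """Return (declination deg, equation of time in minutes) at Julian day jd."""
    t = (jd - _J2000) / 36525.0
    l0 = (280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360.0
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    mrad = math.radians(m)
    c = (
        math.sin(mrad) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + math.sin(2 * mrad) * (0.019993 - 0.000101 * t)
        + math.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + c
    omega = 125.04 - 1934.136 * t
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))
    eps0 = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * math.cos(math.radians(omega))
    decl = math.degrees(
        math.asin(math.sin(math.radians(eps)) * math.sin(math.radians(app_long)))
    )
    vary = math.tan(math.radians(eps / 2.0)) ** 2
    l0r, mr = math.radians(l0), mrad
    eqtime = 4.0 * math.degrees(
        vary * math.sin(2 * l0r)
        - 2 * ecc * math.sin(mr)
        + 4 * ecc * vary * math.sin(mr) * math.cos(2 * l0r)
        - 0.5 * vary * vary * math.sin(4 * l0r)
        - 1.25 * ecc * ecc * math.sin(2 * mr)
    )
    return decl, eqtime


def solar_events(date: _date, lat: float, lon: float) -> SolarDay:
    """NOAA sunrise/sunset (UTC) and day length for one date and location.

    Polar day/night are flagged when the sun never crosses the rise/set
    altitude; day length is then 24 h or 0 h.
    """
    if abs(lat) > 90.0:
        raise ValueError(f"latitude out of range: {lat}")
    midnight = datetime(date.year, date.month, date.day)
    # Evaluate the solar series at local solar noon (two-pass refinement).
    noon_min = 720.0 - 4.0 * lon
    for _ in range(2):
        jd = _julian_day(midnight) + noon_min / 1440.0
        decl, eqtime = _sun_geometry(jd)
        noon_min = 720.0 - 4.0 * lon - eqtime

    latr, declr = math.radians(lat), math.radians(decl)
    cos_ha = (
        math.cos(math.radians(90.0 - SUN_RISESET_ALTITUDE_DEG))
        / (math.cos(latr) * math.cos(declr))
        - math.tan(latr) * math.tan(declr)
    )
    if cos_ha < -1.0:
        return SolarDay(date, lat, lon, None, None, 24.0, polar_day=True)
    if cos_ha > 1.0:
        return SolarDay(date, lat, lon, None, None, 0.0, polar_night=True)
    ha_min = 4.0 * math.degrees(math.acos(cos_ha))
    sunrise = midnight + timedelta(minutes=noon_min - ha_min)
    sunset = midnight + timedelta(minutes=noon_min + ha_min)
    return SolarDay(date, lat, lon, sunrise, sunset, 2.0 * ha_min / 60.0)


def sun_altitude(dt: datetime, lat: float, lon: float) -> float:
    """Geometric solar altitude (deg) — used as an event-finding cross-check."""
    jd = _julian_day(dt)
    decl, eqtime = _sun_geometry(jd)
    minutes = dt.hour * 60.0 + dt.minute + dt.second / 60.0
    tst = (minutes + eqtime + 4.0 * lon) % 1440.0
    ha = tst / 4.0 - 180.0
    latr, declr, har = map(math.radians, (lat, decl, ha))
    sin_alt = math.sin(latr) * math.sin(declr) + math.cos(latr) * math.cos(declr) * math.cos(har)
    return math.degrees(math.asin(sin_alt))


def _moon_equatorial(jd):
    """Low-precision geocentric lunar RA/dec/parallax (degrees); vectorised."""
    t = (np.asarray(jd, dtype=float) - _J2000) / 36525.0
    s, c, rad = np.sin, np.cos, np.radians
    lam = (
        218.32
        + 481267.881 * t
        + 6.29 * s(rad(135.0 + 477198.87 * t))
        - 1.27 * s(rad(259.3 - 413335.36 * t))
        + 0.66 * s(rad(235.7 + 890534.22 * t))
        + 0.21 * s(rad(269.9 + 954397.74 * t))
        - 0.19 * s(rad(357.5 + 35999.05 * t))
        - 0.11 * s(rad(186.5 + 966404.03 * t))
    )
    beta = (
        5.13 * s(rad(93.3 + 483202.02 * t))
        + 0.28 * s(rad(228.2 + 960400.89 * t))
        - 0.28 * s(rad(318.3 + 6003.15 * t))
        - 0.17 * s(rad(217.6 - 407332.21 * t))
    )
    par = (
        0.9508
        + 0.0518 * c(rad(135.0 + 477198.87 * t))
        + 0.0095 * c(rad(259.3 - 413335.36 * t))
        + 0.0078 * c(rad(235.7 + 890534.22 * t))
        + 0.0028 * c(rad(269.9 + 954397.74 * t))
    )
    eps = rad(23.439291 - 0.0130042 * t)
    lamr, betar = rad(lam), rad(beta)
    x = c(betar) * c(lamr)
    y = c(eps) * c(betar) * s(lamr) - s(eps) * s(betar)
    z = s(eps) * c(betar) * s(lamr) + c(eps) * s(betar)
    ra = np.degrees(np.arctan2(y, x))
    dec = np.degrees(np.arcsin(z))
    return ra, dec, par


def moon_altitude(dt, lat: float, lon: float):
    """Topocentric lunar altitude (deg) at datetime(s) ``dt``; vectorised.

    Parallax is applied as alt_topo = alt_geo - par * cos(alt_geo), adequate
    at the ~0.1 deg level for horizon-crossing work.
    """
    dts = np.atleast_1d(np.asarray(dt, dtype="datetime64[s]"))
    jd = _J2000 + (dts - np.datetime64("2000-01-01T12:00:00")) / np.timedelta64(1, "D")
    ra, dec, par = _moon_equatorial(jd)
    d = jd - _J2000
    gmst = (280.46061837 + 360.98564736629 * d) % 360.0
    ha = np.radians((gmst + lon - ra) % 360.0)
    latr, decr = math.radians(lat), np.radians(dec)
    sin_alt = math.sin(latr) * np.sin(decr) + math.cos(latr) * np.cos(decr) * np.cos(ha)
    alt = np.degrees(np.arcsin(np.clip(sin_alt, -1.0, 1.0)))
    alt = alt - par * np.cos(np.radians(alt))
    return alt if np.ndim(dt) or isinstance(dt, (list, np.ndarray)) else float(alt[0])


def night_window(date: _date, lat: float, lon: float) -> NightWindow | None:
    """The night starting at ``date``'s sunset, ending at next sunrise.

    Returns None during polar day (no night).
    """
    today = solar_events(date, lat, lon)
    tomorrow = solar_events(date + timedelta(days=1), lat, lon)
    if today.polar_day:
        return None
    if today.polar_night:
        start = datetime(date.year, date.month, date.day)
        end = start + timedelta(days=1)
    else:
        start = today.sunset
        end = tomorrow.sunrise
        if end is None:  # polar transition: night runs to next midnight
            end = datetime(date.year, date.month, date.day) + timedelta(days=1)
    return NightWindow(date=date, start=start, end=end)


def _merge_intervals(intervals):
    out: list[tuple[datetime, datetime]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def moon_intervals(
    night: NightWindow,
    lat: float,
    lon: float,
    moon_table: pd.DataFrame | None = None,
    step_min: int = 1,
) -> list[tuple[datetime, datetime]]:
    """Intervals within the night when the moon is above the geometric horizon.

    With ``moon_table`` (columns ``moonrise``/``moonset`` as datetimes) the
    listed up-intervals are clipped to the night window; otherwise the
    low-precision lunar altitude is scanned on a ``step_min``-minute grid.
    """
    if moon_table is not None:
        ivs = []
        for _, row in moon_table.iterrows():
            mr, ms = row["moonrise"], row["moonset"]
            if pd.isna(mr) or pd.isna(ms):
                continue
            s, e = max(mr.to_pydatetime(), night.start), min(ms.to_pydatetime(), night.end)
            if s < e:
                ivs.append((s, e))
        night.moonlit_intervals = _merge_intervals(ivs)
        return night.moonlit_intervals

    n_steps = int((night.end - night.start).total_seconds() // (60 * step_min)) + 1
    grid = np.array(
        [night.start + timedelta(minutes=step_min * i) for i in range(n_steps)],
        dtype="datetime64[s]",
    )
    up = moon_altitude(grid, lat, lon) > 0.0
    ivs = []
    i = 0
    while i < n_steps:
        if up[i]:
            j = i
            while j + 1 < n_steps and up[j + 1]:
                j += 1
            s = night.start + timedelta(minutes=step_min * i)
            e = min(night.start + timedelta(minutes=step_min * (j + 1)), night.end)
            ivs.append((s, e))
            i = j + 1
        else:
            i += 1
    night.moonlit_intervals = _merge_intervals(ivs)
    return night.moonlit_intervals


def moonlit_hours(night: NightWindow) -> float:
    """Total moonlit duration of the night in hours (overlaps merged)."""
    merged = _merge_intervals(
        [(max(s, night.start), min(e, night.end)) for s, e in night.moonlit_intervals if s < e]
    )
    return sum((e - s).total_seconds() for s, e in merged if s < e) / 3600.0


def assign_day_night(ts: datetime, solar: SolarDay) -> str:
    """Classify a timestamp as 'day' or 'night' against its SolarDay.

    Day iff sunrise <= t < sunset; polar day is all day, polar night all
    night.
    """
    if solar.polar_day:
        return "day"
    if solar.polar_night:
        return "night"
    return "day" if solar.sunrise <= ts < solar.sunset else "night"


def load_moon_table(path) -> pd.DataFrame:
    """Read an injected moonrise/moonset CSV (date, moonrise, moonset[, fraction_illuminated])."""
    df = pd.read_csv(path, parse_dates=["moonrise", "moonset"])
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df
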