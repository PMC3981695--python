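"""Approximate sunrise/sunset times for day/night assignment.

A compact NOAA-style solar position approximation: solar declination and
the equation of time from the day-of-year, then the sunrise hour angle for
the standard refraction-corrected zenith of 90.833 degrees.  Accuracy is a
few minutes, ample for monthly-mean light categories.
"""

from __future__ import annotations

from datetime import date

import numpy as np

__all__ = ["sun_times", "monthly_sun_table"]

# Default study-area coordinates (San Juan Islands, Salish Sea) and the
# Pacific standard UTC offset used for local clock times.
DEFAULT_LAT = 48.5
DEFAULT_LON = -122.75
DEFAULT_UTC_OFFSET = -8.0

_ZENITH = np.radians(90.833)


def _declination_eot(day_of_year: int) -> tuple[float, float]:
    """Solar declination (radians) and equation of time (minutes)."""
    g = 2 * np.pi / 365.0 * (day_of_year - 1 + 0.5)
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    eot = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    return decl, eot


def sun_times(
    day: date,
    lat: float = DEFAULT_LAT,
    lon: float = DEFAULT_LON,
    utc_offset: float = DEFAULT_UTC_OFFSET,
) -> tuple[float, float]:
    """Sunrise and sunset as local clock hours for one calendar day.

    Polar day/night degenerate cases clamp to (0, 24) and (12, 12)
    respectively; they cannot occur at mid latitudes.
    """
    doy = day.timetuple().tm_yday
    decl, eot = _declination_eot(doy)
    phi = np.radians(lat)
    cos_h = (np.cos(_ZENITH) - np.sin(phi) * np.sin(decl)) / (
        np.cos(phi) * np.cos(decl)
    )
    if cos_h >= 1.0:
        return 12.0, 12.0  # sun never rises
    if cos_h <= -1.0:
        return 0.0, 24.0  # sun never sets
    hour_angle = np.degrees(np.arccos(cos_h))  # degrees
    solar_noon = 12.0 - lon / 15.0 - eot / 60.0 + utc_offset
    sunrise = solar_noon - hour_angle / 15.0
    sunset = solar_noon + hour_angle / 15.0
    return float(sunrise % 24.0), float(sunset % 24.0)


def monthly_sun_table(
    year: int,
    lat: float = DEFAULT_LAT,
    lon: float = DEFAULT_LON,
    utc_offset: float = DEFAULT_UTC_OFFSET,
):
    """Mean sunrise/sunset clock hours per month as a 12-row DataFrame."""
    import calendar

    import pandas as pd

    rows = []
    for month in range(1, 13):
        ndays = calendar.monthrange(year, month)[1]
        times = [
            sun_times(date(year, month, d), lat, lon, utc_offset)
            for d in range(1, ndays + 1)
        ]
        rise = float(np.mean([t[0] for t in times]))
        sett = float(np.mean([t[1] for t in times]))
        rows.append({"month": month, "sunrise": rise, "sunset": sett})
    return pd.DataFrame(rows).set_index("month")
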