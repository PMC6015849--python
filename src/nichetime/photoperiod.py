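"""Day length and civil-twilight-bounded night length at the summer solstice.

The available "time resource" of a day-active predator is the time the sun's
centre spends above the horizon; for a night-active predator it is the time
the sun's centre spends more than 6 degrees below the horizon (civil night).
Both are pure functions of latitude and solar declination; they are evaluated
at the local hemisphere's summer solstice as a proxy for the resource during
the breeding season. Geometric horizon convention: no refraction or solar
disc radius.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "solar_declination",
    "day_length",
    "night_length",
    "solstice_for_cell",
    "annotate_photoperiod",
    "JUNE_SOLSTICE_DOY",
    "DECEMBER_SOLSTICE_DOY",
]

JUNE_SOLSTICE_DOY = 172  # June 21 (non-leap year)
DECEMBER_SOLSTICE_DOY = 355  # December 21


def solar_declination(day_of_year) -> np.ndarray | float:
    """Solar declination (degrees) from day of year, Spencer's Fourier series.

    Accurate to about 0.03 degrees, ample for day-length work.
    """
    day = np.asarray(day_of_year)
    if np.any((day < 1) | (day > 366)):
        raise ValueError("day_of_year must be in 1..366")
    g = 2.0 * np.pi * (day - 1) / 365.0
    decl = (0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
            - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
            - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g))
    out = np.degrees(decl)
    return float(out) if np.isscalar(day_of_year) else out


def _period_length(latitude, declination, depression: float) -> np.ndarray | float:
    """Hours per day with the sun's centre above ``-depression`` degrees."""
    phi = np.radians(np.asarray(latitude, dtype=float))
    delta = np.radians(np.asarray(declination, dtype=float))
    cos_omega = ((np.sin(np.radians(-depression)) - np.sin(phi) * np.sin(delta))
                 / (np.cos(phi) * np.cos(delta)))
    cos_omega = np.clip(cos_omega, -1.0, 1.0)  # polar day/night
    omega = np.degrees(np.arccos(cos_omega))
    hours = 2.0 * omega * 24.0 / 360.0
    return float(hours) if np.ndim(latitude) == 0 and np.ndim(declination) == 0 else hours


def day_length(latitude, declination) -> np.ndarray | float:
    """Sunrise-to-sunset duration in hours (sun centre above the horizon)."""
    return _period_length(latitude, declination, depression=0.0)


def night_length(latitude, declination, depression: float = 6.0) -> np.ndarray | float:
    """Dusk-to-dawn duration in hours: sun centre below ``-depression`` degrees.

    With the default 6-degree depression this is the civil night; at high
    summer latitudes it can be zero ("white nights") even though the sun sets.
    """
    if depression < 0:
        raise ValueError("depression must be non-negative")
    extended_day = _period_length(latitude, declination, depression=depression)
    return np.clip(24.0 - extended_day, 0.0, 24.0) if np.ndim(extended_day) else float(
        min(max(24.0 - extended_day, 0.0), 24.0))


def solstice_for_cell(latitude, hemisphere_local: bool = True) -> np.ndarray | int:
    """Day of year of the local summer solstice.

    June 21 for latitudes >= 0 (ties go north), December 21 south; with
    ``hemisphere_local=False`` June 21 is used globally (sensitivity mode).
    """
    lat = np.asarray(latitude, dtype=float)
    if not hemisphere_local:
        out = np.full(lat.shape, JUNE_SOLSTICE_DOY)
    else:
        out = np.where(lat >= 0, JUNE_SOLSTICE_DOY, DECEMBER_SOLSTICE_DOY)
    return int(out) if np.ndim(latitude) == 0 else out


def annotate_photoperiod(cells, lat_column: str = "lat", depression: float = 6.0,
                         hemisphere_local: bool = True):
    """Add ``day_length`` and ``night_length`` columns to a cell/assemblage table."""
    df = cells.copy()
    doy = solstice_for_cell(df[lat_column].to_numpy(), hemisphere_local)
    decl = solar_declination(doy)
    df["day_length"] = day_length(df[lat_column].to_numpy(), decl)
    df["night_length"] = night_length(df[lat_column].to_numpy(), decl,
                                      depression=depression)
    return df
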