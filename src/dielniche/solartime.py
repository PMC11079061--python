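"""Sunrise/sunset computation and the solar-time transformation.

Clock time has little biological meaning for diel activity: dawn at a fixed
latitude drifts by hours over the year, so activity anchored to twilight
smears out when plotted on the clock.  The standard fix in activity-overlap
work is *double-anchored solar time*: each day's sunrise maps to pi/2 and
sunset to 3*pi/2 on the circle, with clock times interpolated linearly inside
the day and across the adjacent night.  Midday is always pi and solar
midnight 0 (= 2*pi), regardless of date.

Sunrise and sunset come from the NOAA solar-position equations (fractional
year, equation of time, solar declination, hour angle at zenith 90.833 deg),
evaluated at a single reference point — the reserve center — for all cameras.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date, datetime, timedelta

import numpy as np

TWO_PI = 2.0 * math.pi
SUNRISE_ANGLE = math.pi / 2
SUNSET_ANGLE = 3 * math.pi / 2

#: zenith for official sunrise/sunset: 90 deg 50' (refraction + solar radius)
_ZENITH_DEG = 90.833


class PolarDayError(ValueError):
    """The sun does not rise or set on this date at this latitude."""


@dataclass(frozen=True)
class SunTimes:
    """Local civil sunrise and sunset for one date."""

    date: Date
    sunrise: datetime
    sunset: datetime

    def __post_init__(self) -> None:
        if not self.sunrise < self.sunset:
            raise ValueError("sunrise must precede sunset")

    @property
    def day_length(self) -> timedelta:
        return self.sunset - self.sunrise


@dataclass
class SolarSample:
    """Event times of one species-season on the solar circle, in radians."""

    species: str
    season: str
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float) % TWO_PI

    @property
    def n(self) -> int:
        return len(self.times)


def _noaa_eqtime_decl(day_of_year: int, hour: float = 12.0) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians), NOAA form."""
    g = TWO_PI / 365.0 * (day_of_year - 1 + (hour - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )
    return eqtime, decl


def sun_times(date: Date, latitude: float, longitude: float,
              utc_offset: float) -> SunTimes:
    """Local civil sunrise/sunset at a point, by the NOAA equations.

    Accurate to roughly a minute or two at mid-latitudes.  Raises
    :class:`PolarDayError` when the sun never crosses the horizon.
    """
    if abs(latitude) >= 66.5:
        raise PolarDayError(
            f"latitude {latitude} is polar; sunrise/sunset may be undefined"
        )
    doy = date.timetuple().tm_yday
    eqtime, decl = _noaa_eqtime_decl(doy)
    lat = math.radians(latitude)
    cos_ha = (
        math.cos(math.radians(_ZENITH_DEG)) / (math.cos(lat) * math.cos(decl))
        - math.tan(lat) * math.tan(decl)
    )
    if not -1.0 < cos_ha < 1.0:
        raise PolarDayError(f"no sunrise/sunset on {date} at latitude {latitude}")
    ha_deg = math.degrees(math.acos(cos_ha))

    midnight = datetime(date.year, date.month, date.day)
    rise_min = 720.0 - 4.0 * (longitude + ha_deg) - eqtime + utc_offset * 60.0
    set_min = 720.0 - 4.0 * (longitude - ha_deg) - eqtime + utc_offset * 60.0
    return SunTimes(
        date=date,
        sunrise=midnight + timedelta(minutes=rise_min),
        sunset=midnight + timedelta(minutes=set_min),
    )


def _shifted(sun: SunTimes, days: int) -> SunTimes:
    # fallback neighbour-day approximation: sunrise/sunset drift < ~2 min/day
    d = timedelta(days=days)
    return SunTimes(sun.date + d, sun.sunrise + d, sun.sunset + d)


def clock_to_solar(clock: datetime, sun: SunTimes,
                   sun_prev: SunTimes | None = None,
                   sun_next: SunTimes | None = None) -> float:
    """Map a local civil time to the sunrise/sunset-anchored circle.

    Sunrise maps to pi/2 and sunset to 3*pi/2 exactly; daytime interpolates
    linearly between them, and night interpolates linearly from the previous
    sunset to the next sunrise (so solar midnight is 0).  ``sun`` must be the
    :class:`SunTimes` of ``clock``'s own date; the neighbouring days default
    to a shifted copy of ``sun`` when not supplied.
    """
    sun_prev = sun_prev or _shifted(sun, -1)
    sun_next = sun_next or _shifted(sun, +1)
    if clock == sun.sunrise:
        return SUNRISE_ANGLE
    if clock == sun.sunset:
        return SUNSET_ANGLE
    if sun.sunrise < clock < sun.sunset:
        frac = (clock - sun.sunrise) / sun.day_length
        return SUNRISE_ANGLE + math.pi * frac
    if clock > sun.sunset:  # evening: tonight's night interval
        night = sun_next.sunrise - sun.sunset
        frac = (clock - sun.sunset) / night
    else:  # small hours: the night that began yesterday
        night = sun.sunrise - sun_prev.sunset
        frac = (clock - sun_prev.sunset) / night
    return (SUNSET_ANGLE + math.pi * frac) % TWO_PI


def solar_to_clock(theta: float, sun: SunTimes,
                   sun_next: SunTimes | None = None) -> datetime:
    """Invert :func:`clock_to_solar` for ``sun``'s date.

    Day angles (pi/2..3*pi/2) land between that date's sunrise and sunset;
    night angles land between that date's sunset and the next sunrise, so the
    result may fall on the following calendar date.
    """
    sun_next = sun_next or _shifted(sun, +1)
    theta = theta % TWO_PI
    if SUNRISE_ANGLE <= theta <= SUNSET_ANGLE:
        frac = (theta - SUNRISE_ANGLE) / math.pi
        return sun.sunrise + frac * sun.day_length
    frac = ((theta - SUNSET_ANGLE) % TWO_PI) / math.pi
    return sun.sunset + frac * (sun_next.sunrise - sun.sunset)


class SolarClock:
    """Solar-time converter for one reference point, with per-date caching."""

    def __init__(self, latitude: float, longitude: float, utc_offset: float):
        self.latitude = latitude
        self.longitude = longitude
        self.utc_offset = utc_offset
        self._cache: dict[Date, SunTimes] = {}

    def sun_times(self, date: Date) -> SunTimes:
        st = self._cache.get(date)
        if st is None:
            st = sun_times(date, self.latitude, self.longitude, self.utc_offset)
            self._cache[date] = st
        return st

    def to_solar(self, clock: datetime) -> float:
        d = clock.date()
        return clock_to_solar(
            clock,
            self.sun_times(d),
            self.sun_times(d - timedelta(days=1)),
            self.sun_times(d + timedelta(days=1)),
        )

    def to_clock(self, theta: float, date: Date) -> datetime:
        return solar_to_clock(
            theta, self.sun_times(date), self.sun_times(date + timedelta(days=1))
        )


def samples_to_frame(samples: dict[tuple[str, str], SolarSample]):
    """Flatten solar samples to an audit table (species, season, solar_radians)."""
    import pandas as pd

    rows = [
        (s.species, s.season, float(t))
        for s in samples.values()
        for t in s.times
    ]
    return pd.DataFrame(rows, columns=["species", "season", "solar_radians"])


def transform_events(table, latitude: float, longitude: float,
                     utc_offset: float) -> dict[tuple[str, str], SolarSample]:
    """Convert an event table into solar-radian samples keyed by (species, season).

    Every event contributes to exactly one sample, so the sample sizes sum to
    the number of events.  Requires seasons to have been assigned.
    """
    from .detections import EVENT_TIME, SEASON, SPECIES  # avoid cycle at import

    events = table.events
    if SEASON not in events.columns:
        raise ValueError("events must carry a season label; run assign_season first")
    clock = SolarClock(latitude, longitude, utc_offset)
    samples: dict[tuple[str, str], SolarSample] = {}
    for (species, season), group in events.groupby([SPECIES, SEASON], sort=True):
        times = np.array([clock.to_solar(t.to_pydatetime())
                          for t in group[EVENT_TIME]])
        samples[(species, season)] = SolarSample(species, season, times)
    return samples
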