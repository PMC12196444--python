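"""Synthetic daily weather for a subtropical monsoon rice site.

The generator emulates the climate normals of the Sichuan-Basin study area
(annual mean ~17 degC, ~950 mm rain concentrated in summer/autumn, ~1250
sunshine hours) with a sinusoidal annual temperature cycle plus AR(1)
anomalies, a two-state (wet/dry) rainfall occurrence process with
gamma-distributed wet-day amounts weighted by month, and sunshine
anti-correlated with rain. Solar radiation is derived from sunshine hours
with the Angstrom-Prescott relation applied to FAO-56 extraterrestrial
radiation.

Everything is deterministic for a fixed seed; no real station data is used
or downloadable here by design.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "WeatherDay",
    "ClimateSpec",
    "generate_season_weather",
    "solar_radiation_from_sunshine",
    "extraterrestrial_radiation",
    "daylength",
    "read_weather_csv",
    "write_weather_csv",
    "climate_2018_like",
    "climate_2019_like",
    "SEASON_2018",
    "SEASON_2019",
]

#: transplant/harvest windows of the two field seasons
SEASON_2018 = (dt.date(2018, 5, 30), dt.date(2018, 9, 16))
SEASON_2019 = (dt.date(2019, 6, 2), dt.date(2019, 9, 20))

_SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1
_ANGSTROM_A = 0.25
_ANGSTROM_B = 0.50

# monthly share of annual rainfall, Jan..Dec (summer/autumn heavy)
_DEFAULT_RAIN_WEIGHTS = (
    0.015, 0.020, 0.040, 0.065, 0.100, 0.135,
    0.185, 0.170, 0.125, 0.080, 0.040, 0.025,
)


@dataclass(frozen=True)
class WeatherDay:
    """One day of meteorological forcing."""

    date: dt.date
    tmean: float        # degC
    tmax: float         # degC
    tmin: float         # degC
    prec_mm: float      # mm
    rh: float           # %, daily mean relative humidity
    wind_ms: float      # m s-1 at 2 m
    sunshine_h: float   # h
    solar_mj: float     # MJ m-2 d-1, derived from sunshine hours

    def validate(self) -> list[str]:
        v = []
        if not (self.tmin <= self.tmean <= self.tmax):
            v.append(f"{self.date}: requires tmin <= tmean <= tmax")
        if self.prec_mm < 0:
            v.append(f"{self.date}: negative precipitation")
        if not (0 <= self.rh <= 100):
            v.append(f"{self.date}: RH outside [0, 100]")
        if self.sunshine_h < 0:
            v.append(f"{self.date}: negative sunshine hours")
        if self.wind_ms < 0:
            v.append(f"{self.date}: negative wind speed")
        return v


@dataclass(frozen=True)
class ClimateSpec:
    """Climate normals and noise structure of the synthesis procedure."""

    latitude: float = 30.1            # deg N
    elevation: float = 400.0          # m
    annual_mean_temp: float = 17.0    # degC
    annual_rainfall: float = 950.0    # mm
    annual_sunshine: float = 1250.0   # h
    monthly_rain_weights: tuple = _DEFAULT_RAIN_WEIGHTS
    temp_amplitude: float = 9.5       # degC, half peak-to-trough of the annual cycle
    temp_noise_sd: float = 1.5        # degC, stationary sd of the AR(1) anomaly
    temp_ar1: float = 0.7             # day-to-day anomaly persistence
    diurnal_range_dry: float = 8.0    # degC
    diurnal_range_wet: float = 5.0    # degC
    rain_gamma_shape: float = 0.7     # wet-day amount shape
    sunshine_frac_dry: float = 0.36   # mean n/N on dry days
    sunshine_frac_wet: float = 0.12   # mean n/N on wet days
    sunshine_noise_sd: float = 0.12   # sd of the n/N perturbation
    rh_dry: float = 72.0              # % on dry days
    rh_wet: float = 88.0              # % on wet days
    rh_noise_sd: float = 4.0
    wind_mean: float = 1.5            # m s-1
    wind_lognorm_sd: float = 0.4
    et_scale: float = 1.0             # season ET0 multiplier (preset calibration)
    seed: int = 0

    def validate(self) -> list[str]:
        v = []
        for name in ("annual_mean_temp",):
            pass
        if self.annual_rainfall < 0:
            v.append("annual_rainfall must be >= 0")
        if self.annual_sunshine <= 0:
            v.append("annual_sunshine must be > 0")
        if any(w < 0 for w in self.monthly_rain_weights):
            v.append("monthly_rain_weights must be non-negative")
        if len(self.monthly_rain_weights) != 12:
            v.append("monthly_rain_weights must have 12 entries")
        if self.temp_noise_sd < 0 or self.sunshine_noise_sd < 0 or self.rh_noise_sd < 0:
            v.append("noise scales must be >= 0")
        if not (0 <= self.temp_ar1 < 1):
            v.append("temp_ar1 must be in [0, 1)")
        if self.et_scale <= 0:
            v.append("et_scale must be > 0")
        return v


def climate_2018_like() -> ClimateSpec:
    """Preset for the first field season (seasonal crop ET ~350 mm)."""
    return ClimateSpec(seed=2018, et_scale=0.88)


def climate_2019_like() -> ClimateSpec:
    """Preset for the second field season (seasonal crop ET ~310 mm); the
    scenario grid runs on this preset."""
    return ClimateSpec(seed=2019, et_scale=0.78)


def daylength(latitude: float, day_of_year: int) -> float:
    """Astronomical daylength N (h) after FAO-56."""
    phi = math.radians(latitude)
    delta = 0.409 * math.sin(2 * math.pi * day_of_year / 365 - 1.39)
    x = -math.tan(phi) * math.tan(delta)
    x = min(1.0, max(-1.0, x))
    omega_s = math.acos(x)
    return 24.0 / math.pi * omega_s


def extraterrestrial_radiation(latitude: float, day_of_year: int) -> float:
    """Daily extraterrestrial radiation Ra (MJ m-2 d-1) after FAO-56."""
    phi = math.radians(latitude)
    dr = 1 + 0.033 * math.cos(2 * math.pi * day_of_year / 365)
    delta = 0.409 * math.sin(2 * math.pi * day_of_year / 365 - 1.39)
    x = -math.tan(phi) * math.tan(delta)
    x = min(1.0, max(-1.0, x))
    omega_s = math.acos(x)
    return (24 * 60 / math.pi) * _SOLAR_CONSTANT * dr * (
        omega_s * math.sin(phi) * math.sin(delta)
        + math.cos(phi) * math.cos(delta) * math.sin(omega_s)
    )


def solar_radiation_from_sunshine(sunshine_hours: float, latitude: float,
                                  day_of_year: int) -> float:
    """Angstrom-Prescott global radiation (a=0.25, b=0.50) from sunshine hours.

    Output is bounded between a*Ra (fully overcast) and (a+b)*Ra (clear).
    """
    if not (-66.0 < latitude < 66.0):
        raise ValueError(f"latitude {latitude} outside (-66, 66)")
    n_max = daylength(latitude, day_of_year)
    if sunshine_hours < 0:
        raise ValueError("sunshine_hours must be >= 0")
    if sunshine_hours > n_max + 1e-9:
        raise ValueError(
            f"sunshine_hours {sunshine_hours} exceeds daylength {n_max:.3f}"
        )
    ra = extraterrestrial_radiation(latitude, day_of_year)
    frac = min(sunshine_hours, n_max) / n_max
    return (_ANGSTROM_A + _ANGSTROM_B * frac) * ra


def _days_in_month(year: int, month: int) -> int:
    nxt = dt.date(year + month // 12, month % 12 + 1, 1)
    return (nxt - dt.date(year, month, 1)).days


def generate_season_weather(spec: ClimateSpec, start_date: dt.date,
                            n_days: int) -> list[WeatherDay]:
    """Generate a deterministic daily weather series for a fixed seed.

    Temperature follows a sinusoid (warmest mid-July) around the annual
    mean plus an AR(1) anomaly; rainfall occurrence is a monthly-weighted
    two-state process with gamma wet-day amounts whose expectation matches
    the monthly share of the annual total; sunshine is anti-correlated with
    wet days.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    problems = spec.validate()
    if problems:
        raise ValueError("invalid ClimateSpec: " + "; ".join(problems))

    wsum = sum(spec.monthly_rain_weights)
    weights = (tuple(w / wsum for w in spec.monthly_rain_weights)
               if wsum > 0 else (0.0,) * 12)

    rng = np.random.default_rng(spec.seed)
    days: list[WeatherDay] = []
    anomaly = 0.0
    innovation_sd = spec.temp_noise_sd * math.sqrt(1 - spec.temp_ar1 ** 2)
    for i in range(n_days):
        date = start_date + dt.timedelta(days=i)
        doy = date.timetuple().tm_yday
        # fixed number of draws per day keeps the stream layout stable
        z_temp, u_wet, z_rh, z_sun, z_wind = rng.standard_normal(5)
        u_wet = 0.5 * (1 + math.erf(u_wet / math.sqrt(2)))  # to uniform

        t_clim = spec.annual_mean_temp + spec.temp_amplitude * math.cos(
            2 * math.pi * (doy - 196) / 365.25
        )
        anomaly = spec.temp_ar1 * anomaly + innovation_sd * z_temp
        tmean = t_clim + anomaly

        w_m = weights[date.month - 1]
        p_wet = min(0.6, 3.0 * w_m)
        wet = u_wet < p_wet
        if wet:
            target = spec.annual_rainfall * w_m / _days_in_month(date.year, date.month)
            mean_amount = target / p_wet
            prec = float(rng.gamma(spec.rain_gamma_shape,
                                   mean_amount / spec.rain_gamma_shape))
        else:
            prec = 0.0

        half_range = (spec.diurnal_range_wet if wet else spec.diurnal_range_dry) / 2
        tmax = tmean + half_range
        tmin = tmean - half_range

        rh = (spec.rh_wet if wet else spec.rh_dry) + spec.rh_noise_sd * z_rh
        rh = min(100.0, max(20.0, rh))

        n_max = daylength(spec.latitude, doy)
        base_frac = spec.sunshine_frac_wet if wet else spec.sunshine_frac_dry
        # scale toward the annual sunshine target
        frac_scale = spec.annual_sunshine / 1250.0
        frac = base_frac * frac_scale + spec.sunshine_noise_sd * z_sun
        frac = min(1.0, max(0.0, frac))
        sunshine = frac * n_max

        wind = spec.wind_mean * math.exp(spec.wind_lognorm_sd * z_wind
                                         - spec.wind_lognorm_sd ** 2 / 2)
        wind = min(10.0, max(0.2, wind))

        days.append(WeatherDay(
            date=date, tmean=tmean, tmax=tmax, tmin=tmin, prec_mm=prec,
            rh=rh, wind_ms=wind, sunshine_h=sunshine,
            solar_mj=solar_radiation_from_sunshine(sunshine, spec.latitude, doy),
        ))
    return days


_CSV_HEADER = "date,tmean,tmax,tmin,prec_mm,rh,wind_ms,sunshine_h"


def write_weather_csv(path: str | Path, days: list[WeatherDay]) -> None:
    """Write a weather series to CSV (6 significant digits)."""
    lines = [_CSV_HEADER]
    for d in days:
        lines.append(",".join([d.date.isoformat()] + [
            f"{x:.6g}" for x in (d.tmean, d.tmax, d.tmin, d.prec_mm,
                                 d.rh, d.wind_ms, d.sunshine_h)
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_weather_csv(path: str | Path, latitude: float = 30.1) -> list[WeatherDay]:
    """Read a weather CSV, re-deriving solar radiation from sunshine hours.

    Invalid rows are collected and reported together with their 1-based
    line numbers in a single ValueError.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].strip() != _CSV_HEADER:
        raise ValueError(f"expected header '{_CSV_HEADER}'")
    days: list[WeatherDay] = []
    errors: list[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        if len(parts) != 8:
            errors.append(f"line {lineno}: expected 8 fields, got {len(parts)}")
            continue
        try:
            date = dt.date.fromisoformat(parts[0])
            tmean, tmax, tmin, prec, rh, wind, sun = map(float, parts[1:])
        except ValueError as exc:
            errors.append(f"line {lineno}: {exc}")
            continue
        day = WeatherDay(
            date=date, tmean=tmean, tmax=tmax, tmin=tmin, prec_mm=prec,
            rh=rh, wind_ms=wind, sunshine_h=sun,
            solar_mj=0.0,
        )
        problems = day.validate()
        if problems:
            errors.extend(f"line {lineno}: {p}" for p in problems)
            continue
        doy = date.timetuple().tm_yday
        days.append(replace(day, solar_mj=solar_radiation_from_sunshine(
            min(sun, daylength(latitude, doy)), latitude, doy)))
    if errors:
        raise ValueError("invalid weather rows: " + "; ".join(errors))
    return days
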