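"""Paddy water balance: ponding layer over a three-layer soil bucket.

A permanently ponded rice field is represented by a surface ponding store
(kept inside a 0-50 mm management band by irrigation until field drainage
two weeks before harvest) over three soil layers (0-20, 20-40, 40-80 cm)
treated as tipping buckets. Saturated Darcy flow reduces to a
conductivity-limited flux at unit gradient, so percolation through each
interface is capped by the saturated conductivity of the receiving layer.

The daily update order is fixed:

1. rain enters the ponding store;
2. crop ET (Kc * ET0, FAO-56 Penman-Monteith) is removed from ponding
   first, then from the soil layers down to wilting point;
3. ponding infiltrates into layer 1 at min(Ks1, available, pore space),
   then water cascades layer-to-layer at min(Ks, excess over field
   capacity, receiving pore space); outflow from layer 3 is deep
   percolation;
4. ponding above the bund height spills as surface runoff;
5. while the irrigation policy is active, a ponding store at (or below)
   the bottom of the band is refilled to the top of the band.

Each step closes its water mass balance to <= 1e-9 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .params import LAYER_THICKNESS_CM, ParameterSet, SimulationConfig
from .weather import WeatherDay, extraterrestrial_radiation

__all__ = [
    "SoilWaterState",
    "initial_water_state",
    "reference_et",
    "crop_coefficient",
    "daily_water_step",
]

_STEFAN_BOLTZMANN = 4.903e-9  # MJ K-4 m-2 d-1


@dataclass
class SoilWaterState:
    """Ponding depth, per-layer water content, and cumulative fluxes."""

    theta: list[float]          # cm3 cm-3, one per layer
    ponding_mm: float = 0.0
    cum_irrigation: float = 0.0  # mm
    cum_percolation: float = 0.0
    cum_runoff: float = 0.0
    cum_et: float = 0.0

    def storage_mm(self) -> float:
        return self.ponding_mm + sum(
            th * thick * 10.0 for th, thick in zip(self.theta, LAYER_THICKNESS_CM)
        )

    def wfps(self, params: ParameterSet, layer: int = 0) -> float:
        """Water-filled pore space of a layer (porosity identified with theta_s)."""
        return self.theta[layer] / params.theta_s_by_layer[layer]


def initial_water_state(params: ParameterSet,
                        ponding_mm: float = 50.0) -> SoilWaterState:
    """Start-of-season state: field flooded for transplanting, profile saturated."""
    return SoilWaterState(theta=list(params.theta_s_by_layer),
                          ponding_mm=ponding_mm)


def _sat_vapour_pressure(t: float) -> float:
    """kPa, FAO-56 eq. for saturation vapour pressure."""
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def reference_et(day: WeatherDay, latitude: float, elevation: float) -> float:
    """FAO-56 Penman-Monteith grass reference ET0 (mm d-1).

    Missing humidity falls back to dewpoint ~ Tmin; missing wind falls back
    to 2 m s-1. The clear-sky ratio is clamped to [0.05, 1] and net
    longwave loss to >= 0 before the combination equation; the result is
    clamped at zero.
    """
    tmean = (day.tmax + day.tmin) / 2.0
    delta = 4098 * _sat_vapour_pressure(tmean) / (tmean + 237.3) ** 2
    pressure = 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26
    gamma = 0.000665 * pressure
    es = (_sat_vapour_pressure(day.tmax) + _sat_vapour_pressure(day.tmin)) / 2.0
    rh = day.rh
    ea = _sat_vapour_pressure(day.tmin) if rh is None else es * rh / 100.0
    ea = min(ea, es)
    wind = 2.0 if day.wind_ms is None else day.wind_ms

    doy = day.date.timetuple().tm_yday
    ra = extraterrestrial_radiation(latitude, doy)
    rs = day.solar_mj
    rso = (0.75 + 2e-5 * elevation) * ra
    ratio = min(1.0, max(0.05, rs / rso)) if rso > 0 else 0.05
    rns = (1 - 0.23) * rs
    tk4 = ((day.tmax + 273.16) ** 4 + (day.tmin + 273.16) ** 4) / 2.0
    rnl = _STEFAN_BOLTZMANN * tk4 * (0.34 - 0.14 * math.sqrt(ea)) \
        * (1.35 * ratio - 0.35)
    rnl = max(0.0, rnl)
    rn = rns - rnl

    num = 0.408 * delta * rn + gamma * (900.0 / (tmean + 273.0)) * wind * (es - ea)
    et0 = num / (delta + gamma * (1 + 0.34 * wind))
    return max(0.0, et0)


def crop_coefficient(stage_fraction: float, params: ParameterSet) -> float:
    """Piecewise-linear FAO-style Kc curve over the thermal-time fraction.

    Plateau at K_ini for the first 25% of thermal time, linear rise to
    K_mid by 45%, plateau to 75%, then linear fall to K_end at maturity.
    """
    s = stage_fraction
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"stage_fraction {s} outside [0, 1]")
    if s <= 0.25:
        return params.K_ini
    if s <= 0.45:
        return params.K_ini + (params.K_mid - params.K_ini) * (s - 0.25) / 0.20
    if s <= 0.75:
        return params.K_mid
    return params.K_mid + (params.K_end - params.K_mid) * (s - 0.75) / 0.25


def daily_water_step(state: SoilWaterState, day: WeatherDay, kc: float,
                     config: SimulationConfig, params: ParameterSet,
                     irrigating: bool = True,
                     et0: float | None = None) -> tuple[SoilWaterState, dict]:
    """Advance the water state one day; return (new state, daily fluxes).

    ``irrigating`` is False after the drainage date, letting the pond fall
    to zero. ``et0`` may be injected (tests, ET scaling); otherwise it is
    computed from the day's weather.
    """
    if et0 is None:
        et0 = reference_et(day, config.latitude, config.elevation)
    etc = kc * et0

    theta = list(state.theta)
    thick_mm = [t * 10.0 for t in LAYER_THICKNESS_CM]
    ks_mm = [k * 10.0 for k in params.Ks_by_layer]
    start_storage = state.storage_mm()

    pond = state.ponding_mm + day.prec_mm

    # evapotranspiration: ponding first, then soil down to WP
    et_pond = min(pond, etc)
    pond -= et_pond
    et_rem = etc - et_pond
    et_soil = 0.0
    for i in range(3):
        if et_rem <= 0:
            break
        avail = max(0.0, (theta[i] - params.WP_by_layer[i]) * thick_mm[i])
        take = min(avail, et_rem)
        theta[i] -= take / thick_mm[i]
        et_soil += take
        et_rem -= take
    et_actual = et_pond + et_soil

    # infiltration and layer cascade
    space1 = max(0.0, (params.theta_s_by_layer[0] - theta[0]) * thick_mm[0])
    f01 = min(ks_mm[0], pond, space1)
    pond -= f01
    theta[0] += f01 / thick_mm[0]

    space2 = max(0.0, (params.theta_s_by_layer[1] - theta[1]) * thick_mm[1])
    f12 = min(ks_mm[1], max(0.0, (theta[0] - params.FC_by_layer[0]) * thick_mm[0]),
              space2)
    theta[0] -= f12 / thick_mm[0]
    theta[1] += f12 / thick_mm[1]

    space3 = max(0.0, (params.theta_s_by_layer[2] - theta[2]) * thick_mm[2])
    f23 = min(ks_mm[2], max(0.0, (theta[1] - params.FC_by_layer[1]) * thick_mm[1]),
              space3)
    theta[1] -= f23 / thick_mm[1]
    theta[2] += f23 / thick_mm[2]

    perc_out = min(ks_mm[2], max(0.0, (theta[2] - params.FC_by_layer[2]) * thick_mm[2]))
    theta[2] -= perc_out / thick_mm[2]

    # bund overflow
    runoff = max(0.0, pond - config.bund_height_mm)
    pond -= runoff

    # irrigation: refill to the top of the band when the pond hits bottom
    irrigation = 0.0
    if irrigating and pond <= config.ponding_min_mm + 1e-12:
        irrigation = config.ponding_max_mm - pond
        pond += irrigation

    new_state = SoilWaterState(
        theta=theta,
        ponding_mm=pond,
        cum_irrigation=state.cum_irrigation + irrigation,
        cum_percolation=state.cum_percolation + perc_out,
        cum_runoff=state.cum_runoff + runoff,
        cum_et=state.cum_et + et_actual,
    )
    residual = (day.prec_mm + irrigation) - (et_actual + perc_out + runoff) \
        - (new_state.storage_mm() - start_storage)
    if abs(residual) > 1e-9:
        raise AssertionError(f"water balance residual {residual} mm on {day.date}")

    fluxes = {
        "rain": day.prec_mm,
        "et0": et0,
        "et": et_actual,
        "et_pond": et_pond,
        "irrigation": irrigation,
        "infiltration": f01,
        "f12": f12,
        "f23": f23,
        "percolation": perc_out,
        "runoff": runoff,
        "ponding_mm": pond,
        "residual_mm": residual,
    }
    return new_state, fluxes
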