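"""Daily nitrogen cycling in a ponded paddy.

State is carried as bulk concentrations (ug cm-3, numerically equal to
mg L-1 of bulk soil volume) for urea-N, NH4-N and NO3-N in three soil
layers, plus mass pools (kg N ha-1) in the floodwater. Unit bridges:

* 1 ug cm-3 over a layer of thickness d cm  ->  0.1 * d kg N ha-1
* 1 mg N L-1 over 1 mm of ponded water     ->  0.01 kg N ha-1

Processes, in the fixed daily order applied by :func:`daily_nitrogen_step`:

1.  fertilization (urea broadcast into the floodwater when ponded,
    otherwise into the top soil layer; two sub-pools track urea applied
    with and without the urease inhibitor, which differ in Kh);
2.  urea hydrolysis, ``N_urea * (1 - exp(-5 * WFPS * Kh))``, in the
    floodwater (WFPS = 1) and in each soil layer; straw return stimulates
    urease activity as a linear multiplier on Kh;
3.  straw decomposition (fast/slow C pools with microbial immobilization
    and re-release) and background soil organic-matter mineralization with
    a straw priming multiplier, both into layer-1 NH4;
4.  floodwater-soil mineral N mixing, first-order toward the layer-1
    soil-solution concentration;
5.  NH3 volatilization from the floodwater,
    ``Kv * Cp * f(T) * ammonia_fraction(T, pH)`` with
    ``f(T) = 0.25 * exp(0.0693 * T)``, converted to an areal flux by the
    ponding depth; zero when the field is drained;
6.  nitrification (Michaelis-Menten in NH4, suppressed near saturation);
7.  denitrification, ``min(Ad * resp_C, Kd * NO3) * f_wd(WFPS)``;
8.  advective solute transport with the day's water fluxes (floodwater ->
    layer 1 -> 2 -> 3 -> leaching); NH4 moves with a mobility factor to
    represent adsorption;
9.  runoff N at the floodwater mineral concentration.

Every flux is pool-limited; a per-day mass-balance audit closes to 1e-9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .params import LAYER_THICKNESS_CM, ParameterSet

__all__ = [
    "NitrogenPools",
    "StrawPools",
    "FertilizerEvent",
    "initial_nitrogen_pools",
    "urea_hydrolysis_rate",
    "ammonia_fraction",
    "nh3_volatilization",
    "nitrification_rate",
    "denitrification_rate",
    "straw_decomposition_step",
    "daily_nitrogen_step",
    "conc_to_kgha",
    "kgha_to_conc",
]


def conc_to_kgha(conc: float, thickness_cm: float) -> float:
    """Bulk concentration (ug cm-3) to areal mass (kg N ha-1)."""
    return conc * thickness_cm * 0.1


def kgha_to_conc(mass: float, thickness_cm: float) -> float:
    return mass / (thickness_cm * 0.1)


@dataclass
class NitrogenPools:
    """All mineral/urea N pools plus cumulative loss accounts."""

    urea_std: list[float]      # ug cm-3 per layer, plain urea
    urea_ui: list[float]       # ug cm-3 per layer, urea applied with UI
    nh4: list[float]           # ug cm-3 per layer
    no3: list[float]           # ug cm-3 per layer
    pond_mineral: float = 0.0  # kg N ha-1 in the floodwater
    pond_urea_std: float = 0.0
    pond_urea_ui: float = 0.0
    cum_nh3: float = 0.0       # kg N ha-1, cumulative losses
    cum_denit: float = 0.0
    cum_leach: float = 0.0
    cum_runoff_n: float = 0.0
    cum_humus_min: float = 0.0  # cumulative external SOM-N input
    cum_hydrolysis: float = 0.0
    cum_net_min: float = 0.0

    def cp(self, ponding_mm: float) -> float:
        """Floodwater mineral N concentration (mg N L-1); 0 when drained."""
        if ponding_mm <= 0:
            return 0.0
        return self.pond_mineral / (ponding_mm * 0.01)

    def soil_inventory(self) -> float:
        """kg N ha-1 in soil urea + mineral pools."""
        total = 0.0
        for i, thick in enumerate(LAYER_THICKNESS_CM):
            total += conc_to_kgha(
                self.urea_std[i] + self.urea_ui[i] + self.nh4[i] + self.no3[i],
                thick)
        return total

    def inventory(self) -> float:
        """kg N ha-1 in all tracked urea/mineral pools (soil + floodwater)."""
        return (self.soil_inventory() + self.pond_mineral
                + self.pond_urea_std + self.pond_urea_ui)


@dataclass
class StrawPools:
    """Returned-straw organic matter: fast/slow C, straw N, microbial N."""

    c_fast: float = 0.0       # kg C ha-1
    c_slow: float = 0.0       # kg C ha-1
    organic_n: float = 0.0    # kg N ha-1 still bound in straw
    microbial_n: float = 0.0  # kg N ha-1 immobilized in microbial biomass

    @classmethod
    def from_straw(cls, straw_t_ha: float, params: ParameterSet) -> "StrawPools":
        """Initialize from a straw return amount (t DM ha-1)."""
        if straw_t_ha < 0:
            raise ValueError("straw amount must be >= 0")
        c_total = straw_t_ha * 1000.0 * params.straw_c_content
        return cls(
            c_fast=c_total * params.straw_fast_fraction,
            c_slow=c_total * (1.0 - params.straw_fast_fraction),
            organic_n=straw_t_ha * 1000.0 * params.straw_n_content,
        )

    def total_n(self) -> float:
        return self.organic_n + self.microbial_n


@dataclass(frozen=True)
class FertilizerEvent:
    """One fertilization: urea N amount and whether the UI is mixed in."""

    amount_kg_n: float
    ui: bool = False
    kind: str = "urea"
    label: str = ""


def initial_nitrogen_pools(params: ParameterSet) -> NitrogenPools:
    return NitrogenPools(
        urea_std=[0.0, 0.0, 0.0],
        urea_ui=[0.0, 0.0, 0.0],
        nh4=list(params.init_nh4_by_layer),
        no3=list(params.init_no3_by_layer),
    )


def urea_hydrolysis_rate(n_urea: float, wfps: float, kh: float) -> float:
    """Urea hydrolysis rate (ug cm-3 d-1): N_urea * (1 - exp(-5 * WFPS * Kh)).

    WFPS is a fraction in [0, 1]; Kh in d-1. The rate never exceeds the
    urea pool and increases in every argument.
    """
    if n_urea < 0 or kh < 0 or wfps < 0:
        raise ValueError("inputs must be >= 0")
    if wfps > 1.0 + 1e-12:
        raise ValueError(f"WFPS {wfps} > 1: expected a fraction, not percent")
    return n_urea * (1.0 - math.exp(-5.0 * min(wfps, 1.0) * kh))


def ammonia_fraction(t: float, ph: float) -> float:
    """Fraction of floodwater mineral N present as volatile NH3(aq).

    Logistic in pH around the temperature-dependent
    pKa = 0.09018 + 2729.92 / (T + 273.15); equals 1/2 at pH = pKa and
    increases with both temperature and pH.
    """
    if t <= -273.15:
        raise ValueError("temperature below absolute zero")
    pka = 0.09018 + 2729.92 / (t + 273.15)
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


def temperature_function(t: float) -> float:
    """Empirical volatilization temperature factor f(T) = 0.25 * exp(0.0693 T)."""
    return 0.25 * math.exp(0.0693 * t)


def nh3_volatilization(params: ParameterSet, cp: float, t: float, ph: float,
                       ponding_mm: float,
                       pond_mineral_kgha: float | None = None) -> float:
    """Daily NH3-N flux (kg N ha-1 d-1) from the floodwater.

    Nv = Kv * Cp * f(T) * ammonia_fraction(T, pH) in mg N L-1 d-1,
    converted with depth (1 mg L-1 over 1 mm = 0.01 kg ha-1) and capped at
    the floodwater mineral N mass. Zero when the field is drained.
    """
    if cp < 0 or ponding_mm < 0:
        raise ValueError("Cp and ponding depth must be >= 0")
    if ponding_mm == 0:
        return 0.0
    rate_conc = params.Kv * cp * temperature_function(t) * ammonia_fraction(t, ph)
    flux = rate_conc * ponding_mm * 0.01
    cap = cp * ponding_mm * 0.01 if pond_mineral_kgha is None else pond_mineral_kgha
    return min(flux, cap)


def _nitrif_moisture_factor(wfps: float) -> float:
    """1 up to WFPS 0.6, declining linearly to 0.1 at saturation (anoxia)."""
    if wfps <= 0.6:
        return 1.0
    return 1.0 - 0.9 * min(1.0, (wfps - 0.6) / 0.4)


def nitrification_rate(nh4: float, params: ParameterSet, wfps: float) -> float:
    """Michaelis-Menten nitrification (ug cm-3 d-1), moisture-limited.

    Vn * NH4 / (Kn + NH4) * f_w(WFPS), bounded by the NH4 pool.
    """
    if nh4 < 0 or wfps < 0:
        raise ValueError("inputs must be >= 0")
    if nh4 == 0:
        return 0.0
    rate = params.Vn * nh4 / (params.Kn + nh4) * _nitrif_moisture_factor(wfps)
    return min(rate, nh4)


def _denit_moisture_factor(wfps: float) -> float:
    """0 below WFPS 0.7, rising linearly to 1 at saturation."""
    if wfps <= 0.7:
        return 0.0
    return min(1.0, (wfps - 0.7) / 0.3)


def denitrification_rate(no3: float, resp_c: float, params: ParameterSet,
                         wfps: float, thickness_cm: float = 20.0) -> float:
    """Daily denitrification (kg N ha-1 d-1) of a layer.

    min(Ad * resp_C, Kd * NO3 areal mass) * f_wd(WFPS): carbon-limited or
    nitrate-limited, active only in the near-saturated range; bounded by
    the NO3 pool.
    """
    if no3 < 0 or resp_c < 0 or wfps < 0:
        raise ValueError("inputs must be >= 0")
    no3_areal = conc_to_kgha(no3, thickness_cm)
    rate = min(params.Ad * resp_c, params.Kd * no3_areal)
    rate *= _denit_moisture_factor(wfps)
    return min(rate, no3_areal)


def _turnover_factors(tmean: float, wfps: float, params: ParameterSet) -> float:
    """Q10 temperature factor times a wet-suppression moisture factor.

    Decomposition is optimal up to WFPS 0.6 and is halved at saturation
    (anaerobic slowdown under ponding).
    """
    ft = params.q10 ** ((tmean - params.q10_ref_temp) / 10.0)
    if wfps <= 0.6:
        fw = 1.0
    else:
        fw = 1.0 - 0.5 * min(1.0, (wfps - 0.6) / 0.4)
    return ft * fw


def straw_decomposition_step(pools: StrawPools, tmean: float, wfps: float,
                             params: ParameterSet
                             ) -> tuple[float, float, StrawPools]:
    """One day of straw turnover: (respired C, net mineral N, new pools).

    First-order decay of the fast and slow C pools (Q10 temperature and
    moisture factors); decomposed C is split by the assimilation
    efficiency E into microbial growth (demanding N at the microbial C:N)
    and respired C. Straw N is released in proportion to the C decomposed;
    immobilized N re-mineralizes at the microbial turnover rate.
    net_mineral_N = release + microbial re-release - microbial demand
    (negative means immobilization; the caller floors it at the available
    soil mineral N and shrinks the microbial gain accordingly).
    """
    c_total = pools.c_fast + pools.c_slow
    if c_total <= 0 and pools.microbial_n <= 0:
        return 0.0, 0.0, replace(pools)
    f = _turnover_factors(tmean, wfps, params)
    d_fast = pools.c_fast * min(1.0, params.straw_k_fast * f)
    d_slow = pools.c_slow * min(1.0, params.straw_k_slow * f)
    decomposed = d_fast + d_slow

    release = decomposed * (pools.organic_n / c_total) if c_total > 0 else 0.0
    assimilated = params.assimilation_efficiency * decomposed
    demand = assimilated / params.microbial_cn
    resp_c = (1.0 - params.assimilation_efficiency) * decomposed
    m_release = pools.microbial_n * min(1.0, params.microbial_n_turnover * f)

    net_mineral = release + m_release - demand
    new = StrawPools(
        c_fast=pools.c_fast - d_fast,
        c_slow=pools.c_slow - d_slow,
        organic_n=pools.organic_n - release,
        microbial_n=pools.microbial_n - m_release + demand,
    )
    return resp_c, net_mineral, new


def _clamp0(x: float) -> float:
    """Zero out float-noise negatives; anything materially negative is a bug."""
    if x < 0:
        if x < -1e-9:
            raise AssertionError(f"pool went negative: {x}")
        return 0.0
    return x


def _sanitize(p: "NitrogenPools") -> None:
    for arr in (p.urea_std, p.urea_ui, p.nh4, p.no3):
        for i in range(3):
            arr[i] = _clamp0(arr[i])
    p.pond_mineral = _clamp0(p.pond_mineral)
    p.pond_urea_std = _clamp0(p.pond_urea_std)
    p.pond_urea_ui = _clamp0(p.pond_urea_ui)


def daily_nitrogen_step(pools: NitrogenPools, straw: StrawPools,
                        water_fluxes: dict, theta_end: list[float],
                        tmean: float, events: list[FertilizerEvent],
                        params: ParameterSet,
                        straw_return_t_ha: float = 0.0,
                        ) -> tuple[NitrogenPools, StrawPools, dict]:
    """Advance all N pools one day (order documented in the module header).

    ``water_fluxes`` is the dict returned by
    :func:`paddynsim.water.daily_water_step`; ``theta_end`` the end-of-day
    water contents used for WFPS.
    """
    p = NitrogenPools(
        urea_std=list(pools.urea_std), urea_ui=list(pools.urea_ui),
        nh4=list(pools.nh4), no3=list(pools.no3),
        pond_mineral=pools.pond_mineral,
        pond_urea_std=pools.pond_urea_std, pond_urea_ui=pools.pond_urea_ui,
        cum_nh3=pools.cum_nh3, cum_denit=pools.cum_denit,
        cum_leach=pools.cum_leach, cum_runoff_n=pools.cum_runoff_n,
        cum_humus_min=pools.cum_humus_min,
        cum_hydrolysis=pools.cum_hydrolysis, cum_net_min=pools.cum_net_min,
    )
    s = straw
    thick = LAYER_THICKNESS_CM
    pond_mm = water_fluxes["ponding_mm"]
    wfps = [theta_end[i] / params.theta_s_by_layer[i] for i in range(3)]
    wfps = [min(1.0, w) for w in wfps]
    start_n = p.inventory() + s.total_n()

    fert_in = 0.0
    # 1. fertilization
    for ev in events:
        if ev.kind != "urea":
            raise ValueError(f"unknown fertilizer kind: {ev.kind!r}")
        if ev.amount_kg_n < 0:
            raise ValueError("fertilizer amount must be >= 0")
        fert_in += ev.amount_kg_n
        if pond_mm > 0:
            if ev.ui:
                p.pond_urea_ui += ev.amount_kg_n
            else:
                p.pond_urea_std += ev.amount_kg_n
        else:
            conc = kgha_to_conc(ev.amount_kg_n, thick[0])
            if ev.ui:
                p.urea_ui[0] += conc
            else:
                p.urea_std[0] += conc

    # 2. hydrolysis (straw stimulates urease activity)
    kh_mult = 1.0 + params.urease_stim_per_t_straw * straw_return_t_ha
    hydrolyzed = 0.0
    if pond_mm > 0:
        for attr, kh in (("pond_urea_std", params.Kh),
                         ("pond_urea_ui", params.Kh_UI)):
            pool = getattr(p, attr)
            hyd = pool * (1.0 - math.exp(-5.0 * 1.0 * kh * kh_mult))
            setattr(p, attr, pool - hyd)
            p.pond_mineral += hyd
            hydrolyzed += hyd
    for i in range(3):
        for arr, kh in ((p.urea_std, params.Kh), (p.urea_ui, params.Kh_UI)):
            hyd = urea_hydrolysis_rate(arr[i], wfps[i], kh * kh_mult)
            arr[i] -= hyd
            p.nh4[i] += hyd
            hydrolyzed += conc_to_kgha(hyd, thick[i])
    p.cum_hydrolysis += hydrolyzed

    # 3. straw decomposition + background SOM mineralization (layer 1)
    resp_c, net_min, s = straw_decomposition_step(s, tmean, wfps[0], params)
    if net_min >= 0:
        p.nh4[0] += kgha_to_conc(net_min, thick[0])
    else:
        need = -net_min
        avail_nh4 = conc_to_kgha(p.nh4[0], thick[0])
        avail_no3 = conc_to_kgha(p.no3[0], thick[0])
        take_nh4 = min(need, avail_nh4)
        take_no3 = min(need - take_nh4, avail_no3)
        shortfall = need - take_nh4 - take_no3
        p.nh4[0] -= kgha_to_conc(take_nh4, thick[0])
        p.no3[0] -= kgha_to_conc(take_no3, thick[0])
        if shortfall > 0:
            # microbes get less N than demanded
            s = replace(s, microbial_n=s.microbial_n - shortfall)
        net_min = -(take_nh4 + take_no3)
    p.cum_net_min += net_min

    ftfw = _turnover_factors(tmean, wfps[0], params)
    priming = 1.0 + params.priming_per_t_straw * straw_return_t_ha
    humus_min = params.humus_min_rate * ftfw * priming
    p.nh4[0] += kgha_to_conc(humus_min, thick[0])
    p.cum_humus_min += humus_min
    resp_c_total = resp_c + humus_min * params.humus_cn \
        * (1.0 - params.assimilation_efficiency)

    # 4. floodwater-soil mineral mixing (diffusive, both directions)
    mix = 0.0
    if pond_mm > 0:
        c_soil_solution = p.nh4[0] / max(theta_end[0], 1e-9)
        cp = p.cp(pond_mm)
        mix = params.pond_soil_mixing_rate * (c_soil_solution - cp) * pond_mm * 0.01
        if mix > 0:
            mix = min(mix, conc_to_kgha(p.nh4[0], thick[0]))
            p.nh4[0] -= kgha_to_conc(mix, thick[0])
            p.pond_mineral += mix
        else:
            back = min(-mix, p.pond_mineral)
            p.pond_mineral -= back
            p.nh4[0] += kgha_to_conc(back, thick[0])
            mix = -back
    else:
        # drained: floodwater pools merge into the top layer
        p.nh4[0] += kgha_to_conc(p.pond_mineral, thick[0])
        p.urea_std[0] += kgha_to_conc(p.pond_urea_std, thick[0])
        p.urea_ui[0] += kgha_to_conc(p.pond_urea_ui, thick[0])
        p.pond_mineral = p.pond_urea_std = p.pond_urea_ui = 0.0

    _sanitize(p)

    # 5. NH3 volatilization
    nh3 = nh3_volatilization(params, p.cp(pond_mm), tmean,
                             params.floodwater_pH, pond_mm,
                             pond_mineral_kgha=p.pond_mineral)
    p.pond_mineral -= nh3
    p.cum_nh3 += nh3

    # 6. nitrification
    nitrif = 0.0
    for i in range(3):
        r = nitrification_rate(p.nh4[i], params, wfps[i])
        p.nh4[i] -= r
        p.no3[i] += r
        nitrif += conc_to_kgha(r, thick[i])

    # 7. denitrification (layer 1; respiration-fed)
    denit = denitrification_rate(p.no3[0], resp_c_total, params, wfps[0],
                                 thickness_cm=thick[0])
    p.no3[0] -= kgha_to_conc(denit, thick[0])
    p.cum_denit += denit

    # 8. advective transport with the day's water fluxes
    f01 = water_fluxes["infiltration"]
    if f01 > 0 and pond_mm >= 0:
        cp = p.cp(pond_mm) if pond_mm > 0 else 0.0
        move_min = min(p.pond_mineral, cp * f01 * 0.01)
        p.pond_mineral -= move_min
        p.nh4[0] += kgha_to_conc(move_min, thick[0])
        for attr in ("pond_urea_std", "pond_urea_ui"):
            pool = getattr(p, attr)
            if pond_mm > 0 and pool > 0:
                conc_u = pool / (pond_mm * 0.01)
                move_u = min(pool, conc_u * f01 * 0.01)
                setattr(p, attr, pool - move_u)
                target = p.urea_std if attr == "pond_urea_std" else p.urea_ui
                target[0] += kgha_to_conc(move_u, thick[0])

    interface = [water_fluxes["f12"], water_fluxes["f23"],
                 water_fluxes["percolation"]]
    leached = 0.0
    for i, flux in enumerate(interface):
        if flux <= 0:
            continue
        theta_i = max(theta_end[i], 1e-9)
        for arr, mobility in ((p.no3, 1.0), (p.urea_std, 1.0),
                              (p.urea_ui, 1.0), (p.nh4, params.nh4_mobility)):
            c_sol = arr[i] / theta_i
            move_kg = min(conc_to_kgha(arr[i], thick[i]),
                          mobility * c_sol * flux * 0.01)
            arr[i] -= kgha_to_conc(move_kg, thick[i])
            if i < 2:
                arr[i + 1] += kgha_to_conc(move_kg, thick[i + 1])
            else:
                leached += move_kg
    p.cum_leach += leached

    # 9. runoff N at the floodwater mineral concentration
    runoff_mm = water_fluxes["runoff"]
    runoff_n = 0.0
    if runoff_mm > 0 and pond_mm > 0:
        runoff_n = min(p.pond_mineral, p.cp(pond_mm) * runoff_mm * 0.01)
        p.pond_mineral -= runoff_n
    p.cum_runoff_n += runoff_n
    _sanitize(p)

    end_n = p.inventory() + s.total_n()
    residual = (start_n + fert_in + humus_min) \
        - (nh3 + denit + leached + runoff_n) - end_n
    if abs(residual) > 1e-9:
        raise AssertionError(f"N balance residual {residual} kg ha-1")

    fluxes = {
        "fertilizer_n": fert_in,
        "urea_hydrolyzed": hydrolyzed,
        "nh3": nh3,
        "nitrif": nitrif,
        "denit": denit,
        "leach": leached,
        "runoff_n": runoff_n,
        "net_min": net_min,
        "humus_min": humus_min,
        "resp_c": resp_c_total,
        "cp_mgl": p.cp(pond_mm),
        "residual_n": residual,
    }
    return p, s, fluxes
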