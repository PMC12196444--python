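"""Simplified rice growth: phenology, canopy, biomass, N uptake, yield.

Phenology is thermal time above a base temperature Tb, with maturity at an
accumulated temperature Ts. Biomass accumulation is radiation-use
efficiency times intercepted PAR (Beer's-law canopy with extinction
coefficient Ke), scaled by an N stress factor. N uptake is demand-driven:
the crop tries to hold its N concentration at the critical maximum N_crit,
capped per day and limited by the mineral N available inside the root
zone. Grain yield is harvest index times aboveground dry matter, reduced
when the crop was N-stressed during the panicle-fertilizer window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .params import ParameterSet

__all__ = [
    "CropState",
    "initial_crop_state",
    "thermal_time_update",
    "canopy_growth",
    "n_uptake_step",
    "yield_formation",
]

# partition of new dry matter to leaves: 0.55 at transplant, 0 by stage 0.7
_LEAF_PARTITION_0 = 0.55
_LEAF_PARTITION_END_STAGE = 0.7
_PAR_FRACTION = 0.5  # photosynthetically active fraction of global radiation


@dataclass
class CropState:
    """Daily crop state (all quantities non-negative)."""

    tt: float = 0.0            # thermal time, degC d
    stage_fraction: float = 0.0  # min(tt / Ts, 1)
    lai: float = 0.0           # m2 m-2
    leaf_mass: float = 0.0     # t ha-1
    adm: float = 0.0           # aboveground dry matter, t ha-1
    nupt: float = 0.0          # cumulative N uptake, kg N ha-1
    root_depth: float = 0.05   # m
    n_stress: float = 1.0      # 0.3..1, multiplies growth
    mature: bool = False


def initial_crop_state(params: ParameterSet) -> CropState:
    """Transplanted stand: ~0.3 t ha-1 seedling biomass, half of it leaf."""
    state = CropState(adm=0.3, leaf_mass=0.15)
    state.lai = state.leaf_mass * 0.1 * params.SLA_max
    return state


def thermal_time_update(state: CropState, tmean: float,
                        params: ParameterSet) -> CropState:
    """Accumulate max(Tmean - Tb, 0); declare maturity at TT >= Ts."""
    tt = state.tt + max(tmean - params.Tb, 0.0)
    return replace(state, tt=tt,
                   stage_fraction=min(tt / params.Ts, 1.0),
                   mature=tt >= params.Ts)


def canopy_growth(state: CropState, solar_mj: float,
                  params: ParameterSet) -> CropState:
    """Grow biomass from intercepted PAR; update leaf area and root depth."""
    if state.mature:
        return replace(state)
    interception = 1.0 - math.exp(-params.Ke * state.lai)
    # RUE in g MJ-1 -> t ha-1 = g m-2 * 0.01
    dadm = params.rue * _PAR_FRACTION * solar_mj * interception \
        * state.n_stress * 0.01
    sf = state.stage_fraction
    p_leaf = max(0.0, _LEAF_PARTITION_0 * (1.0 - sf / _LEAF_PARTITION_END_STAGE))
    leaf_mass = state.leaf_mass + p_leaf * dadm
    sla = params.SLA_max + (params.SLA_min - params.SLA_max) * sf
    root = max(state.root_depth, params.R_max * min(sf / 0.5, 1.0))
    return replace(state, adm=state.adm + dadm, leaf_mass=leaf_mass,
                   lai=leaf_mass * 0.1 * sla, root_depth=root)


def n_uptake_step(state: CropState, available_kg_ha: float,
                  params: ParameterSet) -> tuple[float, CropState]:
    """Demand-driven uptake; returns (uptake kg N ha-1 d-1, new state).

    Demand tops the plant up to N_crit percent of dry matter, capped at
    the daily uptake limit; the stress factor for the next day's growth is
    the plant N sufficiency clamped to [stress_floor, 1].
    """
    if available_kg_ha < 0:
        raise ValueError("available N must be >= 0")
    adm_kg = state.adm * 1000.0
    n_capacity = params.N_crit / 100.0 * adm_kg
    demand = max(0.0, n_capacity - state.nupt)
    demand = min(demand, params.uptake_cap)
    uptake = min(demand, available_kg_ha)
    nupt = state.nupt + uptake
    if n_capacity > 0:
        stress = min(1.0, max(params.stress_floor, nupt / n_capacity))
    else:
        stress = 1.0
    return uptake, replace(state, nupt=nupt, n_stress=stress)


def yield_formation(state: CropState, mean_pf_stress: float,
                    params: ParameterSet) -> float:
    """Grain yield (t ha-1): HI * ADM * (0.6 + 0.4 * mean PF-stage stress)."""
    if not (0.0 <= mean_pf_stress <= 1.0):
        raise ValueError("mean_pf_stress must be in [0, 1]")
    y = params.harvest_index * state.adm * (0.6 + 0.4 * mean_pf_stress)
    return min(y, state.adm)
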