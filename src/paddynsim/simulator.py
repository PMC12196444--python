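"""Season runner, scenario grid, stage aggregation, and mass-balance audit.

A scenario is one management plan: straw return amount, N split ratio
(BF:TF:PF), urease-inhibitor flag, total urea N, and a weather preset.
``run_season`` couples water -> nitrogen -> crop daily over a transplant-
to-harvest window; ``run_grid`` executes lists of scenarios (the shipped
default grid is 7 straw levels x 6 split ratios x 2 UI options = 84);
``field_experiment_2018`` reproduces the eight-treatment field design
(CK, U, US2/5/8, UIS2/5/8).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import pandas as pd

from . import crop as crop_mod
from . import nitrogen as n_mod
from . import water as water_mod
from .params import (ParameterSet, SimulationConfig, default_parameter_set,
                     default_simulation_config)
from .weather import (SEASON_2018, SEASON_2019, ClimateSpec, WeatherDay,
                      climate_2018_like, climate_2019_like,
                      generate_season_weather)

__all__ = [
    "ScenarioSpec",
    "SeasonResult",
    "DEFAULT_STRAW_LEVELS",
    "DEFAULT_NSR_SET",
    "build_scenario_grid",
    "run_season",
    "run_grid",
    "aggregate_by_stage",
    "mass_balance_audit",
    "field_experiment_2018",
    "GRID_COLUMNS",
]

#: shipped scenario-grid defaults: straw levels (t ha-1) and BF:TF:PF ratios
DEFAULT_STRAW_LEVELS = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
DEFAULT_NSR_SET = (
    (2, 1, 2), (1, 2, 2), (2, 3, 5), (1, 1, 3), (1, 2, 7), (2, 1, 7),
)

GRID_COLUMNS = [
    "key", "straw_tha", "nsr", "ui", "yield_tha", "adm_tha",
    "nupt_kgha", "nupt_bf", "nupt_tf", "nupt_pf",
    "nh3_kgha", "nh3_bf", "nh3_tf", "nh3_pf",
    "denit_kgha", "leach_kgha", "runoffN_kgha", "residual", "error",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One management scenario."""

    straw_t_ha: float
    nsr: tuple[float, float, float]  # BF:TF:PF weights
    ui: bool
    total_n: float = 150.0           # kg urea-N ha-1
    weather_preset: str = "2019-like"
    name: str = ""

    def __post_init__(self):
        if self.straw_t_ha < 0:
            raise ValueError("straw amount must be >= 0")
        if self.total_n < 0:
            raise ValueError("total N must be >= 0")
        if len(self.nsr) != 3 or any(w < 0 for w in self.nsr) or sum(self.nsr) <= 0:
            if self.total_n > 0:
                raise ValueError(f"invalid NSR weights {self.nsr}")

    @property
    def nsr_string(self) -> str:
        return ":".join(f"{w:g}" for w in self.nsr)

    @property
    def key(self) -> str:
        return f"S{self.straw_t_ha:g}_NSR{self.nsr_string}_UI{int(self.ui)}"

    def split_amounts(self) -> tuple[float, float, float]:
        """Urea N per event (BF, TF, PF) by normalized NSR weights."""
        total_w = sum(self.nsr)
        if self.total_n == 0 or total_w == 0:
            return (0.0, 0.0, 0.0)
        return tuple(self.total_n * w / total_w for w in self.nsr)


@dataclass
class SeasonResult:
    """Simulated outputs of one scenario."""

    spec: ScenarioSpec
    yield_t_ha: float
    adm_t_ha: float
    nupt_kg_ha: float
    nh3_kg_ha: float
    denit_kg_ha: float
    leach_kg_ha: float
    runoff_n_kg_ha: float
    et_mm: float
    irrigation_mm: float
    event_days: dict          # label -> day index
    daily: pd.DataFrame       # per-day trace of all fluxes/states
    initial_n_inventory: float
    final_n_inventory: float
    fert_n_total: float
    straw_n_total: float
    humus_min_total: float
    residual: float
    nupt_by_stage: dict = field(default_factory=dict)
    nh3_by_stage: dict = field(default_factory=dict)


def build_scenario_grid(straw_levels=DEFAULT_STRAW_LEVELS,
                        nsr_list=DEFAULT_NSR_SET,
                        ui_options=(False, True),
                        total_n: float = 150.0,
                        weather_preset: str = "2019-like"
                        ) -> list[ScenarioSpec]:
    """Cartesian product of management options (straw outer, NSR middle,
    UI inner). The defaults yield the 84-scenario grid."""
    if not straw_levels or not nsr_list or not ui_options:
        raise ValueError("scenario grid inputs must be non-empty")
    specs = []
    for straw in straw_levels:
        for nsr in nsr_list:
            for ui in ui_options:
                specs.append(ScenarioSpec(
                    straw_t_ha=float(straw), nsr=tuple(nsr), ui=bool(ui),
                    total_n=total_n, weather_preset=weather_preset))
    return specs


_PRESETS = {
    "2018-like": (climate_2018_like, SEASON_2018),
    "2019-like": (climate_2019_like, SEASON_2019),
}


def _preset_weather(preset: str, seed_offset: int = 0
                    ) -> tuple[list[WeatherDay], ClimateSpec, int]:
    if preset not in _PRESETS:
        raise ValueError(f"unknown weather preset: {preset!r}")
    spec_fn, (start, end) = _PRESETS[preset]
    cspec = spec_fn()
    if seed_offset:
        cspec = dataclasses.replace(cspec, seed=cspec.seed + seed_offset)
    n_days = (end - start).days + 1
    return generate_season_weather(cspec, start, n_days), cspec, n_days


def run_season(spec: ScenarioSpec,
               config: SimulationConfig | None = None,
               params: ParameterSet | None = None,
               weather: list[WeatherDay] | None = None,
               et_scale: float | None = None) -> SeasonResult:
    """Simulate one season: straw incorporated at transplanting, urea split
    over BF (transplant day), TF (+tf_offset_days) and PF (first day the
    thermal-time fraction reaches pf_stage_fraction), water -> nitrogen ->
    crop advanced daily; deterministic for a fixed weather series."""
    config = config or default_simulation_config()
    params = params or default_parameter_set()
    if weather is None:
        weather, cspec, _ = _preset_weather(spec.weather_preset,
                                            seed_offset=config.seed)
        if et_scale is None:
            et_scale = cspec.et_scale
    et_scale = 1.0 if et_scale is None else et_scale
    n_days = len(weather)
    if n_days < 2:
        raise ValueError("weather series shorter than season")

    bf_n, tf_n, pf_n = spec.split_amounts()
    drainage_day = max(0, n_days - 1 - config.drainage_offset_days)
    tf_day = min(config.tf_offset_days, n_days - 1)

    wstate = water_mod.initial_water_state(params)
    npools = n_mod.initial_nitrogen_pools(params)
    straw = n_mod.StrawPools.from_straw(spec.straw_t_ha, params)
    cstate = crop_mod.initial_crop_state(params)

    straw_n_total = straw.total_n()
    initial_inventory = npools.inventory()
    event_days: dict[str, int] = {"BF": 0, "TF": tf_day}
    pf_day: int | None = None
    pf_stress: list[float] = []
    rows = []
    fert_total = 0.0

    for d, day in enumerate(weather):
        kc = water_mod.crop_coefficient(cstate.stage_fraction, params)
        et0 = water_mod.reference_et(day, config.latitude, config.elevation) \
            * et_scale
        wstate, wflux = water_mod.daily_water_step(
            wstate, day, kc, config, params,
            irrigating=d < drainage_day, et0=et0)

        events = []
        if d == 0 and bf_n > 0:
            events.append(n_mod.FertilizerEvent(bf_n, ui=spec.ui, label="BF"))
        if d == tf_day and tf_n > 0:
            events.append(n_mod.FertilizerEvent(tf_n, ui=False, label="TF"))
        if pf_day is None and pf_n > 0 and (
                cstate.stage_fraction >= config.pf_stage_fraction
                or d == drainage_day - 1):
            pf_day = d
            event_days["PF"] = d
            events.append(n_mod.FertilizerEvent(pf_n, ui=False, label="PF"))
        fert_total += sum(ev.amount_kg_n for ev in events)

        npools, straw, nflux = n_mod.daily_nitrogen_step(
            npools, straw, wflux, wstate.theta, day.tmean, events, params,
            straw_return_t_ha=spec.straw_t_ha)

        cstate = crop_mod.thermal_time_update(cstate, day.tmean, params)
        cstate = crop_mod.canopy_growth(cstate, day.solar_mj, params)
        uptake, cstate = _crop_uptake(cstate, npools, config, params)
        if pf_day is not None:
            pf_stress.append(cstate.n_stress)

        rows.append({
            "day": d, "date": day.date, "tmean": day.tmean,
            "ponding_mm": wstate.ponding_mm, "et_mm": wflux["et"],
            "irrig_mm": wflux["irrigation"], "perc_mm": wflux["percolation"],
            "runoff_mm": wflux["runoff"],
            "theta1": wstate.theta[0], "theta2": wstate.theta[1],
            "theta3": wstate.theta[2],
            "fert_n": nflux["fertilizer_n"],
            "urea_hydrolyzed": nflux["urea_hydrolyzed"],
            "nh3_kgha": nflux["nh3"], "nitrif": nflux["nitrif"],
            "denit": nflux["denit"], "leach": nflux["leach"],
            "runoffN": nflux["runoff_n"], "net_min": nflux["net_min"],
            "humus_min": nflux["humus_min"], "cp_mgL": nflux["cp_mgl"],
            "nupt_daily": uptake, "tt": cstate.tt, "lai": cstate.lai,
            "adm_tha": cstate.adm, "nupt_kgha": cstate.nupt,
            "stress": cstate.n_stress,
        })

    if pf_day is None:
        event_days["PF"] = drainage_day
    mean_pf_stress = (sum(pf_stress) / len(pf_stress)) if pf_stress \
        else cstate.n_stress
    grain = crop_mod.yield_formation(cstate, mean_pf_stress, params)

    daily = pd.DataFrame(rows)
    final_inventory = npools.inventory() + straw.total_n()
    result = SeasonResult(
        spec=spec,
        yield_t_ha=grain,
        adm_t_ha=cstate.adm,
        nupt_kg_ha=cstate.nupt,
        nh3_kg_ha=npools.cum_nh3,
        denit_kg_ha=npools.cum_denit,
        leach_kg_ha=npools.cum_leach,
        runoff_n_kg_ha=npools.cum_runoff_n,
        et_mm=wstate.cum_et,
        irrigation_mm=wstate.cum_irrigation,
        event_days=event_days,
        daily=daily,
        initial_n_inventory=initial_inventory,
        final_n_inventory=final_inventory,
        fert_n_total=fert_total,
        straw_n_total=straw_n_total,
        humus_min_total=npools.cum_humus_min,
        residual=0.0,
    )
    result.residual = mass_balance_audit(result)
    stage = aggregate_by_stage(result)
    result.nupt_by_stage = dict(zip(stage["stage"], stage["nupt_kgha"]))
    result.nh3_by_stage = dict(zip(stage["stage"], stage["nh3_kgha"]))
    return result


def _crop_uptake(cstate, npools, config, params):
    """Uptake limited to mineral N inside the root zone; withdrawal split
    proportionally over the (layer, species) pools."""
    bounds = config.layer_bounds_cm
    root_cm = cstate.root_depth * 100.0
    avail_parts = []  # (pool list, index, kg available)
    for i in range(3):
        top, bot = bounds[i], bounds[i + 1]
        frac = min(1.0, max(0.0, (root_cm - top) / (bot - top)))
        if frac <= 0:
            continue
        thick = bot - top
        for arr in (npools.nh4, npools.no3):
            avail_parts.append((arr, i, n_mod.conc_to_kgha(arr[i], thick) * frac,
                                thick))
    total_avail = sum(a for _, _, a, _ in avail_parts)
    uptake, cstate = crop_mod.n_uptake_step(cstate, total_avail, params)
    if uptake > 0 and total_avail > 0:
        for arr, i, a, thick in avail_parts:
            take = uptake * a / total_avail
            arr[i] -= n_mod.kgha_to_conc(take, thick)
            if -1e-9 < arr[i] < 0:  # float noise from the round trip
                arr[i] = 0.0
    return uptake, cstate


def aggregate_by_stage(result: SeasonResult,
                       event_days: dict | None = None) -> pd.DataFrame:
    """Partition daily N uptake and NH3 into the BF/TF/PF stage windows.

    Windows are half-open [event_i, event_{i+1}) and [PF, harvest]; the
    stage sums recover the season totals exactly.
    """
    ev = event_days or result.event_days
    bf, tf, pf = ev["BF"], ev["TF"], ev["PF"]
    if not (bf <= tf <= pf):
        raise ValueError(f"stage events out of order: BF={bf}, TF={tf}, PF={pf}")
    daily = result.daily
    windows = {"BF": (bf, tf), "TF": (tf, pf), "PF": (pf, len(daily))}
    rows = []
    for stage, (lo, hi) in windows.items():
        sel = daily[(daily["day"] >= lo) & (daily["day"] < hi)]
        rows.append({"stage": stage,
                     "nupt_kgha": float(sel["nupt_daily"].sum()),
                     "nh3_kgha": float(sel["nh3_kgha"].sum())})
    return pd.DataFrame(rows)


def mass_balance_audit(result: SeasonResult) -> float:
    """Season N balance residual (kg N ha-1), recomputed from the daily trace.

    inputs (fertilizer + straw N + initial mineral/urea N + SOM
    mineralization) minus outputs (NH3 + denitrification + leaching +
    runoff N + crop uptake) minus the change in stored N.
    """
    d = result.daily
    required = {"fert_n", "humus_min", "nh3_kgha", "denit", "leach",
                "runoffN", "nupt_daily"}
    missing = required - set(d.columns)
    if missing:
        raise ValueError(f"daily trace missing columns: {sorted(missing)}")
    inputs = (result.initial_n_inventory + result.straw_n_total
              + float(d["fert_n"].sum()) + float(d["humus_min"].sum()))
    outputs = float(d["nh3_kgha"].sum() + d["denit"].sum() + d["leach"].sum()
                    + d["runoffN"].sum() + d["nupt_daily"].sum())
    return inputs - outputs - result.final_n_inventory


def run_grid(specs: list[ScenarioSpec],
             config: SimulationConfig | None = None,
             params: ParameterSet | None = None,
             existing: pd.DataFrame | None = None) -> pd.DataFrame:
    """Run scenarios into a results table (one row each), resumable.

    Rows whose scenario key already appears in ``existing`` are kept as-is;
    per-scenario failures are recorded in the ``error`` column and the run
    continues.
    """
    config = config or default_simulation_config()
    params = params or default_parameter_set()
    done: dict[str, dict] = {}
    if existing is not None and len(existing):
        done = {row["key"]: dict(row) for _, row in existing.iterrows()}

    weather_cache: dict[str, tuple] = {}
    rows = []
    for spec in specs:
        if spec.key in done:
            rows.append(done[spec.key])
            continue
        row = {"key": spec.key, "straw_tha": spec.straw_t_ha,
               "nsr": spec.nsr_string, "ui": int(spec.ui), "error": ""}
        try:
            if spec.weather_preset not in weather_cache:
                w, cs, _ = _preset_weather(spec.weather_preset,
                                           seed_offset=config.seed)
                weather_cache[spec.weather_preset] = (w, cs.et_scale)
            w, et_scale = weather_cache[spec.weather_preset]
            res = run_season(spec, config, params, weather=w,
                             et_scale=et_scale)
            row.update({
                "yield_tha": res.yield_t_ha, "adm_tha": res.adm_t_ha,
                "nupt_kgha": res.nupt_kg_ha,
                "nupt_bf": res.nupt_by_stage["BF"],
                "nupt_tf": res.nupt_by_stage["TF"],
                "nupt_pf": res.nupt_by_stage["PF"],
                "nh3_kgha": res.nh3_kg_ha,
                "nh3_bf": res.nh3_by_stage["BF"],
                "nh3_tf": res.nh3_by_stage["TF"],
                "nh3_pf": res.nh3_by_stage["PF"],
                "denit_kgha": res.denit_kg_ha, "leach_kgha": res.leach_kg_ha,
                "runoffN_kgha": res.runoff_n_kg_ha, "residual": res.residual,
            })
        except Exception as exc:  # per-scenario isolation
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def field_experiment_2018() -> dict[str, ScenarioSpec]:
    """The eight-treatment field design: control, urea only, urea + straw
    at 2/5/8 t ha-1, and urea + UI + straw at the same amounts; urea at
    150 kg N ha-1 split 2:1:2, UI only in the UIS plans."""
    nsr = (2, 1, 2)
    specs = {
        "CK": ScenarioSpec(0.0, nsr, False, total_n=0.0,
                           weather_preset="2018-like", name="CK"),
        "U": ScenarioSpec(0.0, nsr, False, weather_preset="2018-like",
                          name="U"),
    }
    for amount in (2, 5, 8):
        specs[f"US{amount}"] = ScenarioSpec(
            float(amount), nsr, False, weather_preset="2018-like",
            name=f"US{amount}")
        specs[f"UIS{amount}"] = ScenarioSpec(
            float(amount), nsr, True, weather_preset="2018-like",
            name=f"UIS{amount}")
    return specs
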