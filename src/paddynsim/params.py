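"""Model parameters and simulation settings.

The shipped defaults are the calibrated purple-soil paddy parameter set for
the Ziyang (Sichuan Basin) site: three soil layers (0-20, 20-40, 40-80 cm),
a rice crop parameterized by thermal time, and first-order N-transformation
constants including the urea hydrolysis coefficient with and without a 1%
NBPT urease inhibitor (Kh 0.05 -> 0.007 d-1).

Configuration files are YAML with three top-level keys::

    schema_version: 1
    parameters:      # any ParameterSet field
      Kv: 0.095
    simulation:      # any SimulationConfig field
      bund_height_mm: 50

Unknown keys are rejected by name; omitted fields take their defaults.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ParameterSet",
    "SimulationConfig",
    "ConfigError",
    "default_parameter_set",
    "default_simulation_config",
    "validate_parameters",
    "validate_config",
    "load_config",
    "save_config",
    "dump_parameters_csv",
    "LAYER_THICKNESS_CM",
]

SCHEMA_VERSION = 1

#: thicknesses of the three soil layers (0-20, 20-40, 40-80 cm)
LAYER_THICKNESS_CM = (20.0, 20.0, 40.0)


@dataclass(frozen=True)
class ParameterSet:
    """Full parameter set: soil hydraulics, crop, and N transformation.

    The first block mirrors the calibrated site values; the second block
    holds the stand-in process constants of the simplified organic-matter
    and crop components (all exposed so they can be overridden in config).
    """

    # --- soil hydraulic parameters (per layer: 0-20, 20-40, 40-80 cm) ---
    Ks_by_layer: tuple[float, float, float] = (1.0, 0.6, 0.7)  # cm d-1
    theta_s_by_layer: tuple[float, float, float] = (0.65, 0.50, 0.43)  # cm3 cm-3
    FC_by_layer: tuple[float, float, float] = (0.35, 0.25, 0.24)  # cm3 cm-3
    WP_by_layer: tuple[float, float, float] = (0.17, 0.15, 0.13)  # cm3 cm-3

    # --- crop parameters ---
    Tb: float = 10.0          # base temperature, deg C
    Ts: float = 1630.0        # accumulated temperature to maturity, deg C d
    Ke: float = 0.5           # canopy extinction coefficient, -
    K_ini: float = 0.8        # crop coefficient, initial stage, -
    K_mid: float = 1.4        # crop coefficient, middle stage, -
    K_end: float = 0.7        # crop coefficient, end stage, -
    SLA_max: float = 22.0     # maximum specific leaf area, m2 kg-1
    SLA_min: float = 10.0     # minimum specific leaf area, m2 kg-1
    R_max: float = 0.5        # maximum root depth, m
    N_crit: float = 2.5       # maximum critical N concentration, % of DM

    # --- N transformation parameters ---
    Vn: float = 70.0          # maximum nitrification rate, mg L-1 d-1
    Kn: float = 70.0          # nitrification half-saturation constant, mg L-1
    Kd: float = 0.5           # denitrification proportionality factor, -
    Ad: float = 0.02          # denitrification constant, mg N (mg C)-1
    Kv: float = 0.095         # NH3 volatilization first-order constant, d-1
    Kh: float = 0.05          # urea hydrolysis coefficient, d-1
    Kh_UI: float = 0.007      # urea hydrolysis coefficient under 1% UI, d-1

    # --- site chemistry ---
    floodwater_pH: float = 7.73   # constant per run (no dynamic pH model)
    soil_pH: float = 7.73

    # --- stand-in constants: straw / organic matter turnover ---
    straw_c_content: float = 0.406    # kg C per kg straw DM
    straw_n_content: float = 0.0042   # kg N per kg straw DM
    straw_k_fast: float = 0.05        # fast-pool decay, d-1 at 25 C
    straw_k_slow: float = 0.002       # slow-pool decay, d-1 at 25 C
    straw_fast_fraction: float = 0.6  # share of straw C in the fast pool
    assimilation_efficiency: float = 0.4  # microbial C assimilation E, -
    microbial_cn: float = 8.0         # microbial biomass C:N, -
    microbial_n_turnover: float = 0.03    # immobilized-N re-release, d-1
    q10: float = 2.0                  # temperature sensitivity of turnover
    q10_ref_temp: float = 25.0        # reference temperature, deg C
    humus_min_rate: float = 0.8       # background SOM N mineralization, kg N ha-1 d-1 at 25 C
    humus_cn: float = 10.0            # SOM C:N for respiration bookkeeping, -
    priming_per_t_straw: float = 0.06     # SOM mineralization boost per t straw, -
    urease_stim_per_t_straw: float = 0.05  # Kh multiplier slope per t straw, -

    # --- stand-in constants: transport / crop growth ---
    pond_soil_mixing_rate: float = 0.25   # floodwater-soil solute mixing, d-1
    nh4_mobility: float = 0.1             # NH4+ advective mobility (adsorption), -
    rue: float = 2.2                  # radiation use efficiency, g DM MJ-1 PAR
    harvest_index: float = 0.45       # grain fraction of ADM, -
    uptake_cap: float = 5.0           # max daily crop N uptake, kg N ha-1 d-1
    stress_floor: float = 0.3         # lower clamp of the N stress factor, -

    # --- initial soil mineral N (bulk concentration per layer) ---
    init_nh4_by_layer: tuple[float, float, float] = (2.0, 1.0, 0.5)  # ug cm-3
    init_no3_by_layer: tuple[float, float, float] = (1.0, 1.0, 0.5)  # ug cm-3


@dataclass(frozen=True)
class SimulationConfig:
    """Run-level settings: geometry, ponding policy, event scheduling."""

    layer_bounds_cm: tuple[float, float, float, float] = (0.0, 20.0, 40.0, 80.0)
    ponding_min_mm: float = 0.0       # bottom of the target ponding band
    ponding_max_mm: float = 50.0      # top of the target ponding band
    bund_height_mm: float = 50.0      # overflow spill level
    drainage_offset_days: int = 14    # irrigation stops this many days before harvest
    timestep_days: int = 1            # fixed daily step
    tf_offset_days: int = 12          # tiller fertilizer, days after transplant
    pf_stage_fraction: float = 0.55   # panicle fertilizer trigger (thermal-time fraction)
    latitude: float = 30.1            # deg N
    elevation: float = 400.0          # m
    seed: int = 0


def default_parameter_set() -> ParameterSet:
    """Return the calibrated default parameter set (referentially transparent)."""
    return ParameterSet()


def default_simulation_config() -> SimulationConfig:
    return SimulationConfig()


def _check(violations: list[str], ok: bool, message: str) -> None:
    if not ok:
        violations.append(message)


def validate_parameters(params: ParameterSet) -> list[str]:
    """Return a list of invariant violations (empty iff the set is valid)."""
    v: list[str] = []
    rate_fields = (
        "Ks_by_layer", "Vn", "Kn", "Kd", "Ad", "Kv", "Kh", "Kh_UI",
        "straw_k_fast", "straw_k_slow", "microbial_n_turnover",
        "humus_min_rate", "pond_soil_mixing_rate",
    )
    for name in rate_fields:
        value = getattr(params, name)
        vals = value if isinstance(value, tuple) else (value,)
        for i, x in enumerate(vals):
            suffix = f"[{i}]" if isinstance(value, tuple) else ""
            _check(v, x >= 0, f"{name}{suffix} must be >= 0 (got {x})")
    for i in range(3):
        wp = params.WP_by_layer[i]
        fc = params.FC_by_layer[i]
        ts = params.theta_s_by_layer[i]
        _check(v, wp < fc, f"WP_by_layer[{i}]={wp} must be < FC_by_layer[{i}]={fc}")
        _check(v, fc < ts, f"FC_by_layer[{i}]={fc} must be < theta_s_by_layer[{i}]={ts}")
    _check(v, params.SLA_min < params.SLA_max,
           f"SLA_min={params.SLA_min} must be < SLA_max={params.SLA_max}")
    _check(v, 0.0 < params.Ke <= 1.0, f"Ke={params.Ke} must be in (0, 1]")
    _check(v, params.Kh_UI < params.Kh,
           f"Kh_UI={params.Kh_UI} must be < Kh={params.Kh} (inhibitor slows hydrolysis)")
    _check(v, params.Tb >= 0, f"Tb={params.Tb} must be >= 0")
    _check(v, params.Ts > 0, f"Ts={params.Ts} must be > 0")
    _check(v, 0 < params.N_crit < 10, f"N_crit={params.N_crit} must be in (0, 10) %DM")
    _check(v, 0 < params.assimilation_efficiency < 1,
           "assimilation_efficiency must be in (0, 1)")
    _check(v, params.microbial_cn > 0, "microbial_cn must be > 0")
    _check(v, 0 <= params.straw_fast_fraction <= 1,
           "straw_fast_fraction must be in [0, 1]")
    _check(v, 0 < params.harvest_index <= 1, "harvest_index must be in (0, 1]")
    _check(v, 0 <= params.stress_floor <= 1, "stress_floor must be in [0, 1]")
    for name in ("init_nh4_by_layer", "init_no3_by_layer"):
        for i, x in enumerate(getattr(params, name)):
            _check(v, x >= 0, f"{name}[{i}] must be >= 0 (got {x})")
    return v


def validate_config(config: SimulationConfig) -> list[str]:
    v: list[str] = []
    b = config.layer_bounds_cm
    _check(v, all(b[i] < b[i + 1] for i in range(len(b) - 1)),
           f"layer_bounds_cm={b} must be strictly increasing")
    _check(v, config.drainage_offset_days >= 0, "drainage_offset_days must be >= 0")
    _check(v, config.timestep_days == 1, "timestep_days must be exactly 1")
    _check(v, 0 <= config.ponding_min_mm <= config.ponding_max_mm,
           "ponding band must satisfy 0 <= min <= max")
    _check(v, config.bund_height_mm >= config.ponding_max_mm,
           "bund_height_mm must be >= ponding_max_mm")
    _check(v, 0 < config.pf_stage_fraction < 1, "pf_stage_fraction must be in (0, 1)")
    _check(v, config.tf_offset_days >= 0, "tf_offset_days must be >= 0")
    return v


class ConfigError(ValueError):
    """Raised for unknown keys, schema problems, or invalid loaded values."""


def _coerce(dc_type: type, raw: dict[str, Any], section: str):
    known = {f.name for f in fields(dc_type)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{section}': {', '.join(sorted(unknown))}"
        )
    coerced = {
        k: tuple(x) if isinstance(x, list) else x for k, x in raw.items()
    }
    return dc_type(**coerced)


def load_config(path: str | Path) -> tuple[SimulationConfig, ParameterSet]:
    """Load a YAML config; omitted fields take their documented defaults.

    Raises
    ------
    FileNotFoundError
        if the file does not exist.
    ConfigError
        on unknown keys (named in the message) or failed validation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - {"schema_version", "parameters", "simulation"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version: {version}")
    params = _coerce(ParameterSet, raw.get("parameters") or {}, "parameters")
    config = _coerce(SimulationConfig, raw.get("simulation") or {}, "simulation")
    problems = validate_parameters(params) + validate_config(config)
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))
    return config, params


def _to_plain(value: Any) -> Any:
    return list(value) if isinstance(value, tuple) else value


def save_config(path: str | Path, config: SimulationConfig | None = None,
                params: ParameterSet | None = None) -> None:
    """Write a config file that round-trips field-for-field via load_config."""
    config = config or default_simulation_config()
    params = params or default_parameter_set()
    doc = {
        "schema_version": SCHEMA_VERSION,
        "parameters": {f.name: _to_plain(getattr(params, f.name))
                       for f in fields(params)},
        "simulation": {f.name: _to_plain(getattr(config, f.name))
                       for f in fields(config)},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# units + provenance for the parameter dump
_PARAM_UNITS: dict[str, tuple[str, str]] = {
    "Ks_by_layer": ("cm d-1", "calibrated"),
    "theta_s_by_layer": ("cm3 cm-3", "calibrated"),
    "FC_by_layer": ("cm3 cm-3", "calibrated"),
    "WP_by_layer": ("cm3 cm-3", "calibrated"),
    "Tb": ("degC", "calibrated"),
    "Ts": ("degC d", "calibrated"),
    "Ke": ("-", "calibrated"),
    "K_ini": ("-", "calibrated"),
    "K_mid": ("-", "calibrated"),
    "K_end": ("-", "calibrated"),
    "SLA_max": ("m2 kg-1", "calibrated"),
    "SLA_min": ("m2 kg-1", "calibrated"),
    "R_max": ("m", "calibrated"),
    "N_crit": ("% DM", "calibrated"),
    "Vn": ("mg L-1 d-1", "calibrated"),
    "Kn": ("mg L-1", "calibrated"),
    "Kd": ("-", "calibrated"),
    "Ad": ("mg N (mg C)-1", "calibrated"),
    "Kv": ("d-1", "calibrated"),
    "Kh": ("d-1", "calibrated"),
    "Kh_UI": ("d-1", "calibrated"),
    "floodwater_pH": ("-", "site assumption"),
    "soil_pH": ("-", "site measurement"),
}


def dump_parameters_csv(path: str | Path, params: ParameterSet | None = None) -> None:
    """Dump the parameter set to CSV as ``symbol,value,units,source``."""
    params = params or default_parameter_set()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["symbol", "value", "units", "source"])
        for f in fields(params):
            units, source = _PARAM_UNITS.get(f.name, ("-", "stand-in default"))
            value = getattr(params, f.name)
            if isinstance(value, tuple):
                value = ";".join(repr(x) for x in value)
            writer.writerow([f.name, value, units, source])
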