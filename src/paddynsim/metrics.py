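"""NUE indicators, model-evaluation statistics, synthetic observations,
and grid-search calibration of the urea hydrolysis coefficient.

Nitrogen-use-efficiency indicators (all kg kg-1 unless noted):

* PE  = (Yield_N - Yield_CK) / (Nupt_N - Nupt_CK), physiological efficiency
* AE  = (Yield_N - Yield_CK) / N rate, agronomic efficiency
* PFP = Yield_N / N rate, partial factor productivity
* yield-scaled NH3 = NH3 * 1e3 / Yield, reported in 1e-3 kg kg-1

where the N application rate is total N from urea plus returned straw.

Model fit statistics: normalized RMSE (percent of the observed mean),
Willmott's index of agreement IA, and Nash-Sutcliffe efficiency NSE, with
the standard performance bands (nRMSE < 15% good, 15-30% moderate, > 30%
poor; minimum IA/NSE thresholds differ between crop-growth and N-output
variables).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .params import ParameterSet, SimulationConfig
from .simulator import ScenarioSpec, run_season

__all__ = [
    "NUEInputs",
    "NUEResult",
    "EvaluationReport",
    "nue_indicators",
    "evaluation_metrics",
    "classify_performance",
    "synthetic_observations",
    "calibrate_kh",
    "straw_n_rate",
]


@dataclass(frozen=True)
class NUEInputs:
    yield_n: float        # t ha-1, fertilized treatment
    yield_ck: float       # t ha-1, unfertilized control
    nupt_n: float         # kg N ha-1
    nupt_ck: float        # kg N ha-1
    n_application_rate: float  # kg N ha-1, urea N + straw N
    nh3_total: float      # kg N ha-1


@dataclass(frozen=True)
class NUEResult:
    pe: float             # kg kg-1
    ae: float             # kg kg-1
    pfp: float            # kg kg-1
    yield_scaled_nh3: float  # 1e-3 kg NH3-N per kg grain


def straw_n_rate(straw_t_ha: float, params: ParameterSet) -> float:
    """N brought in by returned straw (kg N ha-1)."""
    return straw_t_ha * 1000.0 * params.straw_n_content


def nue_indicators(inputs: NUEInputs) -> NUEResult:
    """Compute PE, AE, PFP and yield-scaled NH3 volatilization."""
    for name in ("yield_n", "yield_ck", "nupt_n", "nupt_ck",
                 "n_application_rate", "nh3_total"):
        if getattr(inputs, name) < 0:
            raise ValueError(f"{name} must be >= 0")
    if inputs.n_application_rate <= 0:
        raise ValueError("N application rate must be > 0 for AE/PFP")
    dn = inputs.nupt_n - inputs.nupt_ck
    if dn == 0:
        raise ZeroDivisionError(
            "PE undefined: fertilized and control N uptake are equal")
    dy_kg = (inputs.yield_n - inputs.yield_ck) * 1000.0
    pe = dy_kg / dn
    ae = dy_kg / inputs.n_application_rate
    pfp = inputs.yield_n * 1000.0 / inputs.n_application_rate
    if inputs.yield_n <= 0:
        raise ValueError("yield must be > 0 for yield-scaled NH3")
    ysn = inputs.nh3_total * 1e3 / (inputs.yield_n * 1000.0)
    return NUEResult(pe=pe, ae=ae, pfp=pfp, yield_scaled_nh3=ysn)


@dataclass(frozen=True)
class EvaluationReport:
    nrmse: float   # %
    ia: float      # <= 1
    nse: float     # <= 1
    n: int


def evaluation_metrics(simulated, observed) -> EvaluationReport:
    """nRMSE (% of observed mean), index of agreement, Nash-Sutcliffe.

    Requires equal lengths >= 2 and a non-degenerate observed series
    (non-zero variance and non-zero mean).
    """
    s = np.asarray(simulated, dtype=float)
    o = np.asarray(observed, dtype=float)
    if s.shape != o.shape:
        raise ValueError(f"length mismatch: {s.shape} vs {o.shape}")
    n = s.size
    if n < 2:
        raise ValueError("need at least 2 paired values")
    obar = o.mean()
    sse = float(np.sum((s - o) ** 2))
    denom_nse = float(np.sum((o - obar) ** 2))
    if denom_nse == 0:
        raise ValueError("observed series is constant: NSE/IA undefined")
    if obar == 0:
        raise ValueError("observed mean is zero: nRMSE undefined")
    nrmse = math.sqrt(sse / n) / obar * 100.0
    denom_ia = float(np.sum((np.abs(s - obar) + np.abs(o - obar)) ** 2))
    ia = 1.0 - sse / denom_ia
    nse = 1.0 - sse / denom_nse
    return EvaluationReport(nrmse=nrmse, ia=ia, nse=nse, n=n)


_CLASS_THRESHOLDS = {
    # variable class -> (minimum IA, minimum NSE)
    "crop_growth": (0.75, 0.0),
    "n_output": (0.60, -1.0),
}


def classify_performance(report: EvaluationReport, variable_class: str) -> dict:
    """Rate a fit: good (nRMSE < 15), moderate (15-30, inclusive), poor
    (> 30), plus minimum IA/NSE threshold flags for the variable class."""
    if variable_class not in _CLASS_THRESHOLDS:
        raise ValueError(f"unknown variable class: {variable_class!r} "
                         f"(expected one of {sorted(_CLASS_THRESHOLDS)})")
    if report.nrmse < 15.0:
        rating = "good"
    elif report.nrmse <= 30.0:
        rating = "moderate"
    else:
        rating = "poor"
    ia_min, nse_min = _CLASS_THRESHOLDS[variable_class]
    return {
        "rating": rating,
        "ia_pass": report.ia >= ia_min,
        "nse_pass": report.nse >= nse_min,
    }


def synthetic_observations(truth, cv: float, seed: int):
    """Noisy observed-style series: multiplicative lognormal noise with
    coefficient of variation ``cv`` (mean-preserving), truncated at 0.

    cv = 0 returns the truth unchanged; deterministic per seed.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    t = np.asarray(truth, dtype=float)
    if cv == 0:
        return t.copy()
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    rng = np.random.default_rng(seed)
    factors = np.exp(rng.normal(-sigma * sigma / 2.0, sigma, size=t.shape))
    return np.maximum(t * factors, 0.0)


def calibrate_kh(observed_nh3, spec: ScenarioSpec,
                 config: SimulationConfig | None = None,
                 params: ParameterSet | None = None,
                 grid=None,
                 simulated_cache: dict | None = None
                 ) -> tuple[float, list[tuple[float, float]]]:
    """Grid-search the urea hydrolysis coefficient against a daily NH3 series.

    Runs the scenario once per candidate Kh (the UI coefficient when the
    scenario applies the inhibitor, the plain coefficient otherwise) and
    returns the candidate minimizing the nRMSE of daily NH3, with the full
    (kh, nrmse) profile. Ties break toward the smaller Kh.

    ``simulated_cache`` may map kh -> simulated daily NH3 array to reuse
    season runs across repeated calibrations of the same scenario.
    """
    from .params import default_parameter_set, default_simulation_config

    if grid is None or len(grid) == 0:
        raise ValueError("calibration grid must be non-empty")
    if any(k <= 0 for k in grid):
        raise ValueError("all Kh candidates must be > 0")
    config = config or default_simulation_config()
    params = params or default_parameter_set()
    obs = np.asarray(observed_nh3, dtype=float)

    profile = []
    best_kh, best_obj = None, math.inf
    for kh in sorted(grid):
        if simulated_cache is not None and kh in simulated_cache:
            sim = simulated_cache[kh]
        else:
            if spec.ui:
                trial = replace(params, Kh_UI=kh,
                                Kh=max(params.Kh, kh * (1 + 1e-9)))
            else:
                trial = replace(params, Kh=kh,
                                Kh_UI=min(params.Kh_UI, kh * (1 - 1e-9)))
            result = run_season(spec, config, trial)
            sim = result.daily["nh3_kgha"].to_numpy()
            if simulated_cache is not None:
                simulated_cache[kh] = sim
        if sim.shape != obs.shape:
            raise ValueError(
                f"observed series length {obs.size} does not match the "
                f"simulated season length {sim.size}")
        obj = evaluation_metrics(sim, obs).nrmse
        profile.append((kh, obj))
        if obj < best_obj:
            best_kh, best_obj = kh, obj
    return best_kh, profile
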