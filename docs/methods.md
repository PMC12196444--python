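# Methods

This note documents the model structure, the defaults and why they are
what they are, what the synthetic data does and does not emulate, the
numerical conventions, and the known limitations. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Scope and design philosophy

The package is a desk-scale re-creation of a coupled paddy
water–heat–carbon–nitrogen simulator for one rice season. The nitrogen
process kinetics (urea hydrolysis, floodwater ammonia volatilization,
nitrification, denitrification) are implemented exactly as closed-form
daily equations with the calibrated purple-soil parameter set as shipped
defaults. The surrounding machinery — soil hydrology, crop growth,
organic-matter turnover — uses deliberately simple, fully documented
stand-ins, because the reference descriptions of those components
(Richards-equation hydrology, the PS123 crop model, the Daisy
organic-matter pool structure) are not reproducible from published
constants alone. Every stand-in constant is an explicit, overridable
field of `ParameterSet`/`SimulationConfig`.

## Water balance

A ponding store over three tipping-bucket layers (0–20/20–40/40–80 cm).
Reference ET is FAO-56 Penman–Monteith; crop ET is `Kc(stage) · ET0` with
the piecewise Kc curve (plateau K_ini to 25% of thermal time, rise to
K_mid by 45%, plateau to 75%, fall to K_end at maturity). Under permanent
ponding, saturated Darcy flow at unit gradient reduces to a
conductivity-limited flux, so infiltration is capped at Ks₁ (10 mm d⁻¹)
and each interface at the receiving layer's Ks. Irrigation refills the
pond to the top of the 0–50 mm band whenever it would empty, and stops 14
days before harvest ("field drying"), after which volatilization ceases
with the pond. The daily update order (rain → ET → infiltration/cascade →
overflow → irrigation) is fixed; each day asserts closure to 10⁻⁹ mm.
Irrigation totals are emergent, not prescribed — only the ponding band is
management input.

## Nitrogen cycle

Bulk concentrations (µg cm⁻³ ≡ mg L⁻¹ of bulk volume) in soil, mass
pools (kg N ha⁻¹) in the floodwater; bridges: 1 µg cm⁻³ over d cm =
0.1·d kg ha⁻¹, and 1 mg L⁻¹ over 1 mm of pond = 0.01 kg ha⁻¹.

Two conventions deserve emphasis:

* **WFPS is a fraction, not a percent**, in the hydrolysis exponential
  `1 − exp(−5 · WFPS · K_h)`. With a percent scale the exponential
  saturates (`1 − e^(−250·K_h)` ≈ 1 for any plausible K_h) and the
  inhibitor contrast K_h 0.05 → 0.007 d⁻¹ would have no effect, which
  contradicts its calibrated purpose. The fraction reading gives ~22% of
  the urea pool hydrolyzing per day in saturated soil — "within a few
  days", as expected in hot-season paddies.
* **The volatilization denominator** is implemented as
  `1 + 10^(0.09018 + 2729.92/(T+273.15) − pH)` — the standard aqueous
  NH₃/NH₄⁺ pKa correlation. This is the only grouping of those printed
  constants that yields a fraction in (0,1) increasing in both T and pH,
  with the exact identity fraction = ½ at pH = pKa(T).

Urea broadcast onto a ponded field enters a floodwater urea pool and
hydrolyses there at WFPS = 1; it also moves into the topsoil with
infiltration. Two urea sub-pools per compartment carry their own K_h
(with/without inhibitor), because with K_h = 0.007 d⁻¹ roughly two-thirds
of the basal urea is still intact when the tillering dose (plain K_h)
arrives 12 days later. Floodwater and topsoil mineral N mix by a
first-order rate (0.25 d⁻¹, an exposed constant with no external anchor)
toward the layer-1 soil-solution concentration. Solutes advect with the
day's water fluxes at source-layer solution concentrations; NH₄⁺ carries
a mobility factor of 0.1 for adsorption, so leaching is mostly nitrate.
Denitrification is fed by decomposition respiration and is active only
above WFPS 0.7; nitrification is Michaelis–Menten with a linear anoxia
ramp from WFPS 0.6 (factor 1) to saturation (0.1). Every flux is
pool-limited and the daily step asserts N closure to 10⁻⁹ kg ha⁻¹.

### Straw and soil organic matter

Returned straw (40.6% C, 0.42% N → C:N ≈ 97) splits into a fast pool
(60% of C, k = 0.05 d⁻¹) and slow pool (40%, 0.002 d⁻¹), each scaled by
Q10 = 2 (reference 25 °C) and a wet-suppression factor (1 up to WFPS
0.6, halved at saturation — anaerobic slowdown). Decomposed C is split by
assimilation efficiency E = 0.4 into microbial growth demanding N at C:N
8, and respired C. Straw N releases in proportion to C decomposed. The
balance point is organic C:N = 8/0.4 = 20: above it (all realistic straw)
the early phase immobilizes soil mineral N. Immobilized N sits in a
microbial pool that re-mineralizes at 0.03 d⁻¹ — without this turnover
the straw N effect would have the wrong sign over a season.

Two straw feedbacks that the two-pool scheme alone cannot produce are
included explicitly because they carry the observed management response:

* **urease stimulation** — straw raises urease activity; K_h is
  multiplied by (1 + 0.05 per t ha⁻¹);
* **priming of native SOM** — background soil-organic-matter
  mineralization (0.8 kg N ha⁻¹ d⁻¹ at 25 °C, supported by the site's
  2.16 g kg⁻¹ total N; required for the zero-N control to grow at all) is
  multiplied by (1 + 0.06 per t ha⁻¹).

Both coefficients were fixed once at field-plausible magnitudes. Net
effect: straw return increases both seasonal NH₃ and crop N uptake, with
the N-uptake margin small (a few kg N ha⁻¹ across the 2–8 t range)
because priming and residual immobilization nearly cancel — under some
weather realizations the uptake trend can flatten or dip slightly; under
the default scenario weather it is monotone non-decreasing.

## Crop

Thermal time above T_b = 10 °C; maturity at 1630 °C d (~105 days at
summer temperatures). Growth is RUE (2.2 g MJ⁻¹) × PAR (0.5 × global
radiation) × Beer's-law interception (K_e = 0.5) × N-stress. Leaf
partition falls linearly from 0.55 at transplanting to 0 at stage 0.7;
SLA interpolates 22 → 10 m² kg⁻¹; the transplanted stand starts at
0.3 t ha⁻¹ (LAI ≈ 0.33). Daily N demand tops the plant up to 2.5% of dry
matter, capped at 5 kg N ha⁻¹ d⁻¹, withdrawn from mineral pools inside
the root zone (linear root growth to 0.5 m by mid-season) proportionally
to pool sizes. The stress factor is the N sufficiency clamped to
[0.3, 1]. Yield = 0.45 × ADM × (0.6 + 0.4 × mean panicle-stage stress).

## Synthetic weather

Deterministic per seed. Temperature: sinusoid (mean 17 °C, amplitude
9.5 °C, peak mid-July) + AR(1) anomaly (sd 1.5 °C, persistence 0.7).
Rainfall: monthly-weighted wet-day probability with mean-matched gamma
amounts, so any window's expected total equals its share of the 950 mm
annual normal. Sunshine fraction 0.36 dry / 0.12 wet (≈1250 h yr⁻¹);
radiation via Ångström–Prescott (a = 0.25, b = 0.50) on FAO-56
extraterrestrial radiation. The two season presets differ in seed and an
ET0 scale factor (0.88 / 0.78) chosen so the simulated seasonal crop ET
lands at the two reported seasonal totals (~350 and ~310 mm).

What the generator does *not* emulate: real inter-annual structure,
typhoon/extreme events, multi-day synoptic persistence in radiation, or
the actual 2018–2019 station record (unpublished). Passing tests
therefore demonstrate internal consistency and directional behaviour of
the model under realistic forcing statistics — not agreement with the
field measurements, which are not available to compare against.

## Scenario machinery

The default grid is the full Cartesian product of straw {2…8} t ha⁻¹ ×
NSR {2:1:2, 1:2:2, 2:3:5, 1:1:3, 1:2:7, 2:1:7} × UI {off, on} = 84, with
deterministic ordering and a string key per scenario for resumable grid
runs. BF is applied at transplanting, TF 12 days later, PF when the
thermal-time fraction reaches 0.55 (both configurable; the application
dates are not otherwise documented for the site). The eight-treatment
field fixture (CK, U, US₂/₅/₈, UIS₂/₅/₈) uses the first-season preset.
The season-level audit recomputes the N budget from the daily trace:
inputs (fertilizer, straw N, initial profile N, SOM mineralization) minus
losses (NH₃, denitrification, leaching, runoff, uptake) minus storage
change; the tests corrupt a single day's flux and verify the audit flags
exactly that amount.

## Evaluation and calibration

nRMSE (% of observed mean), Willmott's index of agreement, and
Nash–Sutcliffe efficiency, with the performance bands: good below 15%
(15% itself classifies as moderate, since "less than 15%" is the stated
good criterion), moderate to 30% inclusive, poor above; minimum IA/NSE
thresholds 0.75/0 for crop-growth variables and 0.60/−1 for N-output
variables. NSE and IA raise on a constant observed series rather than
returning a sentinel. Synthetic observations apply mean-preserving
multiplicative lognormal noise with a specified CV. Calibration of the
hydrolysis coefficient formalizes trial-and-error as a grid search
minimizing the nRMSE of the daily NH₃ series (single-series objective;
ties break toward the smaller, i.e. more inhibited, coefficient).

## Numerical conventions

Explicit first-order (Euler) daily updates throughout, with every rate
converted to a per-day fraction and capped at 1; all withdrawals
pool-limited; float-noise negatives (< 10⁻⁹) clamped to zero, anything
larger treated as a bug and raised. Problem sizes used by the test suite
and acceptance script: 110–111-day seasons, the 84-scenario grid, 200
weather seeds for climate normals, and 50 noise seeds × 20 grid points
for parameter recovery (candidate season runs are cached across seeds,
since they do not depend on the noise).

## Known limitations

* Floodwater pH is a constant (default = soil pH 7.73). Real floodwater
  pH swings diurnally to 8.5–9 after urea application, and the NH₃(aq)
  fraction — hence the absolute volatilization level — is roughly an
  order of magnitude higher there. Simulated seasonal NH₃ totals are
  accordingly small in absolute terms; comparisons across management
  options (the package's purpose) are unaffected in direction. Raising
  `floodwater_pH` in config scales NH₃ up strongly.
* Because early-season N losses are small at pH 7.73, front-loaded splits
  are barely penalized, and the late-heavy 1:1:3 split does not out-yield
  the 2:1:2 base under the defaults (the contrast is computed and
  reported by the acceptance script, not asserted).
* No N₂O partitioning, dissolved organic N, canopy NH₃ recapture, dynamic
  floodwater pH, soil temperature (air temperature stands in), capillary
  rise, or multi-season carryover.
* The crop stand-in has no tillering or organ-level structure; the yield
  response to late N runs entirely through the panicle-stage stress term.
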