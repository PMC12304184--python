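# Methods

This note documents the models implemented in `lueyield`, the assumptions
and numerical choices behind them, and what the synthetic-data generator
does and does not emulate.

## Semi-physical light-use-efficiency model

The yield chain is: per-composite stress scalars → realised light-use
efficiency ε = ε_max·T_s·W_s·P_s → seasonal ΣNPP = Σ PAR·fAPAR·ε·Δt →
linear yield regression `Yield = a·ΣNPP + b`. Its assumptions are the
standard LUE-model ones: carbon uptake proportional to absorbed PAR, with
environmental limitation entering only through multiplicative scalars in
[0, 1]; an 8-day composite is the native time step, and Δt (days per
composite) makes the accumulation explicit so a truncated final composite
is handled exactly.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| `eps_max` | 0.34 | gC MJ⁻¹ | maximum light-use efficiency of cropland |
| `t_opt` | 30 | °C | photosynthetic optimum for corn/soybean |
| `temp_limit_mode` | `daily_observed` | – | source of T_min/T_max in T_s |
| `t_min_const`, `t_max_const` | 10, 40 | °C | crop constants (alternative mode) |
| `ws_formula` | `as_printed` | – | direction of the water-stress scalar |
| `phase_transition_doy` | 213 (Aug 1) | – | leaf-growth → grain-ripening switch |
| `npp_scale` | 1.0 | – | multiplier on ΣNPP before the regression |
| a, b (corn) | 0.12, 0.739 | t ha⁻¹ per NPP unit; t ha⁻¹ | published regression constants |
| a, b (soybean) | 0.073, 1.298 | 〃 | 〃 |

### Open design points and how they were resolved

**Water-stress direction.** The printed scalar (1 − LSWI)/(1 + LSWI_max)
*increases* with drought, yet it multiplies ε — so drier canopies would
photosynthesise more. The standard vegetation-photosynthesis-model scalar
uses (1 + LSWI) in the numerator and has the opposite (physiologically
expected) direction. Both are implemented behind `ws_formula`; the
`as_printed` form is the default for fidelity to the published formulation,
and neither is asserted to be "the" truth. Both raw ratios can leave [0, 1]
(e.g. LSWI < 0 with a modest seasonal maximum), so both are clamped, keeping
the stated 0–1 range of the scalar.

**Temperature limits.** T_s needs a minimum and maximum viable temperature.
`daily_observed` (default) takes them as the composite-period means of the
observed daily minima and maxima — reading the symbol definitions literally —
while `crop_constants` uses fixed photosynthetic limits (defaults 10/40 °C)
as in the VPM lineage. Outside [T_min, T_max] the quadratic ratio changes
sign; T_s is defined as 0 there (photosynthesis shut down) and the formula
is evaluated only strictly inside the interval, clamped to [0, 1] to guard
the asymmetric-optimum case where the raw ratio exceeds 1.

**Phase transition.** The switch from the leaf-growth scalar (P_s = 1) to
grain ripening ((1 + LSWI)/2) is taken at a fixed calendar day (Aug 1,
configurable). A fixed date is the simplest reproducible rule; LSWI-based
phenology detection is deliberately out of scope.

**NPP units.** The published (a, b) pairs imply an ΣNPP scale their source
does not state; applying a = 0.12 to a field-realistic corn ΣNPP of
~900 gC m⁻² would give an implausible ~108 t/ha. The pipeline therefore
applies the regression verbatim and exposes `npp_scale` (default 1) for
users who need to re-scale ΣNPP; the synthetic data are generated
self-consistently from the same pipeline, so all internal results are
unaffected by this ambiguity.

**Composite temperature.** T in T_s is the mean over the composite window of
the daily mean temperature, using (tmax + tmin)/2 when no measured daily
mean is available.

## Reference evapotranspiration

ET0 = 0.0013·0.408·RA·(T_avg + 17.0)·(TD − 0.0123·P)^0.76 (mm d⁻¹), driven
by extraterrestrial radiation RA from FAO-56 solar geometry: dr = 1 +
0.033·cos(2πJ/365), δ = 0.409·sin(2πJ/365 − 1.39), ω_s = arccos(−tanφ·tanδ)
with the arccos argument clamped to [−1, 1] so polar night/day degrade
gracefully. Two floors guard the Hargreaves term: (TD − 0.0123·P) and
(T_avg + 17) are floored at 0 before use, because the fractional exponent is
undefined for negative bases and both represent shut-down evaporative
demand. RA is validated in the tests against a brute-force numeric
integration of instantaneous top-of-atmosphere irradiance over daylight
hours (agreement ≤ 0.5 %). The CLI default latitude is 40°N (central corn
belt); it is a required physical input, not a fitted quantity.

## Neural-network baseline

A 9–10–1 feed-forward network: nine growing-season mean meteorology features
(tmax, tmin, precipitation, solar radiation, wind, relative humidity, and
surface/profile/root-zone soil wetness), ten tanh hidden units, linear
output. Inputs are z-scored with statistics fitted on the training rows only
(min–max [0, 1] scaling selectable); the target is internally standardised
for conditioning and back-transformed at prediction. Data are split
70/15/15 by a seeded random permutation with largest-remainder rounding, so
n = 100 gives exactly (70, 15, 15).

Training is full-batch resilient propagation (iRprop+): per-weight step
sizes grown ×1.2 while the gradient sign persists, shrunk ×0.5 on a flip,
with the last move undone when a flip coincides with a training-loss
increase. Rprop adapts step sizes from gradient signs only, which makes it
fully deterministic per seed and robust to the MSE scale. The output layer
is initialised at 1 % scale so the network starts near the constant (mean)
predictor. Early stopping monitors validation MSE with a 100-epoch patience
(2000 epoch cap) and restores the best-epoch weights; the per-epoch
train/validation history is kept for performance plots. The long patience
is deliberate: Rprop's validation trace is non-monotone epoch-to-epoch, and
short patience windows systematically under-train (on noiseless linear
targets they cost ~0.04 of test R²); since the best epoch is restored, extra
patience costs only compute, never skill. A deeper variant (several hidden
layers of ten units) is available via `n_hidden_layers` but is not the
default.

Whether the real protocol's features were season means, sums, or monthly
values is ambiguous; this package uses season means and documents that
choice here.

## Evaluation

R² is the coefficient of determination 1 − SS_res/SS_tot about the observed
mean — it can be negative and equals squared correlation only for
calibrated predictions — with Pearson r reported alongside; RMSE is in
ton/ha. The comparison table emits one row per (model, crop, split); models
with a fitting protocol get calibration/validation/test/overall rows, while
the semi-physical model (no split) gets only the overall row. Records are
sorted canonically before scoring, so the table is bit-for-bit permutation
invariant.

## Synthetic-data generator

The generator emulates the statistical structure of the pipeline's real
inputs at region-year scale, with one independent pseudo-random stream per
(region, year, purpose) derived from the master seed (so identical configs
produce byte-identical datasets, and regions can be generated in any order).

* **Meteorology** — sinusoidal seasonal cycles plus Gaussian noise for
  temperature (July-peak tmax climatology 32 °C, season-mean daily mean
  ≈ 24.7 °C, diurnal range ~11 ± 2.5 °C) and solar radiation; intermittent
  precipitation (30 % rain days × gamma amounts, mean ~8 mm); humidity,
  wind and three soil-wetness layers clipped to their physical ranges, the
  wetness layers nudged by recent rainfall. Daily tmax is clipped to the
  observed midwest envelope [−19.23, 41.31] °C as a plausibility bound.
* **Composites** — fAPAR follows a product of green-up and senescence
  logistics (single interior peak) scaled to the crop's canopy peak;
  NIR/SWIR reflectances partition a fixed total so LSWI rises from ~0.05 to
  a mid-season maximum; PAR daily means are 45 % of simulated solar
  radiation clipped to the configured range. Canopy peak and LSWI amplitude
  are weakly coupled to the same region-year's rainfall and warmth, so the
  meteorology features carry genuine (modest) yield signal.
* **Yields** — observed = truth_a·ΣNPP + truth_b + N(0, σ) with ΣNPP
  computed by the *actual* stress/NPP pipeline on the generated composites;
  σ defaults to 0.3 ton/ha, Gaussian and homoscedastic (the simplest error
  model consistent with an OLS yield regression). Crop defaults (corn:
  canopy peak 0.95, PAR 7–12 MJ m⁻² d⁻¹; soybean: 0.55, 6–10) put corn
  yields near 7–15 t/ha and soybean near 2.5–4.4 t/ha with the published
  constants.

What the generator does **not** emulate: spatial correlation between
regions, multi-year climate trends, cloud/QA contamination of reflectance,
heteroscedastic or skewed yield errors, and any raster/pixel structure.
Passing tests therefore demonstrate the correctness and statistical
calibration of the pipeline's machinery — not that the model attains any
particular skill on real satellite and survey data.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: typically 10–50 regions ×
1–10 years (50–200 region-years), 200 replicates for the coverage check,
and 10 seeds for the network skill summary — sizes chosen so the whole suite
completes in well under a minute each while keeping Monte-Carlo noise far
below the tolerances asserted. Ordinary least squares goes through
statsmodels (for standard errors); metric oracles in the tests use
independent closed-form implementations. Floating-point ties in the split
rounding are broken in train → validation → test order. CSV readers use
round-trip float parsing so write→read is bit-exact.

## Known limitations

* The as-printed water-stress direction is physiologically counter-intuitive
  (see above); comparisons across `ws_formula` settings change ΣNPP scale.
* `daily_observed` temperature limits make T_s sensitive to the diurnal
  range of the forcing data.
* The NPP-to-yield unit question is unresolved upstream; absolute ΣNPP
  magnitudes should not be compared against field NPP without `npp_scale`.
* The soil-water-balance crop simulator the ET0 routine would normally feed
  is intentionally not implemented; ET0 is exposed as a forcing-table
  product only.
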