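# lueyield

Crop-yield estimation for corn and soybean from remote-sensing and
meteorological forcing, built around a semi-physical light-use-efficiency
(LUE) model. The package is aimed at agroecologists and yield-forecasting
practitioners who want a transparent, fully seeded desk-scale implementation
of the LUE → NPP → yield chain, together with the supporting pieces such a
study needs: a modified-Hargreaves reference-evapotranspiration routine, a
9–10–1 neural-network yield baseline, an R²/RMSE model-comparison harness,
and a synthetic region-year data generator with known ground truth.

## The model

Realised light-use efficiency down-scales a biome maximum by three stress
scalars in [0, 1]:

    ε = ε_max · T_s · W_s · P_s        ε_max = 0.34 gC MJ⁻¹

* **T_s** (temperature stress) = (T−T_min)(T−T_max) / [(T−T_min)(T−T_max) − (T−T_opt)²],
  zero outside [T_min, T_max], with T_opt = 30 °C for corn and soybean.
* **W_s** (water stress) from the land surface water index
  LSWI = (NIR − SWIR)/(NIR + SWIR): W_s = (1 − LSWI)/(1 + LSWI_max) by
  default, with the standard VPM form (1 + LSWI)/(1 + LSWI_max) selectable
  (`ws_formula="vpm_standard"`); both clamped to [0, 1].
* **P_s** (phenology phase): 1 during leaf growth, (1 + LSWI)/2 during grain
  ripening.

Seasonal net primary productivity accumulates over 8-day composites,

    ΣNPP = Σᵢ PARᵢ · fAPARᵢ · εᵢ · Δtᵢ      [gC m⁻²]

and maps linearly to yield, `Yield = a·ΣNPP + b` (ton/ha), with published
constants a = 0.12, b = 0.739 for corn and a = 0.073, b = 1.298 for soybean,
or constants calibrated by ordinary least squares.

Daily reference evapotranspiration uses the modified Hargreaves form

    ET0 = 0.0013 · 0.408 · RA · (T_avg + 17.0) · (TD − 0.0123·P)^0.76

with extraterrestrial radiation RA from standard FAO-56 solar geometry.

The neural-network baseline is a 9–10–1 multilayer perceptron (nine
season-mean meteorology features, ten tanh hidden units, linear output),
z-score standardised inputs, a seeded 70/15/15 train/validation/test split,
trained full-batch with resilient propagation and validation early stopping.

## Worked example

```python
import lueyield as ly

cfg = ly.SimulationConfig.for_crop(
    "corn", n_regions=10, years=tuple(range(2015, 2025)), seed=42
)
seasons = [ly.generate_season(cfg, rid, yr)
           for rid in [f"R{i+1:03d}" for i in range(cfg.n_regions)]
           for yr in cfg.years]
records = ly.generate_yield_dataset(cfg, seasons=seasons)

model = ly.SemiPhysicalYieldModel(
    seasons, [r.observed_yield for r in records], crop="corn"
)
results = model.fit()
print(results.summary())
```

prints

```
Semi-physical LUE yield model
==============================================
crop:            corn
region-years:    100
constants:       calibrated (OLS)
slope a:         0.122734  (SE 0.004521)
intercept b:     0.530435 ton/ha  (SE 0.282553)
npp_scale:       1.0
R^2:             0.8827
RMSE:            0.3012 ton/ha
Pearson r:       0.9395
```

The generator built 100 region-years whose observed yields follow
`0.12·ΣNPP + 0.739` plus 0.3 ton/ha of Gaussian noise; the OLS calibration
recovers the slope within one standard error and the intercept within one,
and the fitted model explains 88 % of the yield variance with a 0.30 ton/ha
RMSE — consistent with the injected noise level. `ANNYieldModel` exposes the
neural baseline the same way (`fit()` → per-split R²/RMSE and a training
history for performance plots), and `lueyield.comparison_table` assembles the
model-vs-model score table.

The same pipeline is scriptable from a shell:

```bash
lueyield simulate --crop corn --seed 3 --out-dir sim
lueyield et0 --meteo sim/meteorology.csv --out met_et0.csv
lueyield run-spm --composites sim/composites.csv --meteo sim/meteorology.csv \
    --observed sim/yields.csv --crop corn --out spm.csv
lueyield calibrate --yields sim/yields.csv --crop corn --out constants.json
lueyield ann --features sim/features.csv --seed 3 --out-dir annout
lueyield evaluate --yields spm.csv --yields annout/ann_predictions.csv \
    --crop corn --out scores
```

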