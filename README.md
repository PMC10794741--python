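# frostfield

Plot-level **frost-damage-index (FDI) estimation** for open-field lettuce
breeding trials from co-registered RGB and 5-band multispectral rasters of the
kind a low-altitude UAV survey produces.

Breeding trials score frost tolerance by grading every plant of a plot on an
ordinal damage scale 0..MAX_DL and summarizing the plot as

```
FDI = Σᵢ (PNᵢ · i) / (MAX_DL · TPN)        ∈ [0, 1]
```

where `PNᵢ` is the number of plants at level `i` and `TPN` the plot's plant
count. Walking hundreds of plots to grade plants by hand is slow; `frostfield`
implements the image-based alternative end to end:

1. **Radiometric calibration** — DN → reflectance against a gray panel of
   known reflectance.
2. **Segmentation** — vegetation = NDVI > 0.5 on the *healthy-date* scene
   (damaged canopies no longer separate from soil), cleaned by a majority
   filter; the footprint is applied to the *post-frost* scene.
3. **Feature extraction per plot** — 3 channel means + 15 color indexes
   (ExG, VARI, NGRDI, …) + 24 GLCM texture statistics from the RGB raster;
   5 band reflectances + 23 vegetation indexes from the multispectral raster,
   including the frost-damage family FD_VI1..FD_VI4, e.g.
   `FD_VI1 = (R840 + R717 − R668) / (R840 + R717 + R668)`.
4. **Feature screening** — Pearson correlation with FDI per cultivar group
   (ALL / GREEN / RED), keeping features with `p < 0.01`, equivalently
   `|r| > t_crit / √(t_crit² + n − 2)`.
5. **Regression** — 7:3 stratified split over FDI-quantile bins, then
   multiple linear regression, linear ε-SVR (C = 0.19, ε = 0.019) and a
   10-unit Levenberg–Marquardt neural network per feature source
   (RGB / MSI / MULTISOURCE) and group, evaluated by R², RMSE and MAE.

Because no public survey of this kind exists, the package ships a first-class
**synthetic field generator** (`frostfield.synthetic_field`) that renders
co-registered scene pairs with known per-plant grades and a damage response
that follows the frost physiology: blue/red reflectance rises with damage,
NIR falls, and the green band responds with opposite sign in green vs
anthocyanin-rich red cultivars. Every stage is tested against it.

## Worked example

```
$ frostfield simulate --seed 7 --out runs/fix
{"fixture": "runs/fix", "seed": 7}
$ frostfield run --fixture runs/fix --out runs/out --no-figures
{"n_plots": 209, "n_dropped": 0, "n_model_cells": 27}
```

`runs/out/model_reports.csv` then holds one row per (group, source,
algorithm) cell. On this fixture the MULTISOURCE-ALL-MLR row reads

```
group source      algorithm n_features train_r2 test_r2 test_rmse test_mae
ALL   MULTISOURCE MLR       42         0.939    0.862   0.109     0.086
```

i.e. 42 features survived screening in the ALL group, and the fused linear
model explains ~86% of the held-out FDI variance with an RMSE of 0.109 FDI
units. `runs/out/selection.csv` lists every feature's per-group `r`, `p`,
critical `|r|` and selected flag; `runs/out/predictions.csv` the per-plot
actual and predicted FDI.

The same steps are available as library calls (`sample_damage_grades`,
`render_scene`, `ndvi_mask`, `build_feature_table`, `select_features`,
`run_cells`) — see `docs/methods.md` for the model and its assumptions.

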