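# Methods

## The estimation problem

A frost-tolerance trial scores each breeding plot by grading all of its
plants on an ordinal damage scale `0..MAX_DL` (0 = undamaged) and summarizing
the plot as the frost damage index

    FDI = Σᵢ (PNᵢ · i) / (MAX_DL · TPN) ∈ [0, 1],

the mean per-plant level normalized by the maximum level. `frostfield`
estimates FDI from imagery: plot-level features are extracted from a
co-registered RGB digital-number raster and a 5-band reflectance raster
(475/560/668/717/840 nm), screened by Pearson correlation with FDI, and fed
to regression models. The grade scale's semantics are survey-specific; the
package treats levels as purely ordinal and makes `MAX_DL` configurable
(default 5, with level 0 included so FDI = 0 is attainable).

## Imaging chain

**Calibration.** Reflectance = DN × panel_reflectance / panel_DN per band,
clipped to [0, 1]; a gray panel of 50% reflectance is the default reference.
Synthetic scenes are generated directly in reflectance, so calibration is
exercised on DN inputs only.

**Segmentation.** Vegetation is NDVI = (R840 − R668)/(R840 + R668) > 0.5,
computed on a *mask-source* scene acquired before the frost events — a
frost-damaged canopy no longer separates cleanly from soil, so the pipeline
deliberately takes the mask scene and the feature scene as two inputs.
Pixels with a zero NDVI denominator are background (they occur only on
pathological inputs).

**Majority filter.** Small misclassified plaques are removed by a
`window × window` (default 3×3) weighted majority vote with the center pixel
carrying 2 votes and ties keeping the original value; the neighborhood
outside the image counts as background. The center weight of 2 is this
package's kernel convention: an isolated pixel is still removed (3 + 2 votes
of 11 total), while the right-angle corners of a solid rectangular plot
footprint (4 + 2 of 11, a tie at the corner's 5-vs-5 split) are preserved, so
any solid block at least as large as the window is an exact fixed point.
Window size and center weight are configurable.

**Zonal extraction.** For each plot id the pixels with `label == id` and
mask true are collected from both rasters (keeping the bounding-box geometry
for texture work); plots whose footprint is entirely masked out are reported
and dropped, never silently imputed.

## Features (70 per plot)

* **RGB (42):** channel means R, G, B; fifteen color indexes evaluated on the
  zonal mean DN (a per-pixel-then-mean switch exists; on homogeneous plots
  the two agree); twenty-four texture statistics — Mean, Variance,
  Homogeneity, Contrast, Dissimilarity, Entropy, Second Moment, Correlation
  per channel — from gray-level co-occurrence matrices.
* **MSI (28):** the five band reflectances and twenty-three vegetation
  indexes, including the frost-damage family FD_VI1..FD_VI4 whose
  denominators add red-edge/green/blue bands and the constants 25 and 7;
  those constants are reproduced verbatim (they are part of the index
  definitions, dimensionless by construction).

GLCM parameters are rarely published; the defaults here are the conventional
remote-sensing choice: 32 linearly quantized levels with fixed breakpoints
over [0, 255] (bin width 8 DN), the four distance-1 directions, symmetric
counting restricted to pixel pairs that both lie inside the plot's masked
footprint, and texture statistics averaged over directions. A single
offset-averaged matrix is also available (`glcm(..., average=True)`); the two
conventions differ only for the nonlinear statistics. Entropy uses the
natural log (`0·log 0 ≡ 0`, base configurable); Correlation uses the standard
product-moment numerator `Σ i·j·p(i,j) − μxμy` and is flagged NaN on
degenerate marginals.

Any zero-denominator index value is NaN — a flagged missing value excluded
pairwise downstream — never an exception and never imputed at extraction
time.

## Screening and models

Each feature is screened within ALL / GREEN / RED groups; `p < 0.01`
(two-sided, from the exact t transform of r) is realized as
`|r| > t_crit/√(t_crit² + n − 2)` with `n` the feature's complete-pair count
after pairwise deletion. No multiple-testing correction by default (the
screening is intentionally per-feature; Bonferroni is available). Screening
uses the full group rather than the training split, matching the procedure's
ordering; thresholds are always recomputed from `n` rather than hard-coded.

Splitting is stratified 7:3 over FDI-quantile bins (default 5): the train
total is exactly `round(0.7 n)` via largest-remainder allocation, so a
160-plot group always yields 112/48 and a 209-plot group 146/63. Each group
is split independently.

* **MLR** — `numpy` least squares; rank-deficient or under-determined designs
  get the minimum-norm solution with a logged warning (selected CIs can be
  exactly collinear, e.g. ExGR = ExG − ExR).
* **SVM** — `sklearn` ε-SVR with a linear kernel on z-scored features (that
  is what "kernel scale 1" means operationally), C = 0.19 and ε = 0.019, the
  midpoints of the protocol ranges [0.18, 0.2] × [0.018, 0.02]. With the
  sum-form objective used by all mainstream SVR implementations, duplicating
  the training rows changes the optimum unless the box constraint is
  inactive; the duplication-invariance property is therefore only asserted
  in the ε-tube-dominated regime where it holds exactly.
* **NN** — one hidden layer of 10 tanh units with a linear output ("10
  hidden units" being the conventional reading of the classic toolbox
  configuration; a 10-layer LM-trained net on ~150 samples is not plausible
  and the layout is configurable). Trained by damped Gauss–Newton
  (Levenberg–Marquardt) with analytic Jacobians, a light ridge penalty
  (1e-3) on all weights, early stopping on a held-out 15% fold of the
  training rows, and up to 3 deterministic re-initializations on divergence.
  The trainer is implemented in `frostfield.nnet` (~100 lines) since no
  installed package offers LM training for dense nets; it is deterministic
  given the seed.

Features are z-scored (training statistics) for SVM and NN and left raw for
MLR. NaN feature values surviving to modeling are imputed with the training
median. Accuracy is R² = 1 − SS_res/SS_tot (the only reading consistent with
"closer to 1 is better"), RMSE, and MAE; R² is flagged NaN when the observed
values have zero variance, and groups whose split would leave fewer than two
train or test plots are skipped with a reason rather than scored.

## Synthetic field generator

The generator emulates the trial the pipeline targets: 209 rectangular plots
(160 green + 49 red cultivars, assigned at random) of 24 plants each on a
regular grid with soil gaps, rendered as co-registered RGB-DN, reflectance
and label rasters.

* **Grades.** Each plot draws a latent severity `s ~ U(0, spread)`
  (`spread = 1` by default so plot severities span the full range; 0 is the
  all-healthy pre-frost field); plants draw beta-binomial grades around `s`
  (concentration 8), giving realistic within-plot disagreement.
* **Spectral response.** Per cultivar color, pixel value =
  `baseline + slope · FDI` plus an independent per-plot (cultivar) Gaussian
  baseline offset and per-pixel Gaussian noise, clipped to the physical
  range. Slope signs encode the frost mechanism: chlorophyll breakdown
  raises blue (475) and red (668) reflectance, cell-structure collapse
  lowers NIR (840); the green band falls slightly for green cultivars but
  rises for red ones (anthocyanin breakdown), which reproduces the
  group-dependent correlation signs. The type constructor rejects parameter
  sets violating these signs.
* **Defaults.** Pixel noise 0.01 reflectance / 3 DN; per-plot cultivar
  jitter 0.02 reflectance / 8 DN, drawn independently for the two sensors —
  209 distinct cultivars vary in color and architecture, and this
  independent nuisance is exactly what makes the RGB and multispectral
  sources complementary rather than redundant views of FDI. Healthy canopy
  NDVI is ≈ 0.82 (green) / 0.76 (red) and soil ≈ 0.18, leaving > 0.2 margin
  on both sides of the 0.5 threshold.
* **DN rasters are real-valued** in [0, 255] rather than integer-quantized,
  keeping the response exactly linear for parameter-recovery analysis;
  texture extraction quantizes anyway.

What the generator does **not** emulate: radiative transfer, 3-D canopy
structure and per-plant geometry, mosaicking/registration artifacts, weather
and illumination drift, and cultivar-specific morphology beyond a scalar
baseline shift. Consequently, passing tests demonstrate the correctness and
calibration of the *pipeline* (formulas, masks, thresholds, splits, model
machinery) and the qualitative structure of the method's findings (direction
of spectral responses, group-dependent signs, multisource fusion gain) — not
field-level accuracy values: real surveys carry biological nuisance far
stronger than this model's, so accuracies measured on the synthetic default
overstate what the same pipeline achieves on a real trial.

## Problem sizes and numerical choices

The test suite runs its end-to-end properties on 12–40-plot fields with
6×8-pixel plots, and the fusion-gain and calibration properties at the full
209-plot default over 20 seeds — sizes chosen to make the Monte-Carlo checks
stable while keeping the suite fast. `scripts/acceptance.py` always runs the
full default field. Determinism: one integer seed drives grade sampling,
scene noise (an independent derived stream), the split shuffle and the
network initialization; identical seeds reproduce rasters and reports bit
for bit.

Degenerate inputs are policy, not accident: plots with zero plants are
rejected (FDI undefined), zero-variance features are flagged untestable and
never selected, empty selection cells and too-small splits are skipped with
a recorded reason, and ties in the majority filter keep the original pixel.

## Known limitations

* An RGB-only run is not supported: the vegetation mask is defined by the
  NDVI rule and therefore requires the multispectral mask-source scene.
  Missing-source degradation is handled at the modeling stage (cells without
  selected features are skipped with a reason).
* The linear damage response makes feature–FDI relations more monotone than
  real canopies; selection counts on synthetic fields are accordingly
  optimistic.
* ε-SVR with the protocol's small box constraint is close to the flat
  predictor on standardized features; it is kept at that operating point
  rather than tuned.
* The LM trainer solves the full normal equations; it is intended for the
  small networks used here (≲ 10³ parameters), not as a general deep-net
  optimizer.
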