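# Methods

## Problem and model

`hailcanopy` quantifies hail-defoliation damage in maize field trials from
multispectral surface reflectance. The retrieval chain is parametric and
fully invertible:

1. **NDVI** from red and near-infrared reflectance,
   NDVI = (NIR − red)/(NIR + red). Pixels where either band is missing or
   the reflectance sum is zero are treated as nodata, never as zero NDVI.
2. **Fractional vegetation cover** by the dimidiate-pixel model: a linear
   scaling between a bare-soil endpoint and a full-vegetation endpoint,
   FVC = (NDVI − NDVIₛ)/(NDVIᵥ − NDVIₛ), clipped to [0, 1 − ε] with
   ε = 10⁻⁶. The clip ceiling keeps the next step finite under NDVI
   saturation. Endpoint defaults NDVIₛ = 0.15, NDVIᵥ = 0.92 are package
   defaults, configurable per sensor.
3. **LAI** by Beer–Lambert inversion, LAI = −ln(1 − FVC)/k(θ). The
   extinction coefficient k(θ) is a single season-wide scalar per sensor;
   no view-zenith dependence is modelled beyond the fitted constant.

### Calibration of k(θ)

With cᵢ = −ln(1 − FVCᵢ), the RMSE between retrieved LAI cᵢ/k and ground
LAIᵢ has the closed-form minimiser

    k̂ = Σ cᵢ² / Σ cᵢ·LAIᵢ .

The implementation uses the closed form; an independent brute-force grid
search (k ∈ [0.01, 2.00], step 10⁻⁴) is kept in the package as a test
oracle and the two are required to agree to 10⁻⁴. Calibration fails
loudly when no pair carries a vegetation signal (all NDVI at or below the
soil endpoint) or the cross-moment Σcᵢ·LAIᵢ is non-positive.

The workflow object (`run_calibration_validation`) fits k̂ on the first
season only and computes second-season R²/RMSE with the frozen k̂ — the
validation step can never update the coefficient.

Fit diagnostics: RMSE = √(Σ(estᵢ−obsᵢ)²/n); R² is the squared Pearson
correlation (equivalent to the R² of a simple linear regression with
intercept). The convention matters only when the relation has bias; it is
stated here because other conventions (regression through the origin)
give different numbers.

### Ground-truth instrument

The virtual ceptometer implements the LP-80's documented simplification of
the Norman–Jarvis transmission model,

    LAI = [((1 − 1/(2K))·fb − 1) · ln τ] / [A·(1 − 0.47·fb)] ,

with τ the below/above-canopy PAR ratio, K the ellipsoidal (Campbell)
extinction coefficient for leaf-angle parameter χ at the solar zenith,
and A = 0.283 + 0.785a − 0.159a² for leaf absorptivity a. Defaults:
χ = 1 (spherical canopy), a = 0.9, fb = 0.8, zenith 30° — clear-sky
midday survey conditions. The forward model is the algebraic inversion of
the same equation, so forward/inverse round trips are exact by
construction; the instrument's own χ/fb/a values in any given field
campaign are generally unreported, so all three are configurable.

The survey protocol averages 5 sub-measurements into a reading and 3
readings per sampling point (3 points per plot in the first trial year,
2 in the second); multiplicative Gaussian noise (sd 2% of PAR) perturbs
each sub-measurement's below-canopy PAR before inversion, so the protocol
attenuates reading variance roughly fifteen-fold.

## Synthetic experiment

The generator emulates a two-year plot trial on a maize field:

- **Layout.** Year 1: V8 and dough stages × Lo/Me/Hi × 2 replicates of
  60 m squares plus two controls (14 plots). Year 2: V8/flowering/milky/
  dough × Lo/Me/Hi × 3 replicates (two 20 m, one 60 m) plus three
  controls (39 plots), on a 70 m pitch with 10 m alleys.
- **Season curve.** Control LAI follows a logistic rise normalised to hit
  the peak (default 6.0 m² m⁻² on July 7) exactly at the peak date —
  normalisation because a plain logistic only approaches its ceiling —
  then declines exponentially (rate 0.02 d⁻¹). Growth rate 0.23 d⁻¹ with
  the inflection 21 days before the peak puts the control near LAI 1.0 at
  the June 9 survey, matching the observed early-season state.
- **Damage.** At its damage date a plot drops to (1 − f)× the control
  curve, with f = 0.15/0.25/0.40 for Lo/Me/Hi (chosen once inside the
  documented 10–40 % defoliation range). V8 damage relaxes back to the
  control curve exponentially with an 8-day half-life (new-leaf
  emission), leaving a residual deficit below 2 % by the peak date;
  flowering/milky/dough damage keeps the proportional deficit through
  senescence.
- **Scenes.** Per pixel inside a plot, NDVI = forward(LAI × (1 + g)) + η,
  where g is a smooth within-plot field (one sinusoid period per plot
  side, amplitude 8 %, zero mean over the plot — soil-driven
  heterogeneity the satellite undersamples and the UAV resolves) and η is
  white sensor noise (sd 0.02). Red/NIR are synthesised at constant
  brightness red + NIR = 0.6, so the pair reproduces the target NDVI
  exactly. Outside plots the scene is bare soil at the sensor's soil
  endpoint.
- **Scales.** Default ground resolutions are 10 m (satellite-like) and
  0.5 m (UAV-like). The 0.5 m default is a desk-scale stand-in for a
  ~0.04 m flight GSD: it keeps a full-field scene around 10⁶ pixels while
  still resolving within-plot structure; rendering a single plot at
  0.04 m (≥ 250 000 in-plot pixels) is exercised in the tests.
- **Determinism.** One experiment seed is expanded into substreams keyed
  by purpose/plot/date/sensor, so regeneration is byte-identical and
  adding a survey date does not perturb earlier draws.

What the generator does **not** emulate: atmospheric effects and cloud
masking, UAV strip overlap and mosaicking, soil electrical-conductivity
covariates, row structure and leaf clumping, weather-driven growth.
Passing tests therefore show the retrieval and calibration machinery is
correct under the stated noise model, not that the accuracy figures
transfer to real imagery.

## Analysis choices

- **Zonal statistics** use a pixel-center-in-polygon rule with no area
  weighting: deterministic, and edge-pixel treatment in plot means is
  otherwise under-determined. Plot sd uses the n−1 denominator.
- **Percent variation vs control** is computed from unrounded group means
  and rounded half-away-from-zero to one decimal. Worked-example checks
  against published survey means only use table cells that are
  arithmetically consistent with that rounding of the printed means;
  cells evidently computed from unrounded (unpublished) means are
  excluded.
- **Treatment comparison** is a one-way fixed-effect Tukey HSD (α = 0.05)
  on per-plot means. The original campaign used a linear mixed-effects
  model with a soil-conductivity covariate; that covariate is not
  simulated and mixed-model fitting is standard off-the-shelf statistics,
  so the package deliberately ships the simpler fixed-effect comparison.
  Groups with a single replicate are excluded with a warning.
- **Estimator shape.** The retrieval + calibration core is exposed as a
  scikit-learn regressor (`ParametricLAI`: `fit` calibrates k̂, `predict`
  maps NDVI to LAI, `k=` freezes the coefficient for validation), so it
  composes with sklearn pipelines and model selection; the module-level
  functions wrap it for scalar/raster use.

## Numerical notes and limitations

- FVC ≥ 1 is rejected by the inversion rather than silently clipped; only
  `ndvi_to_fvc` clips, and it flags nothing below the soil endpoint
  (LAI = 0 there, making retrieval flat below NDVIₛ and steep near NDVIᵥ —
  the saturation behaviour expected of NDVI-based LAI).
- Geo-referencing is limited to single-band float32 GeoTIFFs in one
  projected metric CRS; geographic (degree) CRSs are rejected because
  plot geometry is metric. No reprojection or mosaicking.
- The problem sizes used by the shipped experiments (50-seed ordering
  study, 20-replicate scale study, n = 200 calibration recovery, 1200
  round-trip samples) are the package's default study sizes; all scale
  linearly if larger runs are wanted.
- k̂ is a ratio estimator; under additive LAI noise it is consistent but
  slightly biased at small n. The recovery experiment quantifies this at
  n = 200.
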