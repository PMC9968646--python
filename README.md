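# hailcanopy

Parametric leaf-area-index (LAI) retrieval and hail-defoliation damage
assessment for maize field trials, from satellite-like and UAV-like
multispectral reflectance.

Crop insurers and agronomists assess hail damage by how much leaf area a
storm removed. This package implements the remote-sensing side of that
assessment: it maps red/NIR surface reflectance to NDVI, NDVI to
fractional vegetation cover (FVC) with the dimidiate-pixel model, and FVC
to LAI by Beer–Lambert inversion,

    NDVI = (NIR − red)/(NIR + red)
    FVC  = (NDVI − NDVIₛ)/(NDVIᵥ − NDVIₛ)      clipped to [0, 1−ε]
    LAI  = −ln(1 − FVC)/k(θ)

with a single sensor-specific extinction coefficient k(θ) calibrated
against ceptometer ground truth by minimising RMSE (closed form
k̂ = Σcᵢ²/Σcᵢ·LAIᵢ with cᵢ = −ln(1−FVCᵢ)). Treatment plots are summarised
by zonal statistics over GeoTIFF rasters, compared to controls as percent
variation, and tested pairwise with Tukey HSD.

Because real campaign data of this kind is rarely public, the package
ships a synthetic field simulator: a two-year plot trial (Lo/Me/Hi
defoliation crossed with four phenological stages plus controls),
seasonal LAI trajectories with stage-dependent recovery, scene rendering
at 10 m and sub-metre ground resolution through the exact forward model,
and a virtual LP-80-style PAR ceptometer with the field averaging
protocol. Every downstream stage is testable end to end from a seed.

## Worked example

Simulate both trial years, calibrate k(θ) on year 1, validate frozen on
year 2, and summarise the first post-damage survey:

```python
from hailcanopy import (SeasonConfig, generate_experiment,
                        run_calibration_validation, survey_summary)

b1 = generate_experiment(SeasonConfig.year1(seed=1), "year1")
b2 = generate_experiment(SeasonConfig.year2(seed=2), "year2")
cal, val = run_calibration_validation(b1, b2, "satellite")
print(f"k_hat={cal.k_hat:.3f}  calibration R2={cal.r2:.2f} RMSE={cal.rmse:.2f} (n={cal.n})")
print(f"validation  R2={val.r2:.2f} RMSE={val.rmse:.2f} (n={val.n})")

summ = survey_summary(b2, "satellite", k_theta=cal.k_hat)
june = summ[(summ.date == "2021-06-09") & summ.stage.isin(["CTRL", "V8"])]
print(june[["stage", "intensity", "mean_ndvi", "mean_lai", "pct_vs_ctrl"]].to_string(index=False))
```

prints

```
k_hat=0.590  calibration R2=0.99 RMSE=0.13 (n=56)
validation  R2=0.99 RMSE=0.13 (n=117)
stage intensity  mean_ndvi  mean_lai  pct_vs_ctrl
   V8        Lo   0.474187  0.927463         -4.5
   V8        Me   0.455787  0.857590         -8.2
   V8        Hi   0.430645  0.768399        -13.2
 CTRL      none   0.496372  1.012893          0.0
```

The simulation truth for the satellite-like sensor is k = 0.59; the
calibration recovers it from 56 plot-level NDVI/ground-LAI pairs, and the
frozen coefficient transfers to the second season (validation RMSE in
LAI units). One week after the V8-stage damage the estimated plot LAI
still ranks Hi < Me < Lo < CTRL, the defoliation gradient the survey is
designed to detect; `pct_vs_ctrl` is the NDVI percent variation versus
the control plots, rounded to one decimal.

The same workflow is available from a shell:

```sh
hailcanopy simulate --year year1 --seed 1 --outdir runs/y1
hailcanopy simulate --year year2 --seed 2 --outdir runs/y2
hailcanopy report --bundle1 runs/y1 --bundle2 runs/y2 --sensor satellite --outdir runs/report
```

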