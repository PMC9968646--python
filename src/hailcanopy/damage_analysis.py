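"""Reporting layer: treatment summaries, percent variation vs control,
calibrate-then-validate workflow, group comparisons and damage maps."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .lai_model import (
    CalibrationResult,
    ParametricLAI,
    calibrate_k,
    fvc_to_lai,
    ndvi_to_fvc,
)
from .raster_io import PlotDef, ReflectanceRaster
from .synthetic_field import ExperimentBundle
from .vegindex import compute_ndvi, plot_ndvi_summary

__all__ = [
    "SurveySummary",
    "percent_variation",
    "collect_pairs",
    "run_calibration_validation",
    "survey_summary",
    "compare_treatments",
    "damage_map",
]


@dataclass(frozen=True)
class SurveySummary:
    """One treatment-group row of a survey summary table."""

    date: str
    sensor: str
    stage: str
    intensity: str
    mean_ndvi: float
    sd_ndvi: float
    mean_lai: float
    pct_vs_ctrl: float  # 1-decimal percent; 0.0 for CTRL rows


def percent_variation(treat_mean: float, ctrl_mean: float) -> float:
    """Relative variation vs control, in percent, rounded half-away-from-zero
    to 1 decimal: 100·(treat − ctrl)/ctrl."""
    if ctrl_mean == 0:
        raise ValueError("control mean must be nonzero")
    pct = 100.0 * (float(treat_mean) - float(ctrl_mean)) / float(ctrl_mean)
    return float(Decimal(repr(pct)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def collect_pairs(bundle: ExperimentBundle, sensor_name: str) -> pd.DataFrame:
    """Per-plot (mean NDVI, ground LAI) pairs over all survey dates.

    NDVI comes from zonal means of the rendered rasters; ground LAI is the
    plot mean of the ceptometer survey (mean over sampling points).
    """
    rows = []
    for dkey in bundle.dates:
        ndvi = compute_ndvi(
            bundle.raster(dkey, sensor_name, "red"),
            bundle.raster(dkey, sensor_name, "nir"),
        )
        summ = plot_ndvi_summary(ndvi, bundle.plots).set_index("plot_id")
        lai = bundle.ground[dkey].groupby("plot_id")["lai_cept"].mean()
        for plot in bundle.plots:
            rows.append(
                {
                    "date": dkey,
                    "plot_id": plot.plot_id,
                    "stage": plot.stage,
                    "intensity": plot.intensity,
                    "ndvi": summ.loc[plot.plot_id, "mean_ndvi"],
                    "lai_cept": lai.loc[plot.plot_id],
                }
            )
    return pd.DataFrame(rows).dropna(subset=["ndvi", "lai_cept"])


def run_calibration_validation(
    bundle_year1: ExperimentBundle,
    bundle_year2: ExperimentBundle,
    sensor_name: str,
) -> tuple[CalibrationResult, CalibrationResult]:
    """Calibrate k(θ) on the first season, validate frozen on the second.

    Returns (calibration, validation) results; the validation result
    carries the *frozen* year-1 k̂ with year-2 R²/RMSE/n — k is never
    re-fitted on validation data.
    """
    spec = bundle_year1.sensor_spec(sensor_name)
    pairs1 = collect_pairs(bundle_year1, sensor_name)
    if pairs1.empty:
        raise ValueError("no calibration pairs in the first-season bundle")
    cal = calibrate_k(
        pairs1[["ndvi", "lai_cept"]].to_numpy(),
        ndvi_soil=spec.ndvi_soil,
        ndvi_veg=spec.ndvi_veg,
    )
    pairs2 = collect_pairs(bundle_year2, sensor_name)
    if pairs2.empty:
        raise ValueError("no validation pairs in the second-season bundle")
    frozen = ParametricLAI(ndvi_soil=spec.ndvi_soil, ndvi_veg=spec.ndvi_veg, k=cal.k_hat)
    frozen.fit(pairs2["ndvi"].to_numpy(), pairs2["lai_cept"].to_numpy())
    return cal, frozen.result_()


def survey_summary(
    bundle: ExperimentBundle, sensor_name: str, k_theta: float | None = None
) -> pd.DataFrame:
    """Treatment-level NDVI / estimated-LAI summary with percent variation
    vs control, per survey date (the experiment's reporting table).

    Group means are taken over plot-level zonal means; percent variation
    is computed from the unrounded group means and rounded to 1 decimal.
    """
    spec = bundle.sensor_spec(sensor_name)
    if k_theta is not None:
        spec = spec.with_k(k_theta)
    rows: list[SurveySummary] = []
    for dkey in bundle.dates:
        ndvi = compute_ndvi(
            bundle.raster(dkey, sensor_name, "red"),
            bundle.raster(dkey, sensor_name, "nir"),
        )
        summ = plot_ndvi_summary(ndvi, bundle.plots)
        summ["lai_est"] = fvc_to_lai(
            ndvi_to_fvc(summ["mean_ndvi"].to_numpy(), spec), spec
        )
        grouped = summ.groupby(["stage", "intensity"], sort=False)
        stats_by_group = grouped.agg(
            mean_ndvi=("mean_ndvi", "mean"),
            sd_ndvi=("mean_ndvi", "std"),
            mean_lai=("lai_est", "mean"),
        )
        ctrl_ndvi = stats_by_group.loc[("CTRL", "none"), "mean_ndvi"]
        for (stage, intensity), rec in stats_by_group.iterrows():
            pct = (
                0.0
                if stage == "CTRL"
                else percent_variation(rec["mean_ndvi"], ctrl_ndvi)
            )
            rows.append(
                SurveySummary(
                    date=dkey, sensor=sensor_name, stage=stage, intensity=intensity,
                    mean_ndvi=float(rec["mean_ndvi"]),
                    sd_ndvi=float(rec["sd_ndvi"]) if np.isfinite(rec["sd_ndvi"]) else 0.0,
                    mean_lai=float(rec["mean_lai"]),
                    pct_vs_ctrl=pct,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def compare_treatments(per_plot: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-HSD pairwise comparison of treatment-group means.

    ``per_plot`` needs columns ``group`` and ``value`` (one row per plot).
    Groups with a single replicate are excluded with a warning.  Returns a
    table with one row per unordered group pair: mean difference, Tukey
    p-value and a significance flag at ``alpha``.
    """
    if not {"group", "value"}.issubset(per_plot.columns):
        raise ValueError("per_plot needs 'group' and 'value' columns")
    samples, names = [], []
    for name, sub in per_plot.groupby("group", sort=True):
        vals = sub["value"].to_numpy(dtype=float)
        if vals.size < 2:
            warnings.warn(f"group {name!r} has a single replicate; excluded", stacklevel=2)
            continue
        samples.append(vals)
        names.append(name)
    if len(samples) < 2:
        raise ValueError("need at least two groups with >=2 replicates")
    if np.ptp(np.concatenate(samples)) == 0:
        # identical values everywhere: no pair can differ
        res_p = np.ones((len(samples), len(samples)))
    else:
        res_p = stats.tukey_hsd(*samples).pvalue
    means = [float(np.mean(s)) for s in samples]
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = float(res_p[i, j])
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "mean_diff": means[i] - means[j],
                    "p_value": p,
                    "significant": bool(p < alpha),
                }
            )
    return pd.DataFrame(rows)


def damage_map(
    lai: ReflectanceRaster,
    plots: list[PlotDef] | None = None,
    ctrl_reference: float = 1.0,
) -> ReflectanceRaster:
    """Per-pixel LAI deficit vs a control reference, in percent.

    100·(LAI − ref)/ref; nodata propagates.  If ``plots`` is given, pixels
    outside all plot polygons are additionally masked out.
    """
    if ctrl_reference <= 0:
        raise ValueError("ctrl_reference must be positive")
    values = 100.0 * (lai.values - ctrl_reference) / ctrl_reference
    mask = lai.nodata_mask.copy()
    if plots:
        from .raster_io import zonal_mask

        inside = np.zeros(lai.shape, dtype=bool)
        for p in plots:
            inside |= zonal_mask(lai, p)
        mask |= ~inside
    values = np.where(mask, 0.0, values)
    return ReflectanceRaster(
        values=values, nodata_mask=mask, origin=lai.origin,
        pixel_size=lai.pixel_size, crs_epsg=lai.crs_epsg,
    )
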