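"""NDVI computation and per-plot NDVI summaries.

NDVI = (NIR - red) / (NIR + red) on co-registered reflectance grids.
Band-geometry fields on :class:`SensorSpec` are metadata only — inputs are
already band-integrated surface reflectance, so no spectral convolution is
performed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .raster_io import PlotDef, ReflectanceRaster, zonal_pixels

__all__ = [
    "SensorSpec",
    "SENTINEL2_LIKE",
    "UAV_LIKE",
    "compute_ndvi",
    "ndvi_values",
    "plot_ndvi_summary",
]


@dataclass(frozen=True)
class SensorSpec:
    """Band layout, FVC endpoints and extinction coefficient for one sensor.

    ``k_theta`` is the calibrated Beer-Lambert extinction coefficient used
    by the parametric LAI retrieval; ``ndvi_soil``/``ndvi_veg`` are the
    bare-soil and full-vegetation NDVI endpoints of the dimidiate-pixel
    fractional-cover scaling.
    """

    name: str
    red_center_nm: float
    red_width_nm: float
    nir_center_nm: float
    nir_width_nm: float
    k_theta: float
    ndvi_soil: float = 0.15
    ndvi_veg: float = 0.92

    def __post_init__(self) -> None:
        if not (-1 < self.ndvi_soil < self.ndvi_veg < 1):
            raise ValueError("require -1 < ndvi_soil < ndvi_veg < 1")
        if self.k_theta <= 0:
            raise ValueError("k_theta must be positive")

    def with_k(self, k_theta: float) -> "SensorSpec":
        return replace(self, k_theta=k_theta)


#: Satellite-like sensor: narrow-NIR band at 865 nm (B8A) and red at 665 nm
#: (B4); season-wide extinction coefficient 0.59.
SENTINEL2_LIKE = SensorSpec(
    name="satellite",
    red_center_nm=665.0,
    red_width_nm=30.0,
    nir_center_nm=865.0,
    nir_width_nm=20.0,
    k_theta=0.59,
)

#: UAV-like multispectral sensor: red 640-680 nm, NIR 770-810 nm;
#: season-wide extinction coefficient 0.37.
UAV_LIKE = SensorSpec(
    name="uav",
    red_center_nm=660.0,
    red_width_nm=40.0,
    nir_center_nm=790.0,
    nir_width_nm=40.0,
    k_theta=0.37,
)


def ndvi_values(red: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """Element-wise NDVI; NaN where red + nir == 0."""
    red = np.asarray(red, dtype=np.float64)
    nir = np.asarray(nir, dtype=np.float64)
    total = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total != 0, (nir - red) / np.where(total == 0, 1, total), np.nan)
    return out


def compute_ndvi(red: ReflectanceRaster, nir: ReflectanceRaster) -> ReflectanceRaster:
    """NDVI raster from co-registered red and NIR reflectance rasters.

    Pixels where either band is nodata, or where red + nir == 0, become
    nodata (a zero reflectance sum indicates missing data, not vegetation).
    """
    if not red.same_grid(nir):
        raise ValueError("red and nir rasters are not on the same grid")
    total = nir.values + red.values
    invalid = red.nodata_mask | nir.nodata_mask | (total == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = (nir.values - red.values) / np.where(total == 0, 1.0, total)
    ndvi = np.where(invalid, 0.0, ndvi)
    return ReflectanceRaster(
        values=ndvi,
        nodata_mask=invalid,
        origin=red.origin,
        pixel_size=red.pixel_size,
        crs_epsg=red.crs_epsg,
    )


def plot_ndvi_summary(
    ndvi: ReflectanceRaster, plots: list[PlotDef]
) -> pd.DataFrame:
    """Per-plot NDVI mean/sd/pixel count.

    The standard deviation uses the n-1 denominator; plots with no valid
    pixel are reported with NaN statistics rather than dropped.
    """
    rows = []
    for plot in plots:
        px = zonal_pixels(ndvi, plot)
        n = px.size
        rows.append(
            {
                "plot_id": plot.plot_id,
                "stage": plot.stage,
                "intensity": plot.intensity,
                "mean_ndvi": float(np.mean(px)) if n else np.nan,
                "sd_ndvi": float(np.std(px, ddof=1)) if n > 1 else (0.0 if n == 1 else np.nan),
                "n_pixels": n,
            }
        )
    return pd.DataFrame(rows)
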