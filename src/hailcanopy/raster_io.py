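"""Georeferenced raster and plot-polygon I/O plus zonal pixel extraction.

Rasters are single-band float32 GeoTIFFs in a projected (metric) CRS with an
explicit nodata tag.  Plot polygons travel as a GeoJSON FeatureCollection
whose features carry ``plot_id``, ``stage``, ``intensity`` and ``side_m``
properties.  Zonal extraction uses a pixel-center-in-polygon rule with no
area weighting, which keeps plot statistics deterministic under raster/plot
misalignment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import shapely
from shapely.geometry import Polygon, box, shape, mapping

__all__ = [
    "ReflectanceRaster",
    "PlotDef",
    "STAGES",
    "INTENSITIES",
    "read_raster",
    "write_raster",
    "zonal_pixels",
    "zonal_mask",
    "read_plots",
    "write_plots",
]

STAGES = ("CTRL", "V8", "F", "M", "D")
INTENSITIES = ("none", "Lo", "Me", "Hi")

# TIFF tag codes used for georeferencing
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_NODATA = 42113

_DEFAULT_NODATA = -9999.0


@dataclass
class ReflectanceRaster:
    """Single-band georeferenced reflectance grid.

    Parameters
    ----------
    values : ndarray of shape (rows, cols)
        Reflectance, dimensionless; valid pixels expected in [0, 1.2]
        (the headroom allows radiometric-calibration overshoot).
    nodata_mask : boolean ndarray, same shape
        True where the pixel is invalid.
    origin : (x, y)
        Projected coordinates (m) of the upper-left corner of the
        upper-left pixel.
    pixel_size : (dx, dy)
        Pixel size in metres; ``dx > 0``, ``dy > 0``.  Row index increases
        southwards, so the y coordinate of row r's upper edge is
        ``origin[1] - r * dy``.
    crs_epsg : int
        EPSG code of a projected, metric CRS.
    """

    values: np.ndarray
    nodata_mask: np.ndarray
    origin: tuple[float, float]
    pixel_size: tuple[float, float]
    crs_epsg: int = 32632

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.values.shape != self.nodata_mask.shape:
            raise ValueError("values and nodata_mask shapes differ")
        dx, dy = self.pixel_size
        if dx <= 0 or dy <= 0:
            raise ValueError("pixel sizes must be positive")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError("valid pixels must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint in metres."""
        rows, cols = self.values.shape
        x0, y0 = self.origin
        dx, dy = self.pixel_size
        return (x0, y0 - rows * dy, x0 + cols * dx, y0)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate arrays of all pixel centers."""
        rows, cols = self.values.shape
        x0, y0 = self.origin
        dx, dy = self.pixel_size
        xs = x0 + (np.arange(cols) + 0.5) * dx
        ys = y0 - (np.arange(rows) + 0.5) * dy
        return np.meshgrid(xs, ys)

    def same_grid(self, other: "ReflectanceRaster") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.pixel_size, other.pixel_size)
            and self.crs_epsg == other.crs_epsg
        )


@dataclass
class PlotDef:
    """A square trial plot with its treatment labels.

    ``stage`` is the maize phenological stage at which simulated hail
    damage was applied (CTRL = undamaged control, V8 = 8th leaf,
    F = flowering, M = early milky, D = dough); ``intensity`` is the
    defoliation class (Lo/Me/Hi, 'none' for controls).
    """

    plot_id: str
    polygon: Polygon
    stage: str = "CTRL"
    intensity: str = "none"
    side_m: float = 20.0

    def __post_init__(self) -> None:
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(self.polygon)
        if not self.polygon.is_valid or not self.polygon.is_simple:
            raise ValueError(f"plot {self.plot_id}: polygon must be simple")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.intensity not in INTENSITIES:
            raise ValueError(f"unknown intensity {self.intensity!r}")
        if (self.stage == "CTRL") != (self.intensity == "none"):
            raise ValueError(
                f"plot {self.plot_id}: stage CTRL iff intensity 'none'"
            )


def _geokeys_epsg(epsg: int) -> tuple[int, ...]:
    # GTModelTypeGeoKey=1 (projected), GTRasterTypeGeoKey=1 (pixel-is-area),
    # ProjectedCSTypeGeoKey=<epsg>
    return (1, 1, 0, 3, 1024, 0, 1, 1, 1025, 0, 1, 1, 3072, 0, 1, epsg)


def write_raster(path: str | Path, raster: ReflectanceRaster) -> Path:
    """Write a ReflectanceRaster as a single-band float32 GeoTIFF."""
    path = Path(path)
    values = raster.values.astype(np.float32).copy()
    values[raster.nodata_mask] = _DEFAULT_NODATA
    dx, dy = raster.pixel_size
    x0, y0 = raster.origin
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(dx), float(dy), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(x0), float(y0), 0.0)),
        (_TAG_GEOKEYS, "H", 16, _geokeys_epsg(raster.crs_epsg)),
        (_TAG_NODATA, "s", 0, str(_DEFAULT_NODATA)),
    ]
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, values, extratags=extratags)
    return path


def read_raster(path: str | Path) -> ReflectanceRaster:
    """Read a single-band georeferenced GeoTIFF.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        If the raster is multi-band, ungeoreferenced, or uses a
        geographic (degree-unit) CRS — plot geometry is metric.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        arr = page.asarray()
        if arr.ndim != 2:
            raise ValueError("expected a single-band raster")
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError("raster lacks georeferencing tags")
        dx, dy, _ = tags[_TAG_PIXEL_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
        x0, y0 = tie[3], tie[4]
        epsg = 0
        if _TAG_GEOKEYS in tags:
            keys = tags[_TAG_GEOKEYS].value
            kv = {keys[i]: keys[i + 3] for i in range(4, len(keys), 4)}
            model_type = kv.get(1024, 0)
            if model_type == 2 or 2048 in kv:  # geographic model / GCS key
                raise ValueError(
                    "geographic (degree-unit) CRS not supported; "
                    "reproject to a metric CRS first"
                )
            epsg = kv.get(3072, 0)
        nodata = _DEFAULT_NODATA
        if _TAG_NODATA in tags:
            nodata = float(str(tags[_TAG_NODATA].value).strip("\x00 "))
    values = arr.astype(np.float64)
    mask = ~np.isfinite(values) | np.isclose(values, nodata)
    values[mask] = np.nan
    return ReflectanceRaster(
        values=np.where(mask, 0.0, values),
        nodata_mask=mask,
        origin=(float(x0), float(y0)),
        pixel_size=(float(dx), float(dy)),
        crs_epsg=int(epsg) if epsg else 32632,
    )


def zonal_mask(raster: ReflectanceRaster, plot: PlotDef) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the plot polygon.

    Pixels on the polygon boundary follow shapely's ``contains`` (strict
    interior) semantics; the nodata mask is *not* applied here.
    """
    xmin, ymin, xmax, ymax = raster.bounds
    if not plot.polygon.intersects(box(xmin, ymin, xmax, ymax)):
        warnings.warn(
            f"plot {plot.plot_id} does not intersect the raster extent",
            stacklevel=2,
        )
        return np.zeros(raster.shape, dtype=bool)
    x0, y0 = raster.origin
    dx, dy = raster.pixel_size
    pxmin, pymin, pxmax, pymax = plot.polygon.bounds
    # restrict the candidate window to the polygon bounding box
    c0 = max(0, int(np.floor((pxmin - x0) / dx - 0.5)))
    c1 = min(raster.shape[1], int(np.ceil((pxmax - x0) / dx + 0.5)))
    r0 = max(0, int(np.floor((y0 - pymax) / dy - 0.5)))
    r1 = min(raster.shape[0], int(np.ceil((y0 - pymin) / dy + 0.5)))
    mask = np.zeros(raster.shape, dtype=bool)
    if c1 <= c0 or r1 <= r0:
        return mask
    xs = x0 + (np.arange(c0, c1) + 0.5) * dx
    ys = y0 - (np.arange(r0, r1) + 0.5) * dy
    X, Y = np.meshgrid(xs, ys)
    mask[r0:r1, c0:c1] = shapely.contains_xy(plot.polygon, X, Y)
    return mask


def zonal_pixels(raster: ReflectanceRaster, plot: PlotDef) -> np.ndarray:
    """Valid pixel values whose centers fall inside the plot polygon.

    Returns an empty array (with a warning) when the plot does not
    intersect the raster extent; nodata pixels are dropped.
    """
    mask = zonal_mask(raster, plot) & ~raster.nodata_mask
    return raster.values[mask]


def write_plots(path: str | Path, plots: list[PlotDef], crs_epsg: int = 32632) -> Path:
    """Write plots as a GeoJSON FeatureCollection."""
    features = []
    for p in plots:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(p.polygon),
                "properties": {
                    "plot_id": p.plot_id,
                    "stage": p.stage,
                    "intensity": p.intensity,
                    "side_m": p.side_m,
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": f"EPSG:{crs_epsg}"}},
        "features": features,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=1))
    return path


def read_plots(path: str | Path) -> list[PlotDef]:
    """Read a plots GeoJSON FeatureCollection written by :func:`write_plots`."""
    doc = json.loads(Path(path).read_text())
    plots = []
    for feat in doc["features"]:
        props = feat["properties"]
        plots.append(
            PlotDef(
                plot_id=str(props["plot_id"]),
                polygon=shape(feat["geometry"]),
                stage=props.get("stage", "CTRL"),
                intensity=props.get("intensity", "none"),
                side_m=float(props.get("side_m", 20.0)),
            )
        )
    return plots
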