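import numpy as np
import pytest
from shapely.geometry import Polygon

from hailcanopy import PlotDef, ReflectanceRaster, SeasonConfig


@pytest.fixture
def raster_factory():
    """Build a simple raster: constant or given values, optional nodata."""

    def make(values, origin=(0.0, 100.0), pixel=10.0, nodata_mask=None, epsg=32632):
        values = np.asarray(values, dtype=float)
        if nodata_mask is None:
            nodata_mask = np.zeros_like(values, dtype=bool)
        return ReflectanceRaster(
            values=values,
            nodata_mask=nodata_mask,
            origin=origin,
            pixel_size=(pixel, pixel),
            crs_epsg=epsg,
        )

    return make


@pytest.fixture
def square_plot_factory():
    def make(x0, y0, side=20.0, plot_id="P1", stage="CTRL", intensity="none"):
        poly = Polygon([(x0, y0), (x0 + side, y0), (x0 + side, y0 - side), (x0, y0 - side)])
        return PlotDef(plot_id, poly, stage, intensity, side)

    return make


@pytest.fixture
def fast_season():
    """Single-survey-date season config for quick end-to-end tests."""
    return SeasonConfig(seed=11, survey_dates=("2021-06-09",))
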