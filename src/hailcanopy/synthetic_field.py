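"""Synthetic two-year hail-defoliation experiment at desk scale.

Generates everything downstream stages need without any field data: a plot
layout (square 20 m / 60 m plots on a projected grid), true LAI
trajectories per plot (logistic rise to an early-July peak near 6 m² m⁻²,
exponential senescence, stage- and intensity-specific defoliation with
full recovery after early V8 damage and persistent deficits after
flowering/milky/dough damage), red+NIR reflectance rasters at satellite-
like and UAV-like ground resolutions rendered through the exact forward
model, and ceptometer ground surveys with the 3-readings-of-5 averaging
protocol.

Randomness is derived from one experiment seed expanded into keyed
substreams (per plot / date / sensor), so regenerating with the same seed
reproduces every file byte-for-byte and adding a survey date does not
perturb earlier draws.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from datetime import date as Date
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .ceptometer import simulate_ground_survey
from .lai_model import lai_to_ndvi_forward
from .raster_io import (
    PlotDef,
    ReflectanceRaster,
    read_plots,
    read_raster,
    write_plots,
    write_raster,
    zonal_mask,
)
from .vegindex import SENTINEL2_LIKE, UAV_LIKE, SensorSpec

__all__ = [
    "SeasonConfig",
    "ExperimentBundle",
    "true_lai",
    "control_lai",
    "render_scene",
    "make_plot_layout",
    "generate_experiment",
    "load_bundle",
]

_DATE_FMT = "%Y-%m-%d"


def _parse_date(d) -> Date:
    return d if isinstance(d, Date) else Date.fromisoformat(str(d))


@dataclass
class SeasonConfig:
    """All knobs of one simulated cropping season.

    Defaults reproduce the second trial year: sowing April 22, control LAI
    ≈ 1 at the June 9 survey, peak 6.0 m² m⁻² on July 7, then senescence;
    damage windows June 2 (V8), July 13 (F), July 19 (M), August 9 (D);
    surveys June 9, July 28, August 25.  Defoliation classes span the
    10–40 % range (Lo 15 %, Me 25 %, Hi 40 %).
    """

    sowing_date: Date = Date(2021, 4, 22)
    peak_date: Date = Date(2021, 7, 7)
    peak_lai: float = 6.0
    growth_rate: float = 0.23  # d⁻¹, logistic slope of the rise
    growth_midpoint_days: int = 21  # inflection this many days before peak
    senescence_rate: float = 0.02  # d⁻¹, exponential decay after peak
    damage_dates: dict[str, Date] = field(
        default_factory=lambda: {
            "V8": Date(2021, 6, 2),
            "F": Date(2021, 7, 13),
            "M": Date(2021, 7, 19),
            "D": Date(2021, 8, 9),
        }
    )
    survey_dates: tuple[Date, ...] = (
        Date(2021, 6, 9),
        Date(2021, 7, 28),
        Date(2021, 8, 25),
    )
    defoliation_fraction: dict[str, float] = field(
        default_factory=lambda: {"Lo": 0.15, "Me": 0.25, "Hi": 0.40}
    )
    recovery_half_life_v8: float = 8.0  # days
    ndvi_noise_sd: float = 0.02  # per-pixel white sensor noise
    spatial_cv: float = 0.08  # amplitude of the smooth within-plot LAI field
    lai_noise_sd: float = 0.10  # point-to-point ground LAI variability
    par_noise_sd_frac: float = 0.02  # ceptometer sub-measurement PAR noise
    points_per_plot: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.sowing_date = _parse_date(self.sowing_date)
        self.peak_date = _parse_date(self.peak_date)
        self.damage_dates = {s: _parse_date(d) for s, d in self.damage_dates.items()}
        self.survey_dates = tuple(_parse_date(d) for d in self.survey_dates)
        f = self.defoliation_fraction
        order = [f.get("Lo"), f.get("Me"), f.get("Hi")]
        if any(v is None for v in order) or not (order[0] < order[1] < order[2]):
            raise ValueError("defoliation fractions must satisfy Lo < Me < Hi")
        if not all(0.10 <= v <= 0.40 for v in order):
            raise ValueError("defoliation fractions must lie in [0.10, 0.40]")
        if "V8" in self.damage_dates and self.peak_date <= self.damage_dates["V8"]:
            raise ValueError("peak_date must fall after the V8 damage date")

    @classmethod
    def year1(cls, **overrides) -> "SeasonConfig":
        """First trial year: sown March 14, V8 and D damage stages only."""
        kwargs = dict(
            sowing_date=Date(2020, 3, 14),
            peak_date=Date(2020, 7, 7),
            damage_dates={"V8": Date(2020, 6, 17), "D": Date(2020, 9, 16)},
            survey_dates=(
                Date(2020, 6, 19),
                Date(2020, 7, 14),
                Date(2020, 8, 6),
                Date(2020, 9, 17),
            ),
            points_per_plot=3,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def year2(cls, **overrides) -> "SeasonConfig":
        return cls(**overrides)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sowing_date"] = self.sowing_date.isoformat()
        d["peak_date"] = self.peak_date.isoformat()
        d["damage_dates"] = {s: v.isoformat() for s, v in self.damage_dates.items()}
        d["survey_dates"] = [v.isoformat() for v in self.survey_dates]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SeasonConfig":
        return cls(**d)


def _substream(seed: int, *key) -> np.random.Generator:
    """Deterministic child RNG keyed by arbitrary labels."""
    digest = zlib.crc32("/".join(str(k) for k in key).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, digest]))


def control_lai(date, cfg: SeasonConfig) -> float:
    """Undamaged-canopy LAI on a date: normalised logistic rise that hits
    ``peak_lai`` exactly at ``peak_date``, exponential decline after."""
    date = _parse_date(date)
    t = (date - cfg.sowing_date).days
    if t < 0:
        raise ValueError("date precedes sowing")
    tp = (cfg.peak_date - cfg.sowing_date).days
    if t <= tp:
        tm = tp - cfg.growth_midpoint_days
        s = 1.0 / (1.0 + np.exp(-cfg.growth_rate * (t - tm)))
        s_peak = 1.0 / (1.0 + np.exp(-cfg.growth_rate * (tp - tm)))
        return float(cfg.peak_lai * s / s_peak)
    return float(cfg.peak_lai * np.exp(-cfg.senescence_rate * (t - tp)))


def true_lai(plot: PlotDef, date, cfg: SeasonConfig) -> float:
    """True LAI of a plot on a date, with its treatment applied.

    Damaged plots drop to (1 - defoliation) × control at the damage date.
    V8 plots relax exponentially back to the control curve with the
    configured half-life (new-leaf emission); F/M/D plots keep the
    proportional deficit through senescence.
    """
    date = _parse_date(date)
    base = control_lai(date, cfg)
    if plot.stage == "CTRL":
        return base
    dmg = cfg.damage_dates.get(plot.stage)
    if dmg is None:
        raise ValueError(f"no damage date configured for stage {plot.stage}")
    if date < dmg:
        return base
    frac = cfg.defoliation_fraction[plot.intensity]
    if plot.stage == "V8":
        elapsed = (date - dmg).days
        deficit = frac * 0.5 ** (elapsed / cfg.recovery_half_life_v8)
    else:
        deficit = frac
    return float(base * (1.0 - deficit))


def _plot_gradient(xs: np.ndarray, ys: np.ndarray, plot: PlotDef, cfg: SeasonConfig) -> np.ndarray:
    """Smooth zero-mean (over the plot) relative LAI field, one full
    sinusoid period per plot side with per-plot random phases."""
    if cfg.spatial_cv == 0:
        return np.zeros(np.broadcast(xs, ys).shape)
    rng = _substream(cfg.seed, "spatial", plot.plot_id)
    phix, phiy = rng.uniform(0, 2 * np.pi, size=2)
    x0, y0, _, _ = plot.polygon.bounds
    side = plot.side_m
    gx = np.sin(2 * np.pi * (xs - x0) / side + phix)
    gy = np.sin(2 * np.pi * (ys - y0) / side + phiy)
    return cfg.spatial_cv * (gx + gy) / 2.0


def render_scene(
    plots: list[PlotDef],
    date,
    cfg: SeasonConfig,
    sensor: SensorSpec,
    pixel_m: float,
    margin_m: float = 20.0,
    crs_epsg: int = 32632,
) -> tuple[ReflectanceRaster, ReflectanceRaster]:
    """Render red and NIR reflectance rasters of the field on one date.

    Per pixel inside a plot, NDVI = forward(true LAI × (1 + smooth
    within-plot field)) + white sensor noise; outside plots the scene is
    bare soil at the sensor's soil endpoint.  The red/NIR pair is
    synthesised at constant brightness red + nir = 0.6, so the NDVI of the
    pair reproduces the target exactly.  Deterministic given cfg.seed.
    """
    if pixel_m <= 0:
        raise ValueError("pixel_m must be positive")
    date = _parse_date(date)
    xs0 = min(p.polygon.bounds[0] for p in plots) - margin_m
    ys0 = min(p.polygon.bounds[1] for p in plots) - margin_m
    xs1 = max(p.polygon.bounds[2] for p in plots) + margin_m
    ys1 = max(p.polygon.bounds[3] for p in plots) + margin_m
    cols = int(np.ceil((xs1 - xs0) / pixel_m))
    rows = int(np.ceil((ys1 - ys0) / pixel_m))
    origin = (xs0, ys0 + rows * pixel_m)

    template = ReflectanceRaster(
        values=np.zeros((rows, cols)),
        nodata_mask=np.zeros((rows, cols), dtype=bool),
        origin=origin,
        pixel_size=(pixel_m, pixel_m),
        crs_epsg=crs_epsg,
    )
    X, Y = template.pixel_centers()

    ndvi = np.full((rows, cols), sensor.ndvi_soil, dtype=np.float64)
    for plot in plots:
        mask = zonal_mask(template, plot)
        if not mask.any():
            continue
        lai_plot = true_lai(plot, date, cfg)
        lai_px = lai_plot * (1.0 + _plot_gradient(X[mask], Y[mask], plot, cfg))
        ndvi[mask] = lai_to_ndvi_forward(np.clip(lai_px, 0.0, None), sensor)
    if cfg.ndvi_noise_sd > 0:
        rng = _substream(cfg.seed, "sensor-noise", sensor.name, date.isoformat())
        ndvi = ndvi + rng.normal(0.0, cfg.ndvi_noise_sd, size=ndvi.shape)
    ndvi = np.clip(ndvi, -0.99, 0.99)

    brightness = 0.6  # red + nir
    red = (1.0 - ndvi) * brightness / 2.0
    nir = (1.0 + ndvi) * brightness / 2.0
    nodata = np.zeros((rows, cols), dtype=bool)
    mk = lambda v: ReflectanceRaster(
        values=v, nodata_mask=nodata.copy(), origin=origin,
        pixel_size=(pixel_m, pixel_m), crs_epsg=crs_epsg,
    )
    return mk(red), mk(nir)


def make_plot_layout(year_mode: str, origin_xy: tuple[float, float] = (700000.0, 5045000.0)) -> list[PlotDef]:
    """Square-plot grid for one trial year.

    year1: V8 and D stages × Lo/Me/Hi × 2 replicates of 60 m plots plus
    two 60 m controls (14 plots).  year2: V8/F/M/D × Lo/Me/Hi × 3
    replicates (reps 1–2 on 20 m, rep 3 on 60 m) plus three controls
    (39 plots).  Plots sit on a 70 m pitch with 10 m alleys.
    """
    x0, y0 = origin_xy
    pitch = 70.0
    plots: list[PlotDef] = []

    def add(plot_id, col, row, stage, intensity, side):
        px = x0 + col * pitch
        py = y0 - row * pitch
        poly = Polygon(
            [(px, py), (px + side, py), (px + side, py - side), (px, py - side)]
        )
        plots.append(PlotDef(plot_id, poly, stage, intensity, side))

    if year_mode == "year1":
        col = 0
        for stage in ("V8", "D"):
            for intensity in ("Lo", "Me", "Hi"):
                for rep in (1, 2):
                    add(f"{stage}-{intensity}-{rep}", col, 0 if rep == 1 else 1,
                        stage, intensity, 60.0)
                col += 1
        add("CTRL-1", col, 0, "CTRL", "none", 60.0)
        add("CTRL-2", col, 1, "CTRL", "none", 60.0)
    elif year_mode == "year2":
        for row, stage in enumerate(("V8", "F", "M", "D")):
            col = 0
            for intensity in ("Lo", "Me", "Hi"):
                for rep in (1, 2, 3):
                    side = 60.0 if rep == 3 else 20.0
                    add(f"{stage}-{intensity}-{rep}", col, row, stage, intensity, side)
                    col += 1
        for rep in (1, 2, 3):
            side = 60.0 if rep == 3 else 20.0
            add(f"CTRL-{rep}", 3 * rep - 2, 4, "CTRL", "none", side)
    else:
        raise ValueError("year_mode must be 'year1' or 'year2'")
    return plots


@dataclass
class ExperimentBundle:
    """One simulated season: plots, rasters, ground surveys and truth."""

    cfg: SeasonConfig
    year_mode: str
    plots: list[PlotDef]
    rasters: dict[tuple[str, str, str], ReflectanceRaster]  # (date, sensor, band)
    ground: dict[str, pd.DataFrame]  # date -> ceptometer table
    truth: dict[str, pd.DataFrame]  # date -> per-plot true LAI
    outdir: Path | None = None
    sensors: tuple[SensorSpec, ...] = (SENTINEL2_LIKE, UAV_LIKE)

    @property
    def dates(self) -> list[str]:
        return [d.isoformat() for d in self.cfg.survey_dates]

    def raster(self, date: str, sensor: str, band: str) -> ReflectanceRaster:
        return self.rasters[(date, sensor, band)]

    def sensor_spec(self, name: str) -> SensorSpec:
        for s in self.sensors:
            if s.name == name:
                return s
        raise KeyError(name)


def generate_experiment(
    cfg: SeasonConfig,
    year_mode: str = "year2",
    outdir: str | Path | None = None,
    sensors: tuple[SensorSpec, ...] = (SENTINEL2_LIKE, UAV_LIKE),
    pixel_m: dict[str, float] | None = None,
) -> ExperimentBundle:
    """Simulate one full season and (optionally) write the bundle to disk.

    Bundle layout on disk: ``plots.geojson``,
    ``rasters/<date>_<sensor>_<band>.tif``, ``ground/<date>.csv``,
    ``truth/<date>.csv`` and ``config.json``.  Default ground resolutions
    are 10 m for the satellite-like sensor and 0.5 m for the UAV-like
    sensor (a desk-scale stand-in for the 0.04 m flight GSD).
    """
    pixel_m = pixel_m or {"satellite": 10.0, "uav": 0.5}
    plots = make_plot_layout(year_mode)
    rasters: dict[tuple[str, str, str], ReflectanceRaster] = {}
    ground: dict[str, pd.DataFrame] = {}
    truth: dict[str, pd.DataFrame] = {}

    for date in cfg.survey_dates:
        dkey = date.isoformat()
        truth[dkey] = pd.DataFrame(
            {
                "date": dkey,
                "plot_id": [p.plot_id for p in plots],
                "stage": [p.stage for p in plots],
                "intensity": [p.intensity for p in plots],
                "true_lai": [true_lai(p, date, cfg) for p in plots],
            }
        )
        for sensor in sensors:
            red, nir = render_scene(plots, date, cfg, sensor, pixel_m[sensor.name])
            rasters[(dkey, sensor.name, "red")] = red
            rasters[(dkey, sensor.name, "nir")] = nir
        point_rng = _substream(cfg.seed, "ground-points", dkey)
        by_plot = {}
        for p in plots:
            base = true_lai(p, date, cfg)
            jitter = point_rng.normal(0.0, cfg.lai_noise_sd) if cfg.lai_noise_sd else 0.0
            by_plot[p.plot_id] = max(base + jitter, 0.0)
        ground[dkey] = simulate_ground_survey(
            by_plot,
            points_per_plot=cfg.points_per_plot,
            par_noise_sd_frac=cfg.par_noise_sd_frac,
            seed=_substream(cfg.seed, "ceptometer", dkey),
            date=dkey,
        )

    bundle = ExperimentBundle(
        cfg=cfg, year_mode=year_mode, plots=plots,
        rasters=rasters, ground=ground, truth=truth,
        outdir=Path(outdir) if outdir else None, sensors=tuple(sensors),
    )
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: ExperimentBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_plots(outdir / "plots.geojson", bundle.plots)
    for (dkey, sensor, band), raster in bundle.rasters.items():
        write_raster(outdir / "rasters" / f"{dkey}_{sensor}_{band}.tif", raster)
    for dkey, df in bundle.ground.items():
        (outdir / "ground").mkdir(exist_ok=True)
        df.to_csv(outdir / "ground" / f"{dkey}.csv", index=False)
    for dkey, df in bundle.truth.items():
        (outdir / "truth").mkdir(exist_ok=True)
        df.to_csv(outdir / "truth" / f"{dkey}.csv", index=False)
    meta = {"year_mode": bundle.year_mode, "season": bundle.cfg.to_dict()}
    (outdir / "config.json").write_text(json.dumps(meta, indent=1))


def load_bundle(outdir: str | Path) -> ExperimentBundle:
    """Re-load a bundle written by :func:`generate_experiment`."""
    outdir = Path(outdir)
    meta = json.loads((outdir / "config.json").read_text())
    cfg = SeasonConfig.from_dict(meta["season"])
    plots = read_plots(outdir / "plots.geojson")
    rasters = {}
    for path in sorted((outdir / "rasters").glob("*.tif")):
        dkey, sensor, band = path.stem.rsplit("_", 2)
        rasters[(dkey, sensor, band)] = read_raster(path)
    ground = {
        p.stem: pd.read_csv(p, dtype={"plot_id": str})
        for p in sorted((outdir / "ground").glob("*.csv"))
    }
    truth = {
        p.stem: pd.read_csv(p, dtype={"plot_id": str})
        for p in sorted((outdir / "truth").glob("*.csv"))
    }
    return ExperimentBundle(
        cfg=cfg, year_mode=meta["year_mode"], plots=plots,
        rasters=rasters, ground=ground, truth=truth, outdir=outdir,
    )
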