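"""End-to-end orchestration: composite -> season -> mask -> statistics -> report.

``run_pipeline`` replays the full analysis on any input bundle (paths to
NetCDF stacks and TIFF masks, or in-memory objects): monthly compositing
where the index stack is daily, growing-season annual aggregation, the
unchanged-wetland mask, per-pixel trend and Hurst maps with area
fractions, basin/region sequential Mann–Kendall change points, per-pixel
correlation fields for each climate variable and lag, regional tables
with partial correlations and period splits, and zonal profiles with
turning points. Analysis stages are deterministic; any randomness lives
only in synthetic-data generation upstream, so reruns with the same
config byte-reproduce the JSON report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import association, profiles, raster, trend
from .hurst import hurst_map
from .sqmk import sqmk as sqmk_analysis
from .raster import RasterStack, WetlandMask

logger = logging.getLogger("rastertrend")

__all__ = ["RunConfig", "validate_inputs", "run_pipeline"]


@dataclass
class RunConfig:
    """Settings for one pipeline run (mirrors the study defaults)."""

    ndvi_path: str = ""
    climate_paths: dict = field(default_factory=dict)      # var -> path
    mask_paths: list = field(default_factory=list)          # 1 or 2 epochs
    region_mask_paths: dict = field(default_factory=dict)   # name -> path
    season_months: tuple = (5, 6, 7, 8, 9)
    alpha: float = 0.05
    start_year: int = 1982
    end_year: int = 2020
    period_splits: list = field(default_factory=lambda: [(1982, 2000), (2000, 2020)])
    lags: tuple = (0, 1, 2)
    band_width: float = 0.5
    precip_reducer: str = "sum"
    out_dir: str = "out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.season_months) <= set(range(1, 13)):
            raise ValueError("season months must lie in 1..12")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for (y0, y1) in self.period_splits:
            if y0 < self.start_year or y1 > self.end_year:
                raise ValueError(f"period {y0}-{y1} outside study years")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "period_splits" in raw:
            raw["period_splits"] = [tuple(p) for p in raw["period_splits"]]
        for key in ("season_months", "lags"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_inputs(config: RunConfig) -> dict:
    """Check the bundle without running; returns {'errors': [...], 'warnings': [...]}."""
    errors: list[str] = []
    warnings_: list[str] = []
    ndvi = None
    if not config.ndvi_path:
        errors.append("no index stack path configured")
    elif not Path(config.ndvi_path).exists():
        errors.append(f"index stack not found: {config.ndvi_path}")
    else:
        ndvi = raster.read_stack(config.ndvi_path)
        years = np.unique(ndvi.years)
        want = np.arange(config.start_year, config.end_year + 1)
        missing = np.setdiff1d(want, years)
        if missing.size:
            warnings_.append(f"index stack missing years {missing.tolist()}")
    for var, path in config.climate_paths.items():
        if not Path(path).exists():
            errors.append(f"climate stack not found: {path} ({var})")
        elif ndvi is not None:
            st = raster.read_stack(path, var)
            if not ndvi.same_grid(st):
                warnings_.append(
                    f"{var} grid differs from index grid; will resample"
                )
    for path in config.mask_paths:
        if not Path(path).exists():
            errors.append(f"mask not found: {path}")
        elif ndvi is not None:
            m = raster.read_mask(path)
            if m.values.shape != ndvi.shape[1:]:
                errors.append(
                    f"mask {path} shape {m.values.shape} does not match "
                    f"index grid {ndvi.shape[1:]}"
                )
            elif not m.values.any():
                errors.append(f"mask {path} is empty")
    return {"errors": errors, "warnings": warnings_}


def _prepare_annual(stack: RasterStack, config: RunConfig,
                    reducer: str) -> RasterStack:
    """Daily -> monthly MVC if needed, then growing-season annual layers."""
    per_year = stack.shape[0] / max(np.unique(stack.years).size, 1)
    if per_year > 13:
        stack = raster.mvc_monthly(stack)
        per_year = stack.shape[0] / max(np.unique(stack.years).size, 1)
    if per_year > 1.5:
        stack = raster.growing_season_annual(
            stack, months=config.season_months, reducer=reducer
        )
    return stack.subset_years(config.start_year, config.end_year)


def run_pipeline(
    config: RunConfig,
    ndvi: RasterStack | None = None,
    climate: dict[str, RasterStack] | None = None,
    masks: list[WetlandMask] | None = None,
    region_masks: dict[str, WetlandMask] | None = None,
    write_outputs: bool = True,
) -> dict:
    """Run every stage and return (and optionally write) the JSON report.

    Inputs may be passed in memory; anything not supplied is read from the
    paths in ``config``.
    """
    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    if ndvi is None:
        ndvi = raster.read_stack(config.ndvi_path)
    if climate is None:
        climate = {v: raster.read_stack(p, v)
                   for v, p in config.climate_paths.items()}
    if masks is None:
        masks = [raster.read_mask(p) for p in config.mask_paths]
    if region_masks is None:
        region_masks = {name: raster.read_mask(p)
                        for name, p in config.region_mask_paths.items()}

    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    def stage(name):
        logger.info("stage: %s", name)
        return report["stages"].setdefault(name, {})

    try:
        # -- compositing / seasonal aggregation --------------------------
        s = stage("prepare")
        ndvi_annual = _prepare_annual(ndvi, config, reducer="mean")
        climate_annual = {}
        for var, stk in climate.items():
            reducer = config.precip_reducer if var == "PRE" else "mean"
            stk_a = _prepare_annual(stk, config, reducer=reducer)
            if not ndvi_annual.same_grid(stk_a):
                stk_a = raster.resample_nearest(stk_a, ndvi_annual.lat,
                                                ndvi_annual.lon)
            climate_annual[var] = stk_a
        s["n_years"] = int(ndvi_annual.shape[0])
        s["grid"] = list(ndvi_annual.shape[1:])

        # -- unchanged mask ----------------------------------------------
        s = stage("mask")
        if len(masks) >= 2:
            study_mask = raster.unchanged_mask(masks[0], masks[1])
        elif len(masks) == 1:
            study_mask = masks[0]
        else:
            study_mask = WetlandMask(np.ones(ndvi_annual.shape[1:], bool),
                                     ndvi_annual.lat, ndvi_annual.lon)
        s["n_pixels"] = study_mask.n_pixels

        # -- trend --------------------------------------------------------
        s = stage("trend")
        tmap = trend.trend_map(ndvi_annual, study_mask, alpha=config.alpha)
        s["class_fractions"] = tmap.fractions
        s["n_valid"] = tmap.n_valid
        basin = association.regional_series(ndvi_annual, study_mask)
        tres = trend.trend_series(basin, alpha=config.alpha)
        s["basin_slope_per_decade"] = tres.slope_per_decade
        s["basin_mk_p"] = tres.p
        s["basin_trend_class"] = tres.trend_class.value
        if write_outputs:
            raster.write_field(tmap.slope_per_decade, tmap.lat, tmap.lon,
                               out / "trend_slope_per_decade.tif",
                               "slope_per_decade")
            raster.write_field(tmap.class_codes.astype(float), tmap.lat,
                               tmap.lon, out / "trend_class.tif", "trend_class")

        # -- persistence ---------------------------------------------------
        s = stage("hurst")
        hmap = hurst_map(ndvi_annual, study_mask)
        s["class_fractions"] = hmap.class_fractions
        s["bin_fractions"] = hmap.bin_fractions
        s["mean_h"] = hmap.mean_h
        if write_outputs:
            raster.write_field(hmap.h, hmap.lat, hmap.lon,
                               out / "hurst.tif", "hurst")

        # -- change points -------------------------------------------------
        s = stage("sqmk")
        sq = sqmk_analysis(basin, alpha=config.alpha)
        s["NDVI"] = {
            "crossings": [
                {"year": c.year, "position": c.position,
                 "within_band": c.within_band}
                for c in sq.crossings
            ]
        }
        for var, stk in climate_annual.items():
            cs = association.regional_series(stk, study_mask)
            sqc = sqmk_analysis(cs, alpha=config.alpha)
            s[var] = {
                "crossings": [
                    {"year": c.year, "position": c.position,
                     "within_band": c.within_band}
                    for c in sqc.crossings
                ]
            }

        # -- correlations --------------------------------------------------
        s = stage("correlation")
        strongest = (None, 0.0)
        for var, stk in climate_annual.items():
            lags = config.lags if var == "PRE" else (0,)
            for lag in lags:
                fld = association.correlation_field(
                    ndvi_annual, stk, study_mask, alpha=config.alpha, lag=lag
                )
                key = f"{var}_lag{lag}" if lag else var
                s[key] = {"fractions": fld.fractions,
                          "mean_r": float(np.nanmean(fld.r))}
                if write_outputs:
                    raster.write_field(fld.r, fld.lat, fld.lon,
                                       out / f"corr_{key}.tif", f"r_{key}")
            cs = association.regional_series(stk, study_mask)
            res = association.pearson(basin, cs, alpha=config.alpha)
            s.setdefault("basin", {})[var] = {"r": res.r, "p": res.p}
            if abs(res.r) > abs(strongest[1]):
                strongest = (var, res.r)
        s["basin_strongest_correlate"] = strongest[0]

        # -- regional tables ----------------------------------------------
        s = stage("regional")
        regions = dict(region_masks) if region_masks else {}
        regions.setdefault("basin", study_mask)
        table = profiles.regional_compare(
            ndvi_annual, climate_annual, regions, alpha=config.alpha,
            periods=[(config.start_year, config.end_year)]
            + list(config.period_splits),
        )
        s["table"] = json.loads(table.to_json(orient="records"))
        if write_outputs:
            table.to_csv(out / "regional_table.csv", index=False)

        # -- zonal profiles -------------------------------------------------
        s = stage("profiles")
        tmp_var = "TMP" if "TMP" in climate_annual else \
            next(iter(climate_annual), None)
        if tmp_var is not None:
            fld = association.correlation_field(
                ndvi_annual, climate_annual[tmp_var], study_mask,
                alpha=config.alpha
            )
            for axis in ("latitude", "longitude"):
                prof = profiles.zonal_profile(fld.r, study_mask, axis,
                                              config.band_width)
                try:
                    turns = profiles.find_turning_points(prof)
                except ValueError:
                    turns = []
                s[axis] = {
                    "band_centers": prof.band_centers.tolist(),
                    "values": [None if not np.isfinite(v) else float(v)
                               for v in prof.values],
                    "turning_points": turns,
                }
                if write_outputs:
                    import pandas as pd

                    pd.DataFrame({
                        "band_center": prof.band_centers,
                        "mean_r": prof.values,
                        "n_pixels": prof.n_pixels,
                    }).to_csv(out / f"profile_{axis}.csv", index=False)
    except Exception as exc:  # noqa: BLE001 — annotate the failing stage
        failed = list(report["stages"])[-1] if report["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    if write_outputs:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
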