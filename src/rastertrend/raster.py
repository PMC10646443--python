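"""Containers and grid operations for gridded index/climate time series.

The data model is deliberately small: a :class:`RasterStack` is a
``time x lat x lon`` cube of one variable with NaN as the missing flag, a
:class:`WetlandMask` is a boolean grid aligned to a stack, and an
:class:`AnnualSeries` is one pixel's (or one region's) yearly values — the
unit on which all one-dimensional statistics operate.

Conventions (fixed once, documented here):

* coordinates are cell **centers**, in degrees; latitude and longitude
  vectors are strictly monotone, longitude in [-180, 180);
* grids are regular (constant step along each axis);
* nearest-neighbour ties (equidistant centers) break toward the lower index.

Stacks round-trip through NetCDF (via xarray's scipy backend); masks and
per-pixel result maps round-trip through single-band TIFF with the grid
coordinates carried in the image description tag.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import tifffile
import xarray as xr

__all__ = [
    "AnnualSeries",
    "RasterStack",
    "WetlandMask",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "write_field",
    "read_field",
    "resample_nearest",
    "unchanged_mask",
    "mvc_monthly",
    "growing_season_annual",
    "GROWING_SEASON_MONTHS",
]

#: May–September, the growing-season window over which monthly layers are
#: aggregated to one annual value per pixel.
GROWING_SEASON_MONTHS: tuple[int, ...] = (5, 6, 7, 8, 9)


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class AnnualSeries:
    """Yearly values X(t) for one pixel or one regional mean.

    Parameters
    ----------
    years
        Strictly increasing integer years.
    values
        Same length as ``years``; NaN marks a missing year.
    name
        Variable name (e.g. ``"NDVI"``, ``"TMP"``).
    """

    years: np.ndarray
    values: np.ndarray
    name: str = "NDVI"

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = _as_float_array(self.values)
        if years.ndim != 1 or values.ndim != 1:
            raise ValueError("years and values must be one-dimensional")
        if years.size != values.size:
            raise ValueError(
                f"years ({years.size}) and values ({values.size}) differ in length"
            )
        if years.size and np.any(np.diff(years) <= 0):
            raise ValueError("years must be strictly increasing")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.years.size

    @property
    def n_valid(self) -> int:
        return int(np.sum(np.isfinite(self.values)))

    def dropna(self) -> "AnnualSeries":
        ok = np.isfinite(self.values)
        return AnnualSeries(self.years[ok], self.values[ok], self.name)

    def subset(self, start: int, stop: int) -> "AnnualSeries":
        """Years in the closed interval [start, stop]."""
        ok = (self.years >= start) & (self.years <= stop)
        return AnnualSeries(self.years[ok], self.values[ok], self.name)

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.years, name="year"),
                         name=self.name)


def _check_monotone(coord: np.ndarray, name: str) -> None:
    if coord.ndim != 1 or coord.size < 1:
        raise ValueError(f"{name} must be a non-empty 1-D vector")
    d = np.diff(coord)
    if coord.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError(f"{name} coordinates must be strictly monotone")


@dataclass
class RasterStack:
    """A ``time x lat x lon`` cube of one variable with NaN as missing flag."""

    values: np.ndarray
    time: pd.DatetimeIndex
    lat: np.ndarray
    lon: np.ndarray
    variable: str = "NDVI"
    units: str = ""
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values)
        self.time = pd.DatetimeIndex(self.time)
        self.lat = _as_float_array(self.lat)
        self.lon = _as_float_array(self.lon)
        if self.values.ndim != 3:
            raise ValueError("values must be (time, lat, lon)")
        nt, ny, nx = self.values.shape
        if nt != self.time.size or ny != self.lat.size or nx != self.lon.size:
            raise ValueError(
                f"shape {self.values.shape} inconsistent with coordinates "
                f"({self.time.size}, {self.lat.size}, {self.lon.size})"
            )
        if self.time.size > 1 and not self.time.is_monotonic_increasing:
            raise ValueError("time axis must be increasing")
        if self.time.has_duplicates:
            raise ValueError("time axis must be strictly increasing")
        _check_monotone(self.lat, "lat")
        _check_monotone(self.lon, "lon")

    # -- convenience ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.time.year)

    def same_grid(self, other: "RasterStack | WetlandMask") -> bool:
        return (
            self.lat.size == other.lat.size
            and self.lon.size == other.lon.size
            and np.allclose(self.lat, other.lat)
            and np.allclose(self.lon, other.lon)
        )

    def subset_years(self, start: int, stop: int) -> "RasterStack":
        """Layers whose year lies in the closed interval [start, stop]."""
        sel = (self.years >= start) & (self.years <= stop)
        if not sel.any():
            raise ValueError(f"no layers in {start}-{stop}")
        return replace(self, values=self.values[sel], time=self.time[sel])

    def pixel_series(self, i: int, j: int) -> AnnualSeries:
        """The annual series at grid cell (i, j); time axis must be yearly."""
        years = self.years
        if np.unique(years).size != years.size:
            raise ValueError("pixel_series requires one layer per year")
        return AnnualSeries(years, self.values[:, i, j], self.variable)

    def to_xarray(self) -> xr.DataArray:
        da = xr.DataArray(
            self.values,
            dims=("time", "lat", "lon"),
            coords={"time": self.time, "lat": self.lat, "lon": self.lon},
            name=self.variable,
            attrs={"units": self.units, **self.attrs},
        )
        da["lat"].attrs.update(units="degrees_north", standard_name="latitude")
        da["lon"].attrs.update(units="degrees_east", standard_name="longitude")
        return da

    @classmethod
    def from_xarray(cls, da: xr.DataArray) -> "RasterStack":
        da = da.transpose("time", "lat", "lon")
        attrs = dict(da.attrs)
        units = attrs.pop("units", "")
        return cls(
            values=np.asarray(da.values, dtype=float),
            time=pd.DatetimeIndex(da["time"].values),
            lat=np.asarray(da["lat"].values, dtype=float),
            lon=np.asarray(da["lon"].values, dtype=float),
            variable=str(da.name or "var"),
            units=str(units),
            attrs=attrs,
        )


@dataclass
class WetlandMask:
    """Binary wetland-extent grid for one mapping epoch."""

    values: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    epoch: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.dtype != bool:
            uniq = np.unique(vals[np.isfinite(vals.astype(float))])
            if not np.all(np.isin(uniq, [0, 1])):
                raise ValueError("mask values must be 0/1")
            vals = vals.astype(bool)
        if vals.ndim != 2:
            raise ValueError("mask must be 2-D (lat, lon)")
        self.values = vals
        self.lat = _as_float_array(self.lat)
        self.lon = _as_float_array(self.lon)
        if vals.shape != (self.lat.size, self.lon.size):
            raise ValueError("mask shape inconsistent with coordinates")
        _check_monotone(self.lat, "lat")
        _check_monotone(self.lon, "lon")

    @property
    def n_pixels(self) -> int:
        return int(self.values.sum())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_stack(stack: RasterStack, path) -> None:
    """Write a stack as NetCDF (CF-style time/lat/lon coordinates)."""
    ds = stack.to_xarray().to_dataset()
    ds.to_netcdf(path, engine="scipy")


def read_stack(path, variable: str | None = None) -> RasterStack:
    """Read one variable of a NetCDF file into a :class:`RasterStack`.

    Raises ``KeyError`` naming the available variables if ``variable`` is
    absent; with ``variable=None`` the file must contain exactly one
    non-coordinate variable.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        names = list(ds.data_vars)
        if variable is None:
            if len(names) != 1:
                raise KeyError(
                    f"file has {len(names)} variables {names}; specify one"
                )
            variable = names[0]
        if variable not in ds:
            raise KeyError(
                f"variable {variable!r} not found; available: {names}"
            )
        return RasterStack.from_xarray(ds[variable].load())


def write_mask(mask: WetlandMask, path) -> None:
    """Write a mask as single-band 0/1 TIFF; grid coords go in the tag."""
    meta = {
        "lat": mask.lat.tolist(),
        "lon": mask.lon.tolist(),
        "epoch": mask.epoch,
    }
    tifffile.imwrite(path, mask.values.astype(np.uint8),
                     description=json.dumps(meta))


def read_mask(path, reference: RasterStack | None = None) -> WetlandMask:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        meta = json.loads(page.description or "{}")
    if "lat" in meta:
        lat, lon = np.asarray(meta["lat"]), np.asarray(meta["lon"])
    elif reference is not None:
        lat, lon = reference.lat, reference.lon
    else:
        lat = np.arange(arr.shape[0], dtype=float)
        lon = np.arange(arr.shape[1], dtype=float)
    mask = WetlandMask(arr, lat, lon, epoch=str(meta.get("epoch", "")))
    if reference is not None and mask.values.shape != reference.shape[1:]:
        raise ValueError(
            f"mask shape {mask.values.shape} does not match reference grid "
            f"{reference.shape[1:]}"
        )
    return mask


#: no-data value used in float result maps written to TIFF
NODATA = -9999.0


def write_field(values: np.ndarray, lat: np.ndarray, lon: np.ndarray, path,
                name: str = "") -> None:
    """Write a per-pixel result map (2-D float, NaN = no data) as TIFF."""
    out = np.where(np.isfinite(values), values, NODATA).astype(np.float32)
    meta = {"lat": np.asarray(lat).tolist(), "lon": np.asarray(lon).tolist(),
            "name": name, "nodata": NODATA}
    tifffile.imwrite(path, out, description=json.dumps(meta))


def read_field(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray().astype(float)
        meta = json.loads(page.description or "{}")
    nodata = meta.get("nodata", NODATA)
    arr[arr == nodata] = np.nan
    return arr, np.asarray(meta.get("lat", [])), np.asarray(meta.get("lon", []))


# ---------------------------------------------------------------------------
# Grid harmonisation and masking
# ---------------------------------------------------------------------------

def _nearest_indices(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Index of the nearest source center for each destination center.

    Ties break toward the lower index. Works for ascending or descending
    source vectors.
    """
    order = np.argsort(src, kind="stable")
    s = src[order]
    pos = np.searchsorted(s, dst)
    pos = np.clip(pos, 1, s.size - 1) if s.size > 1 else np.zeros_like(pos)
    left = np.clip(pos - 1, 0, s.size - 1)
    right = np.clip(pos, 0, s.size - 1)
    d_left = np.abs(dst - s[left])
    d_right = np.abs(dst - s[right])
    # prefer the candidate with strictly smaller distance; on ties prefer the
    # lower ORIGINAL index
    idx_left, idx_right = order[left], order[right]
    use_left = (d_left < d_right) | ((d_left == d_right) & (idx_left < idx_right))
    return np.where(use_left, idx_left, idx_right)


def _extents_overlap(src: np.ndarray, dst: np.ndarray) -> bool:
    half = np.abs(np.diff(src)).mean() / 2 if src.size > 1 else 0.0
    lo, hi = src.min() - half, src.max() + half
    return bool((dst.max() >= lo) and (dst.min() <= hi))


def resample_nearest(stack: RasterStack, target_lat: np.ndarray,
                     target_lon: np.ndarray) -> RasterStack:
    """Nearest-neighbour resampling onto a target grid.

    Each output cell takes the value of the source cell whose center is
    nearest to the output cell center; missing stays missing.
    """
    target_lat = _as_float_array(target_lat)
    target_lon = _as_float_array(target_lon)
    _check_monotone(target_lat, "target lat")
    _check_monotone(target_lon, "target lon")
    if not (_extents_overlap(stack.lat, target_lat)
            and _extents_overlap(stack.lon, target_lon)):
        raise ValueError("target grid extent is disjoint from source extent")
    iy = _nearest_indices(stack.lat, target_lat)
    ix = _nearest_indices(stack.lon, target_lon)
    vals = stack.values[:, iy[:, None], ix[None, :]]
    return replace(stack, values=vals, lat=target_lat, lon=target_lon)


def unchanged_mask(m1: WetlandMask, m2: WetlandMask) -> WetlandMask:
    """Cells that are wetland in both epochs (cellwise logical AND)."""
    if m1.values.shape != m2.values.shape:
        raise ValueError(
            f"mask shapes differ: {m1.values.shape} vs {m2.values.shape}"
        )
    if not (np.allclose(m1.lat, m2.lat) and np.allclose(m1.lon, m2.lon)):
        raise ValueError("masks are on different grids")
    epoch = f"{m1.epoch}&{m2.epoch}" if (m1.epoch or m2.epoch) else ""
    return WetlandMask(m1.values & m2.values, m1.lat, m1.lon, epoch=epoch)


# ---------------------------------------------------------------------------
# Compositing and seasonal aggregation
# ---------------------------------------------------------------------------

def mvc_monthly(daily: RasterStack) -> RasterStack:
    """Maximum-value composite: per pixel, the largest value in each month.

    Cloud and atmospheric contamination bias optical vegetation indices
    low, so the per-month maximum is the standard compositing choice. A
    cell is missing in a month only if every daily value that month is
    missing.
    """
    periods = daily.time.to_period("M")
    uniq = periods.unique().sort_values()
    out = np.full((uniq.size,) + daily.shape[1:], np.nan)
    for k, p in enumerate(uniq):
        sel = periods == p
        block = daily.values[sel]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            out[k] = np.nanmax(block, axis=0)
        if np.all(~np.isfinite(block)):
            warnings.warn(f"month {p} has no valid observations", stacklevel=2)
    time = pd.DatetimeIndex([p.to_timestamp() for p in uniq])
    return replace(daily, values=out, time=time)


def growing_season_annual(
    monthly: RasterStack,
    months: Sequence[int] = GROWING_SEASON_MONTHS,
    reducer: str | Callable[..., np.ndarray] = "mean",
    policy: str = "lenient",
) -> RasterStack:
    """Aggregate monthly layers to one growing-season value per year.

    ``reducer`` is ``"mean"`` (indices, temperatures) or ``"sum"``
    (precipitation totals), or any callable like ``np.nanmean``. Under the
    default ``"lenient"`` missing policy a cell uses whatever months are
    available; ``"strict"`` marks a cell missing if any required month is.
    """
    months = tuple(int(m) for m in months)
    if not months or not set(months) <= set(range(1, 13)):
        raise ValueError("months must be within 1..12")
    if policy not in ("lenient", "strict"):
        raise ValueError("policy must be 'lenient' or 'strict'")
    if callable(reducer):
        reduce_fn = reducer
    elif reducer == "mean":
        reduce_fn = np.nanmean
    elif reducer == "sum":
        reduce_fn = np.nansum
    else:
        raise ValueError("reducer must be 'mean', 'sum' or a callable")

    years = np.unique(monthly.time.year)
    out = np.full((years.size,) + monthly.shape[1:], np.nan)
    for k, year in enumerate(years):
        sel = (monthly.time.year == year) & np.isin(monthly.time.month, months)
        if not sel.any():
            warnings.warn(f"year {year} has no growing-season layers",
                          stacklevel=2)
            continue
        block = monthly.values[sel]
        any_valid = np.isfinite(block).any(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vals = reduce_fn(block, axis=0)
        vals = np.where(any_valid, vals, np.nan)
        if policy == "strict":
            complete = (sel.sum() == len(months)) & np.isfinite(block).all(axis=0)
            vals = np.where(complete, vals, np.nan)
        out[k] = vals
    time = pd.DatetimeIndex([pd.Timestamp(int(y), 1, 1) for y in years])
    return replace(monthly, values=out, time=time)
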