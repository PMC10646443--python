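"""Zonal (latitudinal/longitudinal) profiles and regional summary tables.

A zonal profile averages a per-pixel field (correlation coefficient, trend
slope, ...) over contiguous bands along latitude or longitude, restricted
to the analysis mask. Turning points — band centers where a smoothed
profile switches between increasing and decreasing — locate geographic
shift lines such as the latitude/longitude where an index–climate
correlation changes direction.

``regional_compare`` builds the per-region summary table (trend slope and
significance, mean value, mean Hurst exponent, Pearson and partial
correlations with each climate variable), optionally split into periods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import partial_corr_series, pearson, regional_series
from .hurst import hurst_exponent
from .raster import RasterStack, WetlandMask
from .trend import trend_series

__all__ = [
    "ZonalProfile",
    "zonal_profile",
    "find_turning_points",
    "regional_compare",
]


@dataclass
class ZonalProfile:
    axis: str                  # "latitude" or "longitude"
    band_centers: np.ndarray   # degrees, increasing
    band_width: float
    values: np.ndarray         # mean field value per band, NaN if empty
    n_pixels: np.ndarray       # valid masked pixels per band


def zonal_profile(field: np.ndarray, mask: WetlandMask, axis: str,
                  band_width: float = 0.5) -> ZonalProfile:
    """Mean of a masked per-pixel field in bands along one axis."""
    if band_width <= 0:
        raise ValueError("band_width must be positive")
    if axis not in ("latitude", "longitude"):
        raise ValueError("axis must be 'latitude' or 'longitude'")
    field = np.asarray(field, dtype=float)
    if field.shape != mask.values.shape:
        raise ValueError("field shape does not match mask")
    if not mask.values.any():
        raise ValueError("mask is empty")
    coord = mask.lat if axis == "latitude" else mask.lon
    coords2d = (np.broadcast_to(coord[:, None], field.shape)
                if axis == "latitude"
                else np.broadcast_to(coord[None, :], field.shape))
    use = mask.values & np.isfinite(field)
    c = coords2d[use]
    v = field[use]
    lo = np.floor(coord.min() / band_width) * band_width
    hi = np.ceil((coord.max() + 1e-12) / band_width) * band_width
    edges = np.arange(lo, hi + band_width / 2, band_width)
    if edges.size < 2:
        edges = np.array([lo, lo + band_width])
    idx = np.clip(np.digitize(c, edges) - 1, 0, edges.size - 2)
    n_bands = edges.size - 1
    sums = np.bincount(idx, weights=v, minlength=n_bands)
    counts = np.bincount(idx, minlength=n_bands)
    values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (edges[:-1] + edges[1:]) / 2
    return ZonalProfile(axis, centers, float(band_width), values,
                        counts.astype(int))


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; shrinks the window at the edges."""
    if window <= 1:
        return y.copy()
    half = window // 2
    out = np.empty_like(y)
    for i in range(y.size):
        seg = y[max(0, i - half): i + half + 1]
        out[i] = np.nanmean(seg) if np.isfinite(seg).any() else np.nan
    return out


def find_turning_points(profile: ZonalProfile,
                        smooth_window: int = 3) -> list[float]:
    """Band centers where the smoothed profile reverses direction.

    The profile is smoothed with a centered moving average, then a turning
    point is any interior band where the first difference changes sign.
    Flat stretches (zero difference) are skipped when locating the sign
    change, so a plateau top counts once.
    """
    ok = np.isfinite(profile.values)
    if ok.sum() < 5:
        raise ValueError("need at least 5 non-missing bands")
    centers = profile.band_centers[ok]
    y = _moving_average(profile.values[ok], smooth_window)
    d = np.diff(y)
    signs = np.sign(d)
    nz = np.nonzero(signs)[0]
    turns: list[float] = []
    for a, b in zip(nz[:-1], nz[1:]):
        if signs[a] != signs[b]:
            turns.append(float(centers[a + 1]))
    return turns


def regional_compare(
    ndvi: RasterStack,
    climate: dict[str, RasterStack],
    regions: dict[str, WetlandMask],
    alpha: float = 0.05,
    periods: list[tuple[int, int]] | None = None,
    partial_pairs: tuple[tuple[str, str], ...] = (("TMP", "PRE"), ("PRE", "TMP")),
) -> pd.DataFrame:
    """Per-region x per-period summary table.

    Columns: mean index value, Theil–Sen slope per decade, Mann–Kendall p,
    mean pixel Hurst exponent, Pearson r (and p) per climate variable, and
    first-order partial correlations for the requested (variable | control)
    pairs. Empty regions yield a row of NaN with a warning.
    """
    if not regions:
        raise ValueError("need at least one region")
    if periods is None:
        yrs = ndvi.years
        periods = [(int(yrs.min()), int(yrs.max()))]
    rows = []
    for rname, mask in regions.items():
        for (y0, y1) in periods:
            row: dict[str, object] = {"region": rname, "period": f"{y0}-{y1}"}
            if not mask.values.any():
                warnings.warn(f"region {rname!r} is empty", stacklevel=2)
                rows.append(row)
                continue
            nd = regional_series(ndvi, mask).subset(y0, y1)
            tr = trend_series(nd, alpha=alpha)
            row["mean"] = float(np.nanmean(nd.values))
            row["slope_per_decade"] = tr.slope_per_decade
            row["mk_p"] = tr.p
            row["trend_class"] = tr.trend_class.value
            sub = ndvi.subset_years(y0, y1)
            hs = []
            for i, j in zip(*np.nonzero(mask.values)):
                try:
                    hs.append(hurst_exponent(sub.values[:, i, j]).h)
                except ValueError:
                    continue
            if hs:
                row["mean_hurst"] = float(np.mean(hs))
            series_by_var = {"NDVI": nd}
            for var, stack in climate.items():
                cs = regional_series(stack, mask).subset(y0, y1)
                series_by_var[var] = cs
                res = pearson(nd, cs, alpha=alpha)
                row[f"r_{var}"] = res.r
                row[f"p_{var}"] = res.p
            for var, ctrl in partial_pairs:
                if var in series_by_var and ctrl in series_by_var:
                    pres = partial_corr_series(nd, series_by_var[var],
                                               series_by_var[ctrl])
                    row[f"partial_r_{var}|{ctrl}"] = pres.r_xy_z
                    row[f"partial_p_{var}|{ctrl}"] = pres.p
            rows.append(row)
    return pd.DataFrame(rows)
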