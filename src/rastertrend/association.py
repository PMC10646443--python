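"""Pearson and partial correlation between vegetation index and climate.

Per-pixel (and regional) Pearson product-moment correlation with the
exact-t significance test (t = r sqrt(n-2)/sqrt(1-r^2), df = n-2), a
lagged variant for delayed precipitation effects (index of the current
year against precipitation of 1 or 2 years before), and the first-order
partial correlation

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

which isolates the index–temperature association net of precipitation and
vice versa (significance with df = n-3). Pixel-level correlations are
categorised four ways by sign and significance; no multiple-testing
correction is applied across pixels — category fractions are descriptive
summaries of the map, not simultaneous inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .raster import AnnualSeries, RasterStack, WetlandMask

__all__ = [
    "CorrelationCategory",
    "CorrelationResult",
    "PartialCorrelationResult",
    "CorrelationField",
    "pearson",
    "lagged_pearson",
    "partial_corr",
    "partial_corr_series",
    "correlation_field",
    "regional_series",
]


class CorrelationCategory(str, Enum):
    SIG_POSITIVE = "sig_positive"
    NONSIG_POSITIVE = "nonsig_positive"
    SIG_NEGATIVE = "sig_negative"
    NONSIG_NEGATIVE = "nonsig_negative"


CATEGORY_CODES = {
    CorrelationCategory.SIG_POSITIVE: 1,
    CorrelationCategory.NONSIG_POSITIVE: 2,
    CorrelationCategory.SIG_NEGATIVE: 3,
    CorrelationCategory.NONSIG_NEGATIVE: 4,
}


def categorize(r: float, p: float, alpha: float = 0.05) -> CorrelationCategory:
    """Four-way category by sign of r and significance at level alpha.

    r = 0 exactly is grouped with the positive side so every finite pixel
    receives a category.
    """
    if r >= 0:
        return (CorrelationCategory.SIG_POSITIVE if p < alpha
                else CorrelationCategory.NONSIG_POSITIVE)
    return (CorrelationCategory.SIG_NEGATIVE if p < alpha
            else CorrelationCategory.NONSIG_NEGATIVE)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n_eff: int
    p: float
    category: CorrelationCategory
    lag: int = 0


@dataclass(frozen=True)
class PartialCorrelationResult:
    r_xy_z: float
    r_xy: float
    r_xz: float
    r_yz: float
    p: float | None = None      # set when a sample size is supplied
    n: int | None = None


def _aligned_values(x, y) -> tuple[np.ndarray, np.ndarray]:
    """Complete pairs of two series aligned on years (arrays align on index)."""
    if isinstance(x, AnnualSeries) and isinstance(y, AnnualSeries):
        common, ix, iy = np.intersect1d(x.years, y.years, return_indices=True)
        xv, yv = x.values[ix], y.values[iy]
    else:
        xv = x.values if isinstance(x, AnnualSeries) else np.asarray(x, dtype=float)
        yv = y.values if isinstance(y, AnnualSeries) else np.asarray(y, dtype=float)
        if xv.size != yv.size:
            raise ValueError("series of unequal length with no year alignment")
    ok = np.isfinite(xv) & np.isfinite(yv)
    return xv[ok], yv[ok]


def _pearson_r_p(xv: np.ndarray, yv: np.ndarray) -> tuple[float, float]:
    n = xv.size
    xc, yc = xv - xv.mean(), yv - yv.mean()
    sx = np.sqrt(np.sum(xc ** 2))
    sy = np.sqrt(np.sum(yc ** 2))
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined: a series has zero variance")
    r = float(np.clip(np.sum(xc * yc) / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def pearson(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson correlation with the exact t test (df = n-2)."""
    xv, yv = _aligned_values(x, y)
    if xv.size < 3:
        raise ValueError("need at least 3 complete pairs")
    r, p = _pearson_r_p(xv, yv)
    return CorrelationResult(r, xv.size, p, categorize(r, p, alpha), lag=0)


def lagged_pearson(x, y, lag: int, alpha: float = 0.05) -> CorrelationResult:
    """Correlate x_t with y_{t-lag} (y leading x by ``lag`` years)."""
    if lag not in (0, 1, 2):
        raise ValueError("lag must be 0, 1 or 2")
    if isinstance(x, AnnualSeries) and isinstance(y, AnnualSeries):
        y_shift = AnnualSeries(y.years + lag, y.values, y.name)
        xv, yv = _aligned_values(x, y_shift)
    else:
        xv = x.values if isinstance(x, AnnualSeries) else np.asarray(x, dtype=float)
        yv = y.values if isinstance(y, AnnualSeries) else np.asarray(y, dtype=float)
        if lag:
            xv, yv = xv[lag:], yv[:-lag]
        ok = np.isfinite(xv) & np.isfinite(yv)
        xv, yv = xv[ok], yv[ok]
    if xv.size < 3:
        raise ValueError("insufficient overlap after lagging")
    r, p = _pearson_r_p(xv, yv)
    return CorrelationResult(r, xv.size, p, categorize(r, p, alpha), lag=lag)


def partial_corr(r_xy: float, r_xz: float, r_yz: float,
                 n: int | None = None) -> PartialCorrelationResult:
    """First-order partial correlation from the three pairwise coefficients.

    With ``n`` supplied, the two-sided p-value uses t with df = n-3.
    """
    for name, val in (("r_xy", r_xy), ("r_xz", r_xz), ("r_yz", r_yz)):
        if not np.isfinite(val) or abs(val) > 1:
            raise ValueError(f"{name} must lie in [-1, 1]")
    if abs(r_xz) >= 1 or abs(r_yz) >= 1:
        raise ValueError("partial correlation undefined when |r_xz| or |r_yz| = 1")
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
    r = float(np.clip(r, -1.0, 1.0))
    p = None
    if n is not None:
        if n < 4:
            raise ValueError("need n >= 4 for a partial-correlation test")
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt(n - 3) / np.sqrt(1 - r * r)
            p = float(2.0 * stats.t.sf(abs(t), df=n - 3))
    return PartialCorrelationResult(r, r_xy, r_xz, r_yz, p=p, n=n)


def partial_corr_series(x, y, z) -> PartialCorrelationResult:
    """Partial correlation of x and y controlling z, from three series."""
    xv, yv = _aligned_values(x, y)
    xv2, zv = _aligned_values(x, z)
    if xv.size != xv2.size:
        raise ValueError("series must share the same complete years")
    r_xy, _ = _pearson_r_p(xv, yv)
    r_xz, _ = _pearson_r_p(xv, zv)
    r_yz, _ = _pearson_r_p(yv, zv)
    return partial_corr(r_xy, r_xz, r_yz, n=xv.size)


@dataclass
class CorrelationField:
    """Per-pixel correlation maps for one climate variable and lag."""

    r: np.ndarray               # (lat, lon), NaN outside mask/invalid
    p: np.ndarray
    category_codes: np.ndarray  # CATEGORY_CODES ints, 0 where invalid
    lat: np.ndarray
    lon: np.ndarray
    variable: str
    lag: int
    fractions: dict[str, float]
    n_valid: int


def correlation_field(ndvi: RasterStack, climate: RasterStack,
                      mask: WetlandMask | None = None, alpha: float = 0.05,
                      lag: int = 0) -> CorrelationField:
    """Pixel-wise correlation of an index stack with a climate stack."""
    if not ndvi.same_grid(climate):
        raise ValueError("index and climate stacks are on different grids")
    if mask is None:
        mvals = np.ones(ndvi.shape[1:], dtype=bool)
    else:
        if not ndvi.same_grid(mask):
            raise ValueError("mask grid does not match stack grid")
        mvals = mask.values
    if not mvals.any():
        raise ValueError("mask is empty")
    ny, nx = ndvi.shape[1:]
    rmap = np.full((ny, nx), np.nan)
    pmap = np.full((ny, nx), np.nan)
    codes = np.zeros((ny, nx), dtype=np.int16)
    counts = {c: 0 for c in CorrelationCategory}
    n_valid = 0
    for i, j in zip(*np.nonzero(mvals)):
        try:
            res = lagged_pearson(ndvi.pixel_series(i, j),
                                 climate.pixel_series(i, j), lag, alpha=alpha)
        except ValueError:
            continue
        rmap[i, j] = res.r
        pmap[i, j] = res.p
        codes[i, j] = CATEGORY_CODES[res.category]
        counts[res.category] += 1
        n_valid += 1
    if n_valid == 0:
        raise ValueError("no masked pixel has a defined correlation")
    fractions = {c.value: counts[c] / n_valid for c in CorrelationCategory}
    return CorrelationField(rmap, pmap, codes, ndvi.lat, ndvi.lon,
                            climate.variable, lag, fractions, n_valid)


def regional_series(stack: RasterStack, mask: WetlandMask,
                    area_weighted: bool = False) -> AnnualSeries:
    """Per-year mean over masked pixels (the basin/region mean series).

    Unweighted by default, matching the convention of averaging all
    wetland pixels; ``area_weighted=True`` applies cosine-latitude weights.
    """
    if not stack.same_grid(mask):
        raise ValueError("mask grid does not match stack grid")
    if not mask.values.any():
        raise ValueError("mask is empty")
    sel = stack.values[:, mask.values]  # (time, n_masked)
    if area_weighted:
        w2d = np.broadcast_to(np.cos(np.deg2rad(stack.lat))[:, None],
                              mask.values.shape)
        w = w2d[mask.values]
        valid = np.isfinite(sel)
        num = np.nansum(np.where(valid, sel, 0.0) * w, axis=1)
        den = np.sum(valid * w, axis=1)
        means = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    else:
        valid = np.isfinite(sel)
        num = np.where(valid, sel, 0.0).sum(axis=1)
        den = valid.sum(axis=1)
        means = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return AnnualSeries(stack.years, means, stack.variable)
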