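"""Theil–Sen slope, Mann–Kendall significance, and trend classification.

The trend magnitude is the Theil–Sen estimator — the median of all pairwise
slopes (X_j - X_i)/(t_j - t_i) — which is robust to outliers and makes no
distributional assumption. Significance comes from the Mann–Kendall test on
the pairwise-sign statistic

    S = sum_{i<j} sgn(X_j - X_i),       Var(S) = n(n-1)(2n+5)/18,

standardised with the +-1 continuity correction (Z = (S-1)/sqrt(Var) for
S > 0, (S+1)/sqrt(Var) for S < 0, 0 at S = 0) and referred to the normal
distribution; |Z| > 1.96 corresponds to p < 0.05 two-sided.

Two variance modes are provided: ``"plain"`` (the formula above, no tie
term — the default) and ``"tie-corrected"`` (the standard correction
subtracting sum t_g(t_g-1)(2t_g+5)/18 over tie groups g). With annual
index/climate values ties are rare, so the two modes usually coincide.

Per-pixel maps report slopes per decade (10x the per-year slope), the
common reporting convention for slow vegetation-index trends.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .raster import AnnualSeries, RasterStack, WetlandMask

__all__ = [
    "TrendClass",
    "TrendResult",
    "TrendMap",
    "theil_sen",
    "mann_kendall",
    "classify_trend",
    "trend_series",
    "trend_map",
]


class TrendClass(str, Enum):
    SIGNIFICANT_INCREASE = "significant_increase"
    SIGNIFICANT_DECREASE = "significant_decrease"
    NONSIGNIFICANT = "nonsignificant"


#: integer codes used in classified maps
TREND_CODES = {
    TrendClass.SIGNIFICANT_INCREASE: 1,
    TrendClass.SIGNIFICANT_DECREASE: 2,
    TrendClass.NONSIGNIFICANT: 3,
}


@dataclass(frozen=True)
class TrendResult:
    """Per-series trend estimate and Mann–Kendall test."""

    q_median: float          # Theil–Sen slope per year
    intercept: float         # median(X - Q t)
    s: int                   # MK pairwise-sign statistic
    var_s: float
    z: float
    p: float
    trend_class: TrendClass

    @property
    def slope_per_decade(self) -> float:
        return 10.0 * self.q_median


def _series_arrays(series) -> tuple[np.ndarray, np.ndarray]:
    """(t, x) with missing values dropped; accepts AnnualSeries or array."""
    if isinstance(series, AnnualSeries):
        t = series.years.astype(float)
        x = series.values
    else:
        x = np.asarray(series, dtype=float)
        t = np.arange(x.size, dtype=float)
    ok = np.isfinite(x)
    return t[ok], x[ok]


def theil_sen(series) -> tuple[float, float]:
    """Theil–Sen slope and intercept of a series.

    slope = median over all i < j of (X_j - X_i)/(t_j - t_i), using the
    series' own time coordinates; intercept = median(X - slope * t).
    Missing values are dropped pairwise.
    """
    t, x = _series_arrays(series)
    if x.size < 2 or np.unique(t).size < 2:
        raise ValueError("Theil–Sen needs at least two distinct time points")
    i, j = np.triu_indices(x.size, k=1)
    dt = t[j] - t[i]
    keep = dt != 0
    slopes = (x[j] - x[i])[keep] / dt[keep]
    slope = float(np.median(slopes))
    intercept = float(np.median(x - slope * t))
    return slope, intercept


def mann_kendall(series, mode: str = "plain") -> tuple[int, float, float, float]:
    """Mann–Kendall test: returns (S, Var(S), Z, p).

    ``mode="plain"`` uses Var(S) = n(n-1)(2n+5)/18 with no tie term;
    ``mode="tie-corrected"`` subtracts the standard tie-group correction.
    p is the two-sided normal-approximation p-value of the
    continuity-corrected Z.
    """
    if mode not in ("plain", "tie-corrected"):
        raise ValueError("mode must be 'plain' or 'tie-corrected'")
    _, x = _series_arrays(series)
    n = x.size
    if n < 3:
        raise ValueError(f"Mann–Kendall needs n >= 3 non-missing values, got {n}")
    diff = x[None, :] - x[:, None]
    s = int(np.sum(np.sign(diff[np.triu_indices(n, k=1)])))
    var_s = n * (n - 1) * (2 * n + 5) / 18.0
    if mode == "tie-corrected":
        _, counts = np.unique(x, return_counts=True)
        ties = counts[counts > 1]
        var_s -= float(np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return s, var_s, float(z), float(p)


def classify_trend(q_median: float, p: float, alpha: float = 0.05) -> TrendClass:
    """Three-way class: significant increase / decrease, else nonsignificant."""
    if not (np.isfinite(q_median) and np.isfinite(p)):
        raise ValueError("q_median and p must be finite")
    if p < alpha and q_median > 0:
        return TrendClass.SIGNIFICANT_INCREASE
    if p < alpha and q_median < 0:
        return TrendClass.SIGNIFICANT_DECREASE
    return TrendClass.NONSIGNIFICANT


def trend_series(series, alpha: float = 0.05, mode: str = "plain") -> TrendResult:
    """Full Theil–Sen + Mann–Kendall analysis of one series."""
    slope, intercept = theil_sen(series)
    s, var_s, z, p = mann_kendall(series, mode=mode)
    return TrendResult(slope, intercept, s, var_s, z, p,
                       classify_trend(slope, p, alpha))


@dataclass
class TrendMap:
    """Per-pixel trend maps over a masked grid plus class area fractions."""

    slope_per_decade: np.ndarray   # (lat, lon), NaN outside mask
    z: np.ndarray
    p: np.ndarray
    class_codes: np.ndarray        # int codes of TREND_CODES, 0 outside mask
    lat: np.ndarray
    lon: np.ndarray
    fractions: dict[str, float]    # class name -> fraction of valid pixels
    n_valid: int


def trend_map(stack: RasterStack, mask: WetlandMask | None = None,
              alpha: float = 0.05, mode: str = "plain") -> TrendMap:
    """Theil–Sen + Mann–Kendall at every masked pixel of an annual stack."""
    if stack.shape[0] < 3:
        raise ValueError("need at least three annual layers")
    if mask is None:
        mvals = np.ones(stack.shape[1:], dtype=bool)
    else:
        if not stack.same_grid(mask):
            raise ValueError("mask grid does not match stack grid")
        mvals = mask.values
    if not mvals.any():
        raise ValueError("mask is empty")

    ny, nx = stack.shape[1:]
    slope = np.full((ny, nx), np.nan)
    zmap = np.full((ny, nx), np.nan)
    pmap = np.full((ny, nx), np.nan)
    codes = np.zeros((ny, nx), dtype=np.int16)
    counts = {c: 0 for c in TrendClass}
    n_valid = 0
    for i, j in zip(*np.nonzero(mvals)):
        series = stack.pixel_series(i, j)
        if series.n_valid < 3:
            continue
        res = trend_series(series, alpha=alpha, mode=mode)
        slope[i, j] = res.slope_per_decade
        zmap[i, j] = res.z
        pmap[i, j] = res.p
        codes[i, j] = TREND_CODES[res.trend_class]
        counts[res.trend_class] += 1
        n_valid += 1
    if n_valid == 0:
        raise ValueError("no masked pixel has enough valid data")
    fractions = {c.value: counts[c] / n_valid for c in TrendClass}
    return TrendMap(slope, zmap, pmap, codes, stack.lat, stack.lon,
                    fractions, n_valid)
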