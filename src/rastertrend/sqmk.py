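"""Sequential Mann–Kendall (SQMK) abrupt-change detection.

The forward statistic follows Sneyers' progressive rank construction: for
each position i, R_i counts earlier samples strictly exceeded by X_i
(ties contribute nothing), S_k = sum_{i<=k} R_i, and

    UF_k = (S_k - E(S_k)) / sqrt(Var(S_k)),   UF_1 = 0,
    E(S_k) = k(k-1)/4,   Var(S_k) = k(k-1)(2k+5)/72,

evaluated at the running index k (the standardisation must track the
growing subsample, not the full length n). The backward sequence UB is the
negated forward statistic of the time-reversed series, mapped back onto
the original axis, so UB and UF are exactly antisymmetric under reversal.

A crossing of the UF and UB curves marks a candidate abrupt-change year.
Crossings are located by linear interpolation of UF - UB between adjacent
years and reported at the nearer integer year; each carries a flag saying
whether the interpolated |UF| lies inside the +-z_{1-alpha/2} confidence
band (+-1.96 at alpha = 0.05) — the conventional requirement for calling
the crossing an abrupt change rather than noise. All crossings are
reported; no "primary" one is selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .raster import AnnualSeries

__all__ = ["Crossing", "SQMKResult", "sqmk_forward", "sqmk"]


def _values_years(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, AnnualSeries):
        ok = np.isfinite(series.values)
        return series.values[ok], series.years[ok]
    x = np.asarray(series, dtype=float)
    ok = np.isfinite(x)
    return x[ok], np.nonzero(ok)[0]


def sqmk_forward(series) -> tuple[np.ndarray, np.ndarray]:
    """Rank-sum sequence S_k and forward statistic UF_k.

    R_i = #{j <= i : X_i > X_j}; S_k = cumulative sum of R_i; UF_1 = 0.
    """
    x, _ = _values_years(series)
    n = x.size
    if n < 3:
        raise ValueError(f"SQMK needs n >= 3, got {n}")
    r = np.array([np.sum(x[i] > x[:i]) for i in range(n)], dtype=float)
    s_k = np.cumsum(r)
    k = np.arange(1, n + 1, dtype=float)
    uf = np.zeros(n)
    e = k * (k - 1) / 4.0
    var = k * (k - 1) * (2 * k + 5) / 72.0
    uf[1:] = (s_k[1:] - e[1:]) / np.sqrt(var[1:])
    return s_k, uf


@dataclass(frozen=True)
class Crossing:
    """One UF/UB intersection."""

    year: int               # nearer integer year
    position: float         # interpolated position on the year axis
    uf_at_crossing: float
    within_band: bool       # |UF| < critical value at the crossing


@dataclass
class SQMKResult:
    years: np.ndarray
    s_k: np.ndarray
    uf: np.ndarray
    ub: np.ndarray
    alpha: float
    band: float             # +-critical value of the confidence band
    crossings: list[Crossing]


def sqmk(series, alpha: float = 0.05) -> SQMKResult:
    """Full SQMK analysis: UF, UB and their crossings."""
    x, years = _values_years(series)
    n = x.size
    if n < 3:
        raise ValueError(f"SQMK needs n >= 3, got {n}")
    s_k, uf = sqmk_forward(x)
    _, uf_rev = sqmk_forward(x[::-1])
    ub = -uf_rev[::-1]
    band = float(stats.norm.ppf(1 - alpha / 2))

    crossings: list[Crossing] = []
    d = uf - ub
    yrs = years.astype(float)
    for k in range(n - 1):
        d0, d1 = d[k], d[k + 1]
        if d0 == 0.0 and k > 0:
            # exact touch at an interior sample point
            frac = 0.0
        elif d0 * d1 < 0:
            frac = d0 / (d0 - d1)
        else:
            continue
        pos = yrs[k] + frac * (yrs[k + 1] - yrs[k])
        uf_cross = uf[k] + frac * (uf[k + 1] - uf[k])
        crossings.append(Crossing(
            year=int(round(pos)),
            position=float(pos),
            uf_at_crossing=float(uf_cross),
            within_band=bool(abs(uf_cross) < band),
        ))
    return SQMKResult(years, s_k, uf, ub, alpha, band, crossings)
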