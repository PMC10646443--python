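"""Rescaled-range (R/S) Hurst-exponent estimation and persistence classes.

For a window length tau the series is split into consecutive
non-overlapping blocks of length tau. Per block, with block mean m:

    cumulative deviations  X(t) = sum_{u<=t} (x_u - m)
    range                  R = max X - min X
    scale                  S = population standard deviation about m

and the R/S statistic at tau is the mean of R/S over blocks (blocks with
S = 0 are skipped). The Hurst exponent H is the slope of the OLS fit of
log(mean R/S) on log(tau): the long-memory scaling E[R/S] ~ (c tau)^H.

Interpretation: 0.5 < H < 1 — persistent, the future tendency of the
series is expected to be consistent with the past; H = 0.5 — random walk
increments, no long-term correlation; 0 < H < 0.5 — anti-persistent, the
future tendency opposes the past. Reporting additionally bins persistent
pixels into moderate (0.5, 0.7] and strong (0.7, 1) persistence.

The classical R/S estimator is biased upward for short series (well known
since Anis & Lloyd); tests and recovery claims are therefore framed over
replicate distributions, never single draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .raster import AnnualSeries, RasterStack, WetlandMask

__all__ = [
    "PersistenceClass",
    "HurstResult",
    "HurstMap",
    "rs_statistic",
    "default_taus",
    "hurst_exponent",
    "hurst_map",
]

#: tolerance inside which an estimate counts as exactly 0.5 ("random")
_RANDOM_TOL = 1e-9


class PersistenceClass(str, Enum):
    ANTI_PERSISTENT = "anti_persistent"
    RANDOM = "random"
    PERSISTENT = "persistent"


#: reporting bins for the persistent range
REPORT_BINS = ("(0.5,0.7]", "(0.7,1)", "other")


def classify_hurst(h: float) -> PersistenceClass:
    if abs(h - 0.5) <= _RANDOM_TOL:
        return PersistenceClass.RANDOM
    return PersistenceClass.PERSISTENT if h > 0.5 else PersistenceClass.ANTI_PERSISTENT


def report_bin(h: float) -> str:
    """Reporting bin: moderate (0.5,0.7], strong (0.7,1), else 'other'."""
    if 0.5 < h <= 0.7:
        return REPORT_BINS[0]
    if 0.7 < h < 1.0:
        return REPORT_BINS[1]
    return REPORT_BINS[2]


def rs_statistic(series, tau: int) -> float:
    """Mean rescaled range R/S over non-overlapping blocks of length tau."""
    if isinstance(series, AnnualSeries):
        x = series.values
    else:
        x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    tau = int(tau)
    if tau < 2:
        raise ValueError("tau must be at least 2")
    if x.size < tau:
        raise ValueError(f"series length {x.size} shorter than tau {tau}")
    n_blocks = x.size // tau
    ratios = []
    for b in range(n_blocks):
        block = x[b * tau:(b + 1) * tau]
        dev = block - block.mean()
        cum = np.cumsum(dev)
        r = cum.max() - cum.min()
        s = np.sqrt(np.mean(dev ** 2))  # population standard deviation
        if s > 0:
            ratios.append(r / s)
    if not ratios:
        raise ValueError("constant series: every block has zero variance")
    return float(np.mean(ratios))


def default_taus(n: int, min_tau: int = 4) -> np.ndarray:
    """Window lengths min_tau .. n//2 (each gives >= 2 complete blocks)."""
    hi = n // 2
    if hi < min_tau:
        raise ValueError(f"series too short for R/S analysis (n={n})")
    return np.arange(min_tau, hi + 1)


@dataclass(frozen=True)
class HurstResult:
    h: float
    log_fit_intercept: float
    window_lengths: np.ndarray
    rs_values: np.ndarray
    r_squared: float
    persistence_class: PersistenceClass
    report_bin: str


def hurst_exponent(series, taus=None) -> HurstResult:
    """Estimate H by OLS of log(mean R/S) on log(tau)."""
    if isinstance(series, AnnualSeries):
        x = series.values
    else:
        x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 8:
        raise ValueError("need at least 8 non-missing values")
    taus = default_taus(x.size) if taus is None else np.asarray(taus, dtype=int)
    rs = []
    used = []
    for tau in taus:
        try:
            rs.append(rs_statistic(x, tau))
            used.append(tau)
        except ValueError:
            continue
    if len(used) < 3:
        raise ValueError("fewer than 3 usable window lengths")
    used = np.asarray(used)
    rs = np.asarray(rs)
    lx, ly = np.log(used.astype(float)), np.log(rs)
    # OLS slope/intercept via centered normal equations
    lxc = lx - lx.mean()
    h = float(np.sum(lxc * ly) / np.sum(lxc ** 2))
    a = float(ly.mean() - h * lx.mean())
    resid = ly - (a + h * lx)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return HurstResult(h, a, used, rs, r2, classify_hurst(h), report_bin(h))


@dataclass
class HurstMap:
    h: np.ndarray                 # (lat, lon), NaN outside mask
    lat: np.ndarray
    lon: np.ndarray
    class_fractions: dict[str, float]
    bin_fractions: dict[str, float]
    mean_h: float
    n_valid: int


def hurst_map(stack: RasterStack, mask: WetlandMask | None = None,
              taus=None) -> HurstMap:
    """Per-pixel Hurst exponent over a masked annual stack."""
    if mask is None:
        mvals = np.ones(stack.shape[1:], dtype=bool)
    else:
        if not stack.same_grid(mask):
            raise ValueError("mask grid does not match stack grid")
        mvals = mask.values
    if not mvals.any():
        raise ValueError("mask is empty")
    ny, nx = stack.shape[1:]
    hmap = np.full((ny, nx), np.nan)
    class_counts = {c: 0 for c in PersistenceClass}
    bin_counts = dict.fromkeys(REPORT_BINS, 0)
    n_valid = 0
    for i, j in zip(*np.nonzero(mvals)):
        vals = stack.values[:, i, j]
        try:
            res = hurst_exponent(vals, taus=taus)
        except ValueError:
            continue
        hmap[i, j] = res.h
        class_counts[res.persistence_class] += 1
        bin_counts[res.report_bin] += 1
        n_valid += 1
    if n_valid == 0:
        raise ValueError("no masked pixel has enough valid data")
    return HurstMap(
        hmap, stack.lat, stack.lon,
        {c.value: class_counts[c] / n_valid for c in PersistenceClass},
        {b: bin_counts[b] / n_valid for b in REPORT_BINS},
        float(np.nanmean(hmap)), n_valid,
    )
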