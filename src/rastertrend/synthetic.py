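"""Synthetic inputs with known ground truth for every pipeline stage.

Everything downstream (trend maps, Hurst maps, change-point detection,
correlation fields, zonal profiles) is validated against data generated
here, where the slope field, persistence, change year and index–climate
coupling are imposed and therefore known exactly.

What is emulated, and how:

* **Annual index/climate series** — linear trend plus AR(1) Gaussian noise
  (initialised from the stationary distribution, so early years are not
  transient), with an optional step change.
* **Fractional Gaussian noise** — exact Davies–Harte circulant embedding
  of the fGn autocovariance, giving an unbiased oracle for the rescaled-
  range Hurst estimator.
* **Scenes** — a time x lat x lon index cube with a per-pixel slope field,
  climate cubes whose anomalies have a prescribed population correlation
  with the index anomalies (shared latent noise mixing), and blob-shaped
  wetland masks at two epochs built from thresholded smoothed noise.
* **Daily months** — a daily sequence with reproducible dropouts for
  testing maximum-value compositing.

Index values are clipped to [-1, 1] after noise addition; the number of
clipped samples is recorded in the stack attrs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import AnnualSeries, RasterStack, WetlandMask

__all__ = [
    "SeriesSpec",
    "FgnSpec",
    "SceneSpec",
    "Scene",
    "gen_trend_series",
    "gen_fgn",
    "gen_scene",
    "gen_daily_month",
    "fgn_autocovariance",
]

#: default study span: 39 annual values (e.g. 1982..2020)
DEFAULT_N_YEARS = 39
DEFAULT_START_YEAR = 1982


@dataclass(frozen=True)
class SeriesSpec:
    """One annual series: linear trend + AR(1) noise + optional step."""

    n_years: int = DEFAULT_N_YEARS
    intercept: float = 0.6
    slope: float = 0.0023          # per year; 0.023 per decade
    noise_sd: float = 0.05
    ar1_coef: float = 0.3
    change_year: int | None = None  # 0-based index of first shifted year
    change_magnitude: float = 0.0
    start_year: int = DEFAULT_START_YEAR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 3:
            raise ValueError("n_years must be at least 3")
        if not abs(self.ar1_coef) < 1:
            raise ValueError("ar1_coef must satisfy |phi| < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.change_year is not None and not (
            0 <= self.change_year < self.n_years
        ):
            raise ValueError("change_year outside the series")


def _ar1_noise(n: int, sd: float, phi: float, rng: np.random.Generator
               ) -> np.ndarray:
    """AR(1) noise with stationary marginal sd ``sd``; stationary start."""
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1 - phi ** 2)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + shocks[t - 1]
    return e


def gen_trend_series(spec: SeriesSpec) -> AnnualSeries:
    """value(t) = intercept + slope*t + step(t)*magnitude + AR(1) noise."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_years, dtype=float)
    x = spec.intercept + spec.slope * t
    if spec.change_year is not None:
        x[spec.change_year:] += spec.change_magnitude
    x += _ar1_noise(spec.n_years, spec.noise_sd, spec.ar1_coef, rng)
    years = spec.start_year + np.arange(spec.n_years)
    return AnnualSeries(years, x, "NDVI")


# ---------------------------------------------------------------------------
# Exact fractional Gaussian noise (Davies–Harte circulant embedding)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FgnSpec:
    n: int
    hurst: float
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if not 0 < self.hurst < 1:
            raise ValueError("hurst must lie in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def fgn_autocovariance(k: np.ndarray, hurst: float, sigma: float = 1.0
                       ) -> np.ndarray:
    """gamma(k) = sigma^2/2 (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})."""
    k = np.abs(np.asarray(k, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * sigma ** 2 * (
        np.abs(k + 1) ** h2 - 2 * np.abs(k) ** h2 + np.abs(k - 1) ** h2
    )


def gen_fgn(spec: FgnSpec) -> np.ndarray:
    """Exact stationary fGn sample of length n via circulant embedding.

    The circulant eigenvalues of the embedded autocovariance are
    provably non-negative for fGn, so the construction is exact; tiny
    negative values from floating-point round-off are clipped, and a
    genuinely indefinite embedding raises.
    """
    n, h, sigma = spec.n, spec.hurst, spec.sigma
    rng = np.random.default_rng(spec.seed)
    m = 2 * (n - 1) if n > 1 else 2
    row = np.empty(m)
    gam = fgn_autocovariance(np.arange(n), h, sigma)
    row[:n] = gam
    row[n:] = gam[1:-1][::-1]
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        raise ValueError(
            f"circulant embedding not positive semidefinite (min eigenvalue "
            f"{lam.min():.3e}); cannot generate exact fGn for H={h}"
        )
    lam = np.clip(lam, 0.0, None)
    # Hermitian-symmetric Gaussian spectrum -> real field via inverse FFT
    z = np.empty(m, dtype=complex)
    half = m // 2
    z[0] = rng.normal() * np.sqrt(m * lam[0])
    z[half] = rng.normal() * np.sqrt(m * lam[half])
    a = rng.normal(size=half - 1)
    b = rng.normal(size=half - 1)
    z[1:half] = np.sqrt(m * lam[1:half] / 2) * (a + 1j * b)
    z[half + 1:] = np.conj(z[1:half][::-1])
    x = np.fft.ifft(z).real[:n]
    return x


# ---------------------------------------------------------------------------
# Scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneSpec:
    """A synthetic study region: index cube, climate cubes, two mask epochs.

    ``coupling`` maps climate-variable name to the target population
    correlation between the variable's anomalies and the index anomalies
    at the same pixel. ``trend_field`` (n_lat x n_lon, per-year slopes)
    defaults to a uniform ``slope``.
    """

    n_lat: int = 20
    n_lon: int = 20
    lat_extent: tuple[float, float] = (44.0, 54.0)
    lon_extent: tuple[float, float] = (115.0, 135.0)
    n_years: int = DEFAULT_N_YEARS
    start_year: int = DEFAULT_START_YEAR
    intercept: float = 0.6
    slope: float = 0.0023
    trend_field: np.ndarray | None = None
    noise_sd: float = 0.05
    ar1_coef: float = 0.3
    change_year: int | None = None
    change_magnitude: float = 0.0
    coupling: dict = field(default_factory=lambda: {
        "TMP": 0.7, "TMX": 0.5, "TMN": 0.4, "PRE": -0.1,
    })
    climate_params: dict = field(default_factory=lambda: {
        # mean level, per-year trend, anomaly sd — plausible regional values
        "TMP": (2.0, 0.02, 0.6), "TMX": (8.0, 0.02, 0.7),
        "TMN": (-4.0, 0.03, 0.7), "PRE": (450.0, 0.15, 45.0),
    })
    mask_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid must be at least 1x1")
        if self.lat_extent[0] >= self.lat_extent[1] or \
                self.lon_extent[0] >= self.lon_extent[1]:
            raise ValueError("extents must be ordered (min, max)")
        if not 0 < self.mask_fraction <= 1:
            raise ValueError("mask_fraction must lie in (0, 1]")
        if not abs(self.ar1_coef) < 1:
            raise ValueError("|ar1_coef| must be < 1")
        for var, rho in self.coupling.items():
            if not -1 <= rho <= 1:
                raise ValueError(f"coupling[{var}] outside [-1, 1]")
        if self.trend_field is not None:
            tf = np.asarray(self.trend_field, dtype=float)
            if tf.shape != (self.n_lat, self.n_lon):
                raise ValueError("trend_field shape must be (n_lat, n_lon)")
            object.__setattr__(self, "trend_field", tf)


@dataclass
class Scene:
    """Generated scene plus its ground truth."""

    ndvi: RasterStack
    climate: dict[str, RasterStack]
    mask_epoch1: WetlandMask
    mask_epoch2: WetlandMask
    truth_slope: np.ndarray        # imposed per-year slope field
    truth_coupling: dict[str, float]
    n_clipped: int


def _smooth2d(a: np.ndarray, passes: int = 8) -> np.ndarray:
    """Cheap separable box smoothing (keeps the generator dependency-free)."""
    out = a.copy()
    for _ in range(passes):
        out = (np.roll(out, 1, 0) + out + np.roll(out, -1, 0)) / 3.0
        out = (np.roll(out, 1, 1) + out + np.roll(out, -1, 1)) / 3.0
    return out


def _blob_mask(rng: np.random.Generator, shape: tuple[int, int],
               fraction: float) -> np.ndarray:
    if fraction >= 1.0:
        return np.ones(shape, dtype=bool)
    fld = _smooth2d(rng.normal(size=shape))
    thr = np.quantile(fld, 1.0 - fraction)
    return fld > thr


def gen_scene(spec: SceneSpec) -> Scene:
    """Generate an index cube, coupled climate cubes and two mask epochs."""
    rng = np.random.default_rng(spec.seed)
    ny, nx, nt = spec.n_lat, spec.n_lon, spec.n_years
    lat = np.linspace(*spec.lat_extent, ny)
    lon = np.linspace(*spec.lon_extent, nx)
    t = np.arange(nt, dtype=float)
    slope_field = (np.full((ny, nx), spec.slope)
                   if spec.trend_field is None else spec.trend_field)

    # standardized AR(1) index anomalies shared with the climate couplings
    if spec.noise_sd > 0:
        u = np.empty((nt, ny, nx))
        innov = np.sqrt(1 - spec.ar1_coef ** 2)
        u[0] = rng.normal(size=(ny, nx))
        for k in range(1, nt):
            u[k] = spec.ar1_coef * u[k - 1] + innov * rng.normal(size=(ny, nx))
    else:
        u = np.zeros((nt, ny, nx))

    ndvi_vals = (spec.intercept
                 + slope_field[None, :, :] * t[:, None, None]
                 + spec.noise_sd * u)
    if spec.change_year is not None:
        ndvi_vals[spec.change_year:] += spec.change_magnitude
    n_clipped = int(np.sum((ndvi_vals < -1) | (ndvi_vals > 1)))
    if n_clipped:
        warnings.warn(f"clipped {n_clipped} index samples to [-1, 1]",
                      stacklevel=2)
    ndvi_vals = np.clip(ndvi_vals, -1.0, 1.0)

    time = pd.DatetimeIndex(
        [pd.Timestamp(spec.start_year + k, 1, 1) for k in range(nt)]
    )
    ndvi = RasterStack(ndvi_vals, time, lat, lon, variable="NDVI",
                       attrs={"n_clipped": n_clipped})

    # latitudinal gradient so climate fields are spatially structured
    lat_grad = (lat - lat.mean()) / max(np.ptp(lat), 1e-9)
    climate: dict[str, RasterStack] = {}
    for var, rho in spec.coupling.items():
        mean, trend, sd = spec.climate_params.get(var, (0.0, 0.0, 1.0))
        w = rng.normal(size=(nt, ny, nx))
        # Solve the noise-mixing weight so that the population correlation of
        # the FULL series (trend + noise, with time treated as a uniform
        # index) equals the coupling target. With index X = b t + sigma u and
        # climate Y = d t + s v, corr(u, v) = m:
        #   corr(X, Y) = (b d Vt + sigma s m) / sqrt((b^2 Vt + sigma^2)(d^2 Vt + s^2))
        # where Vt = Var(t). Infeasible targets (|m| > 1, e.g. noise-free
        # scenes) are clipped with a warning.
        vt = float(np.var(t))
        b = slope_field
        num = (rho * np.sqrt((b ** 2 * vt + spec.noise_sd ** 2)
                             * (trend ** 2 * vt + sd ** 2))
               - b * trend * vt)
        if spec.noise_sd > 0 and sd > 0:
            mix = num / (spec.noise_sd * sd)
        else:
            mix = np.full_like(b, rho)
        if np.any(np.abs(mix) > 1):
            warnings.warn(
                f"coupling target {rho} for {var} infeasible at some pixels; "
                "mixing weight clipped", stacklevel=2)
            mix = np.clip(mix, -1.0, 1.0)
        anom = mix[None, :, :] * u + np.sqrt(1 - mix ** 2)[None, :, :] * w
        vals = (mean
                - lat_grad[None, :, None] * (abs(mean) * 0.1 + 0.1)
                + trend * t[:, None, None]
                + sd * anom)
        units = "mm" if var == "PRE" else "degC"
        climate[var] = RasterStack(vals, time, lat, lon, variable=var,
                                   units=units)

    m1 = _blob_mask(rng, (ny, nx), spec.mask_fraction)
    # second epoch: correlated with the first so the intersection is stable
    if spec.mask_fraction >= 1.0:
        m2 = np.ones((ny, nx), dtype=bool)
    else:
        fld1 = _smooth2d(rng.normal(size=(ny, nx)))
        base = np.where(m1, 1.0, -1.0)
        fld = 0.8 * base + 0.6 * fld1
        thr = np.quantile(fld, 1.0 - spec.mask_fraction)
        m2 = fld > thr
    if not (m1 & m2).any():
        raise ValueError("generated mask epochs have empty intersection")
    mask1 = WetlandMask(m1, lat, lon, epoch="epoch1")
    mask2 = WetlandMask(m2, lat, lon, epoch="epoch2")
    return Scene(ndvi, climate, mask1, mask2, slope_field.copy(),
                 dict(spec.coupling), n_clipped)


def gen_daily_month(values: np.ndarray, dropout: float = 0.0,
                    seed: int = 0) -> np.ndarray:
    """Daily sequence with reproducible dropouts (NaN) for MVC tests."""
    vals = np.asarray(values, dtype=float).copy()
    if vals.size < 1:
        raise ValueError("need at least one daily value")
    if not 0 <= dropout <= 1:
        raise ValueError("dropout must lie in [0, 1]")
    if dropout > 0:
        rng = np.random.default_rng(seed)
        miss = rng.random(vals.size) < dropout if dropout < 1.0 else \
            np.ones(vals.size, dtype=bool)
        vals[miss] = np.nan
    return vals
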