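# rastertrend

Trend, persistence, change-point and climate-association analysis for
gridded vegetation-index time series.

`rastertrend` is aimed at ecological remote-sensing work of the common
"greening/browning attribution" kind: you have a multi-decade stack of
annual (or daily/monthly, to be composited) NDVI-like values on a
latitude–longitude grid, matching gridded climate variables (mean, maximum
and minimum temperature; precipitation), and a wetland or land-cover mask
at two mapping epochs — and you want per-pixel and regional answers to
*is vegetation greening, will the tendency persist, when did it shift,
and which climate variable drives it?*

## Methods at the core

All statistics are nonparametric and operate per pixel (or on a regional
mean series) over the annual growing-season values `X(t)`:

- **Theil–Sen slope** `Q = median_{i<j} (X_j − X_i)/(t_j − t_i)`, reported
  per decade (`10·Q`), with intercept `median(X − Q·t)`.
- **Mann–Kendall test** on `S = Σ_{i<j} sgn(X_j − X_i)` with
  `Var(S) = n(n−1)(2n+5)/18`, continuity-corrected
  `Z = (S∓1)/√Var(S)`; `|Z| > 1.96 ⇔ p < 0.05`. Pixels are classed as
  significant increase / significant decrease / nonsignificant.
- **Rescaled-range Hurst exponent**: blockwise `R/S` statistics fitted by
  `log(R/S) = a + H·log(τ)`; `H > 0.5` persistent (future tendency
  consistent with the past), `H < 0.5` anti-persistent, with reporting
  bins `(0.5, 0.7]` and `(0.7, 1)`.
- **Sequential Mann–Kendall (SQMK)**: progressive forward `UF_k` and
  backward `UB_k` standardized rank statistics; a crossing of the two
  curves inside the ±1.96 band marks an abrupt-change year.
- **Pearson, lagged and first-order partial correlation**
  `r_xy.z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²))` between the index
  and each climate variable, with four-way sign/significance categories,
  1–2-year precipitation lags, and zonal (latitudinal/longitudinal)
  profiles with turning-point detection.

Everything upstream of these statistics — daily→monthly maximum-value
compositing, May–September growing-season aggregation, nearest-neighbour
grid harmonization, two-epoch unchanged-wetland masking — is included, as
is a synthetic-scene generator (linear trends + AR(1) noise, exact
fractional Gaussian noise via circulant embedding, prescribed
index–climate coupling, blob masks) that provides known ground truth for
every stage.

## Worked example

```python
import numpy as np
from rastertrend import (SceneSpec, gen_scene, trend_map, regional_series,
                         trend_series, pearson, sqmk, hurst_map)
from rastertrend.raster import unchanged_mask

scene = gen_scene(SceneSpec(n_lat=12, n_lon=12, n_years=39,
                            coupling={"TMP": 0.7, "PRE": -0.1}, seed=42))
mask = unchanged_mask(scene.mask_epoch1, scene.mask_epoch2)
basin = regional_series(scene.ndvi, mask)

tr = trend_series(basin)
print(f"basin slope: {tr.slope_per_decade:+.4f} per decade "
      f"(MK p = {tr.p:.2e}, {tr.trend_class.value})")
tmap = trend_map(scene.ndvi, mask)
print("pixel trend fractions:", {k: round(v, 3) for k, v in tmap.fractions.items()})
hm = hurst_map(scene.ndvi, mask)
print(f"mean Hurst exponent: {hm.mean_h:.3f}; "
      f"persistent fraction: {hm.class_fractions['persistent']:.3f}")
for var in ("TMP", "PRE"):
    r = pearson(basin, regional_series(scene.climate[var], mask))
    print(f"NDVI~{var}: r = {r.r:+.3f} (p = {r.p:.3g}, {r.category.value})")
```

prints

```
basin slope: +0.0240 per decade (MK p = 3.09e-15, significant_increase)
pixel trend fractions: {'significant_increase': 0.847, 'significant_decrease': 0.0, 'nonsignificant': 0.153}
mean Hurst exponent: 0.757; persistent fraction: 0.986
NDVI~TMP: r = +0.959 (p = 7.25e-22, sig_positive)
NDVI~PRE: r = +0.258 (p = 0.112, nonsig_positive)
```

The scene was built with a +0.0023/yr index trend (hence the recovered
+0.024 per decade), strong temperature coupling and weak negative
precipitation coupling; the basin-level temperature correlation dominates
because both series share the warming trend, exactly the situation the
partial-correlation tools are there to disentangle.

The same analyses run from the shell: `rastertrend simulate`,
`composite`, `season`, `mask-intersect`, `trend`, `hurst`, `sqmk`,
`correlate`, `profile`, and `rastertrend run --config run.yaml` for the
full pipeline (see `rastertrend --help`).

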