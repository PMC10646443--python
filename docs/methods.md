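# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter for reproducing
results.

## Data model and grid conventions

A `RasterStack` is a `time × lat × lon` cube of one variable with NaN as
the missing flag; coordinates are cell centers in degrees, strictly
monotone, longitude in [−180, 180). Grids are regular. An `AnnualSeries`
is one pixel's (or one region's) yearly growing-season values — the unit
of every 1-D statistic. A `WetlandMask` is a boolean grid for one mapping
epoch; the analysis mask is the cellwise AND of two epochs ("unchanged"
wetland), so statistics are never computed over pixels that changed class
between mappings.

Stacks round-trip through NetCDF (xarray, scipy backend). Masks and
per-pixel result maps round-trip through single-band TIFF with grid
coordinates carried in the image description tag and a −9999 no-data
value; no CRS machinery is involved because all grids are plain
geographic lat/lon.

Nearest-neighbour resampling assigns each output cell the value of the
source cell whose center is nearest; equidistant ties break toward the
lower index (fixed and tested for reproducibility). Missing stays
missing.

## Compositing and seasonal aggregation

Monthly maximum-value compositing takes the per-pixel maximum over each
calendar month's non-missing daily values (cloud and atmospheric effects
bias optical indices low, so the monthly maximum is the standard
estimator of the uncontaminated value); a cell is missing only when every
day is. The growing season is May–September. Seasonal reduction is the
mean for index and temperature variables and the **sum** for
precipitation — a seasonal precipitation total is the hydrologically
standard quantity; the reducer is configurable since conventions differ.
The missing-month policy defaults to lenient (use whatever months exist);
a strict mode marks a year missing when any required month is.

## Trend: Theil–Sen + Mann–Kendall

Slope `Q = median{(X_j − X_i)/(t_j − t_i)}` over all pairs, using real
year coordinates so missing years simply drop out pairwise; intercept
`median(X − Q t)`. Reporting is per decade (10×Q), the usual convention
for slow vegetation-index trends.

Mann–Kendall uses the pairwise-sign statistic `S`, variance
`n(n−1)(2n+5)/18`, and the ±1 continuity-corrected normal `Z`; p-values
come from the normal approximation (no exact small-sample tables), which
matches the `|Z| > 1.96 ⇔ p < 0.05` decision rule for n ≈ 39. Two
variance modes exist: plain (no tie term, the default — annual index
values are effectively continuous so ties are rare) and tie-corrected
(standard group correction). Classification is three-way: significant
increase (Q > 0, p < α), significant decrease (Q < 0, p < α), else
nonsignificant.

No prewhitening is applied: the statistics are implemented exactly as
defined. Under serial correlation the MK test is anticonservative — with
AR(1) φ = 0.3 and n = 39 the empirical type-I rate is roughly 0.17 at
nominal 0.05 — which is a documented property of the plain test, not a
defect; the null-calibration claim (type-I ∈ [0.04, 0.06]) is made, and
verified, for iid series.

## Persistence: rescaled-range Hurst exponent

For window length τ the series is cut into consecutive non-overlapping
blocks of length τ; per block, R is the range of cumulative deviations
from the block mean and S the **population** standard deviation (divide
by τ, matching the defining formula); blocks with S = 0 are skipped, an
all-degenerate (constant) series is an error. H is the OLS slope of
log(mean R/S) on log(τ). The τ schedule defaults to {4, …, ⌊n/2⌋} so every
window has ≥ 2 complete blocks; it is configurable. No small-sample
(Anis–Lloyd) bias correction is applied by default — the classical
estimator is biased toward 0.5-from-above for short series (measured here:
mean ĥ ≈ 0.56 on iid noise at n = 512, ≈ 0.41 at H = 0.3, ≈ 0.78 at
H = 0.8) — so all recovery claims are distributional statements over
replicates, never single-draw assertions. Classification: H < 0.5
anti-persistent, H > 0.5 persistent, H = 0.5 "random" only within 1e−9;
persistent pixels are additionally binned into (0.5, 0.7] and (0.7, 1).

## Abrupt change: sequential Mann–Kendall

Forward statistic per Sneyers: `R_i = #{j ≤ i : X_i > X_j}` (ties add
nothing), `S_k = Σ R_i`, `UF_k = (S_k − k(k−1)/4)/√(k(k−1)(2k+5)/72)`
with `UF_1 = 0`. The mean and variance are evaluated at the **running
index k**, not the full length n: the standardization must track the
growing subsample, and implementing the printed-with-n variant would make
UF non-pivotal. The backward curve is the negated forward statistic of
the reversed series mapped back onto the original axis, which makes
`sqmk(reverse(X)).uf == −reverse(sqmk(X).ub)` an exact identity (tested
to 1e−12). Crossings of UF and UB are located by linear interpolation of
UF − UB between adjacent years, reported at the nearer integer year, and
flagged `within_band` when the interpolated |UF| is inside the
±z₁₋α/₂ band (±1.96 at α = 0.05). All crossings are reported; no
"primary" one is selected, since real series (e.g. minimum temperature)
can have several genuine break points.

Localization precision: on a 1.5σ mean shift at the middle of an n = 39
series the crossing estimate is essentially unbiased (median offset
≈ −0.4 yr) but has a spread of ≈ 3.5 yr sd, so ≈ 70% of replicates land
within ±3 years and ≈ 86% within ±5. This dispersion is intrinsic to the
UF/UB crossing construction at that effect size.

## Association

Pearson correlation uses the product-moment formula with the exact t
reference (df = n−2); the lagged variant correlates the index of year t
with a driver of year t−lag (lags 0–2, for delayed precipitation
effects), with the effective sample reduced accordingly. The four-way
category (significant/nonsignificant × positive/negative) uses strict
`p < α`; r = 0 is grouped with the positive side so the categories
partition. No multiple-testing correction is applied across pixels —
category fractions are descriptive map summaries, not simultaneous
inference.

First-order partial correlation uses the three pairwise coefficients;
significance with df = n−3. The formula is verified against the
residual-regression definition (correlate the residuals of x|z and y|z)
to 1e−10 on random trivariate Gaussian samples.

Regional series are unweighted means over masked, non-missing pixels
("average of all wetland pixels"); cosine-latitude weighting is available
as an option. Two-period analyses subset by closed year intervals, so a
boundary year shared by both periods (e.g. 2000 in 1982–2000 and
2000–2020) is deliberately included in both.

## Zonal profiles

A profile is the mean of a masked per-pixel field over contiguous bands
(default width 0.5°, the typical native climate-grid resolution) along
latitude or longitude; empty bands are missing. Turning points are interior
bands where the first difference of a moving-average-smoothed profile
(window 3 bands; edges shrink the window) changes sign, with flat
stretches skipped so a plateau counts once. Turning-point detection is
invariant to adding a constant to the profile.

## Synthetic data: what it emulates, what it does not

- **Series**: linear trend + AR(1) Gaussian noise, AR(1) initialized
  from its stationary distribution (no transient early years), optional
  step change. Defaults mirror the study scale: 39 years, intercept 0.6,
  slope 0.0023/yr (0.023/decade), noise sd 0.05, φ = 0.3. The AR(1)
  structure is an assumption — real NDVI noise structure is not known —
  and is exposed as a parameter.
- **fGn**: exact Davies–Harte circulant embedding of the fGn
  autocovariance `γ(k) = σ²/2(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})`. The
  embedding is provably nonnegative-definite for fGn; round-off-scale
  negative eigenvalues are clipped and a genuinely indefinite embedding
  raises. This gives an unbiased oracle for the R/S estimator.
- **Scenes**: per-pixel slope field; climate cubes with a latitudinal
  gradient, linear trend and anomalies built by mixing a fresh noise
  field with the index's standardized AR(1) anomalies. The mixing weight
  is solved per pixel so that the **full-series** population correlation
  (time treated as a uniform index, trends included) equals the coupling
  target; infeasible targets (e.g. noise-free pixels) are clipped with a
  warning. Index values are clipped to [−1, 1] after noise addition and
  the clip count is recorded in the stack attributes.
- **Masks**: thresholded smoothed Gaussian noise gives blob-shaped
  extents at a prescribed areal fraction; the second epoch mixes the
  first epoch's field with fresh noise so the intersection is stable and
  non-empty (empty intersection raises).

Not emulated: phenology or radiative transfer, cloud/atmosphere artifacts
beyond simple dropouts, real geographic boundaries, spatial correlation
of the noise between pixels (pixel noises are independent, so map-level
sampling variability is optimistic relative to real, spatially correlated
data). Passing tests therefore demonstrate correctness of the statistics
and pipeline plumbing under a known stochastic model, not realism of any
particular ecological conclusion.

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds (`numpy.random.default_rng`);
analysis stages are deterministic, so a pipeline rerun with the same
config byte-reproduces the JSON report (stamped with a config hash and
seed). The calibration/recovery script uses 10,000 replicates for the MK
null rate, 2,000 for Theil–Sen recovery, 200 per H value (n = 512) for
Hurst recovery, 500 for SQMK detection, 100 for the partial-correlation
oracle and 20 instances per brute-force equivalence check, with the
end-to-end scene at 20×20×39 — sizes chosen so each claim's Monte-Carlo
error is an order of magnitude below the asserted tolerance while the
whole script runs in well under a minute on one core.

## Known limitations

- Plain MK inflates type-I error under positive autocorrelation (no
  prewhitening option yet).
- R/S Hurst is biased for short series; at n = 39 per-pixel estimates are
  noisy and only distributional/map-level statements are meaningful.
- SQMK crossing years carry ±3–4 yr uncertainty at moderate effect sizes.
- TIFF outputs carry coordinates in a private tag, not CRS metadata;
  consumers expecting georeferenced GeoTIFF need a conversion step.
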