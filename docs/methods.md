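# Methods

`grasstrend` implements a raster time-series workflow for mapping grassland
degradation, attributing it to climate versus human drivers, and forecasting
its persistence. This note documents the models, the choices made where the
design was genuinely open, and what the synthetic validation does and does
not demonstrate.

## Indicators: NDVI and windowed CV

Vegetation cover is tracked by annual NDVI; spatial heterogeneity by the
coefficient of variation of NDVI inside a 3×3-pixel moving window,

    CV = s / m,

where `s` is the sample (n−1) standard deviation and `m` the mean of the
nine window values for that year. Degrading grassland becomes patchy
(bare-soil gaps), so a rising CV is an early-warning signal even while mean
cover still rises. The windowed statistics require all nine cells valid;
window centers at scene edges or touching nodata are nodata. A companion
3×3 window median gives the per-year cover value. Window mean ≤ 0 also
yields nodata (CV is meaningless there).

## Trend mapping

Per-pixel trends are Theil–Sen slopes (median of all pairwise slopes), with
significance from the two-sided Mann–Kendall test:

    S = Σ_{i<j} sgn(a_j − a_i),
    Var(S) = [n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)] / 18   (tie groups t),
    Z = (S∓1)/√Var(S)  for S≷0,  Z = 0 for S = 0,

with a two-sided normal p-value and default α = 0.05. Exact zero slopes are
carried as 0 and become the `Stable` class downstream rather than being
perturbed. No pre-whitening is applied (annual series, n ≈ 20).

## Degradation levels

Each pixel maps to one of six levels from (sign of NDVI slope, sign of CV
slope, mean windowed-median NDVI vs 0.2): Improving, Regrowing, Slight /
Moderate / Severe degradation, Desertification; 0.2 is closed on the high
side, and the "NDVI value" is the study-period mean of the per-year window
median. Hot plots are detected with Anselin's Local Moran's I of the NDVI
Sen slope over the degraded region, with row-standardized queen weights,
999 conditional permutations and α = 0.05; none of these four choices is
forced by the classification itself, so all are configurable.

## Improved residual-trend attribution

RESTREND assumes NDVI responds linearly to climate; what the regression
cannot explain is attributed to human activity:

    NDVI_C = aT + bP + cS + d       (per-pixel OLS),
    NDVI_H = NDVI_obs − NDVI_C,
    CV_C   = windowed CV of the NDVI_C stack,  CV_H = CV_obs − CV_C.

The predictor set is chosen once per scene by combining two methods: a
random forest (500 trees) ranks candidates by permutation importance, and
bidirectional stepwise OLS (entry p ≤ 0.05, removal p ≥ 0.10) on the
spatially averaged series decides retention. A variable is selected only if
it is retained by stepwise *and* carries positive forest importance (above
1% of the top importance), ordered by importance. Two details matter in
practice and are deliberate:

- importance is computed on *within-pixel temporal anomalies* (each pixel's
  mean removed), otherwise any spatially structured variable acts as a
  location proxy and inflates its importance;
- importance is scored on a held-out half of the subsample, since
  training-set permutation importance credits memorized noise, and a
  leaf-size floor (`min_samples_leaf = 15`) stabilizes the ranking. The
  stepwise-only rule would admit a pure-noise decoy with probability
  ≈ 1 − 0.95^k for k decoys; requiring support from both methods is the
  stricter and more stable reading of "combining" them.

Driver classes compare the signs of the observed, climate and human slopes
(the same table serves NDVI and CV): same-sign climate with opposing human
→ climate-driven (100%/0%); the reverse → human-driven (0%/100%); all three
same sign → both, with contributions 100·slope_C/slope_obs and
100·slope_H/slope_obs. **Slopes inside this table are OLS slopes**, because
OLS is exactly additive under the decomposition, so contributions sum to
100% identically; Sen/M–K remains the mapping method everywhere else. A
Sen-based mode (with renormalization to restore additivity) exists for
sensitivity checks. The (NDVI driver, CV driver) pair indexes one of twelve
scenarios; the 36-row lookup is generated by the closed rule *combined
driver = C for {CC, CB, BC}, H for {HH, HB, BH}, B for {CH, HC, BB}* with
the scenario group fixed by the two trend directions, and is tested
row-by-row against the full table.

## Persistence forecast

The Hurst exponent is estimated per pixel by rescaled-range analysis: for
each window length m the series is cut into ⌊n/m⌋ blocks; each block
contributes (range of cumulative deviations from the block mean) / (block
population sd); H is the slope of the OLS fit of log(R/S) on log(m),
clipped to (0, 1). For short annual series the window set is every integer
8 ≤ m ≤ n/2 (n = 20 → {8, 9, 10}); for long series, twelve log-spaced
lengths. Plain (uncorrected) R/S is the default; the Anis–Lloyd
small-sample expectation (exact gamma form below m = 340) is available
behind `correction=True` and demonstrably reduces white-noise bias. With 20
annual points H is noisy — the log–log fit R² is carried as a quality flag.
The transition map keeps the trend signs where H > 0.5, flips them where
H < 0.5, marks H = 0.5 or missing as indeterminate, re-applies the level
classification, and reports the four classes (continuous improvement,
degradation → improvement, improvement → degradation, continuous
degradation) from membership in the degraded set {Slight, Moderate, Severe,
Desertification}; {Improving, Regrowing, Stable} count as improved.

## The synthetic scene and its ground truth

Every stage is validated on scenes whose generating process *is* the model
the attribution assumes. Per pixel,

    NDVI(t) = Σ_v coef_v·clim_v(t) + d + texture + h_p·t + ε(t),

clipped to the physical range [−0.2, 1] **before** noise is added
(saturation is part of the signal, so truth and pipeline see the same
deterministic series; saturated-cell counts are reported). Components:

- **Climate**: smooth time-constant spatial field + linear trend + an
  interannual anomaly drawn once per year (weather is regional at scene
  scale) + optional per-pixel microclimate noise. The yearly anomaly is
  **detrended in-sample**, so each pixel's realized climate trend equals the
  prescribed one exactly; without this, a 20-year anomaly realization
  carries a random trend of the same order as the prescribed one and the
  scene's nominal conditions are simply not realized in the sample.
- **Micro-site texture** (default sd 0.08 NDVI): static soil/topography
  heterogeneity. It is the carrier of the CV signal — without it the 3×3
  window sd is observation-noise dominated and CV trends carry no
  information.
- **Human trend** h_p = h·(1 + δ·u_p) with a fixed per-pixel multiplier
  (u_p ~ N(0,1) clipped at ±2, δ the region's patchiness). Patchy pressure
  (δ > 0) raises window heterogeneity over time, which is how degradation
  reaches the CV axis; uniform restoration (δ = 0) lowers CV as cover rises.
- Default conditions: 40×40 pixels × 20 years, NDVI noise sd 0.02, four
  quadrant regimes (both-driver improvement; patchy slight degradation;
  human-driven and climate-driven moderate degradation), every driver
  component ≥ 0.003 NDVI/yr in magnitude. Temperature and precipitation are
  the true predictors; sunshine, wind and radiation are decoys.

**Truth labels.** The generator's driver field records which components are
switched on. Scenario and level truth, however, are defined on the
*identifiable* decomposition: the share of a linear human trend that is
collinear in-sample with the climate series cannot be recovered by any
residual method (it is absorbed into the regression's climate coefficients
by construction), so the true component slopes are the exact OLS projection
of the noise-free signal onto the true predictor set, computed
independently of the estimation pipeline. With zero observation noise the
pipeline reproduces this truth at every labelled pixel; at the default
noise it recovers 91–95% across seeds.

**What passing these tests does not show.** The generator realizes the
attribution model's own assumptions: linear instantaneous climate response,
additive linear human trend, Gaussian noise, no lags, no phenology, no
clouds or gaps, rectangular regions. Recovery rates here are upper bounds
on real-data behavior, where lagged and nonlinear responses, disturbance
events, and sensor artifacts all violate the model. The scene validates the
machinery and its bookkeeping, not the ecological adequacy of RESTREND.

## Fractional Gaussian noise oracle

Hurst-estimator tests use exact-covariance fGn via circulant (Davies–Harte)
embedding: eigenvalues are the FFT of the autocovariance
γ(k) = ½(|k+1|^2H − 2|k|^2H + |k−1|^2H) on the 2n-circle; series length must
be a power of two ≥ 64 (keeps the embedding nonnegative and the FFT fast).
The lag-1 autocorrelation 2^(2H−1) − 1 and unit variance are asserted in
tests, making the generator an oracle that is independent of the R/S
estimator it checks.

## Numerical choices and degenerate inputs

- Pixel regressions are solved by batched normal equations; Gram
  determinants below 1e−12 mark a pixel rank-deficient → nodata with a
  warning. Constant NDVI gives zero coefficients, intercept = the constant,
  R² reported as 0.
- Sen/M–K need ≥ 2 / ≥ 4 valid points; R/S needs ≥ 16 and a non-constant
  series; pixels failing these are nodata, never silently filled.
- Resampling works in cell-center map coordinates; bilinear never invents
  values outside the local envelope, and any target cell touching a nodata
  source cell is nodata. Climate is bilinear-resampled, masks
  nearest-resampled. Inputs must share a CRS (no reprojection).
- Road/river masks are dilated by a configurable buffer (default 1 pixel,
  queen-shaped) before exclusion.
- Local Moran's I p-values are one-sided conditional-permutation pseudo
  p-values ((extreme + 1)/(perms + 1)), slightly conservative by
  construction.

## Problem sizes used in validation

The shipped test-suite and acceptance runs use: 1,000 series (lengths 5–30)
for the estimator-oracle check; 10,000 replicates (n = 20) for Mann–Kendall
calibration; 30×30 (noiseless) and 60×60 (noisy) regression-recovery
scenes; 50 seeded 20×20 scenes for selection recovery (RF subsample 3,000
pixel-year anomalies); 200 fGn replicates of length 1,024 at each of five H
values; and the 40×40 default scene for end-to-end scenario recovery. These
sizes give binomial/Monte-Carlo standard errors comfortably inside each
acceptance band.

## Known limitations

- RESTREND's identifiability limit (collinear human trend absorbed into
  climate) is inherent, not an implementation artifact; see the truth-label
  discussion above.
- The coverage check for regression recovery uses ±2 standard errors built
  from the *known* noise sd, giving an exactly Gaussian pivot (nominal
  95.45%). With SEs *estimated* at 16 residual dof, the same ±2·SE interval
  covers only P(|t₁₆| ≤ 2) ≈ 93.7% — a Student-t fact worth remembering
  when reading per-pixel regression output from 20-year series.
- Scenario groups with jointly falling NDVI and CV (severe degradation /
  desertification, scenarios 10–12) appear only marginally in the default
  scene; generating them requires heterogeneity collapse (variance
  reversion), which the additive generator does not model. The lookup
  itself is exercised exhaustively in the table tests.
- With n = 20, per-pixel Hurst estimates have sd ≈ 0.1; the forecast map
  should be read as a persistence tendency, not a prediction.
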