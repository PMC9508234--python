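# grasstrend

Raster time-series analysis of grassland degradation: trend mapping from
NDVI and its windowed coefficient of variation, attribution of each pixel's
dynamics to climate versus human drivers by an improved residual-trend
(RESTREND) method with twelve driver scenarios, and persistence forecasting
with the rescaled-range Hurst exponent.

**Who it is for.** Ecologists and remote-sensing analysts who have
co-registered annual raster stacks (NDVI plus climate grids and masks) and
want a reproducible, testable pipeline from those stacks to degradation
maps, driver-contribution rates and forecast maps — plus a synthetic-scene
generator with known per-pixel ground truth for validating every stage.

## The methods in brief

- **Spatial heterogeneity**: per year, CV_NDVI = s/m over a 3×3 moving
  window (sample sd / mean) — rising CV flags the bare-patch mosaics of
  degrading grassland even while mean cover still rises.
- **Trends**: Theil–Sen slope M = median{(a_j − a_i)/(j − i)} with the
  Mann–Kendall test (S statistic, tie-corrected Var(S), continuity-corrected
  Z) at α = 0.05.
- **Degradation levels**: the (sign NDVI slope, sign CV slope, NDVI ≷ 0.2)
  truth table → Improving, Regrowing, Slight/Moderate/Severe degradation,
  Desertification; hot plots by Anselin's Local Moran's I over the degraded
  region (queen weights, conditional permutations).
- **Attribution**: select dominant climate variables (random-forest
  importance ∩ stepwise regression), fit NDVI_C = aT + bP + cS + d per
  pixel by OLS, split NDVI_obs = NDVI_C + NDVI_H and CV likewise, classify
  drivers from the component slope signs with contribution rates
  100·slope_C/slope_obs + 100·slope_H/slope_obs = 100 exactly, and map the
  (NDVI driver, CV driver) pair to one of twelve scenarios (CDI … BDSD).
- **Forecast**: per-pixel Hurst exponent from R/S analysis
  (log(R/S) = a + H·log(m)); H > 0.5 keeps the current trend sign, H < 0.5
  flips it, H = 0.5 is unforecastable; re-classifying gives the four-class
  transition map (continuous improvement / degradation → improvement /
  improvement → degradation / continuous degradation).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

`examples/04_restrend_attribution.py` generates the default synthetic scene
(40×40 pixels × 20 years, four driver regimes, noise sd 0.02) and runs the
attribution chain:

```text
variable selection
  stepwise retained : ['precipitation', 'temperature']
  forest importance : precipitation=0.189, temperature=0.111, wind=0.005, ...
  selected          : ['precipitation', 'temperature']

pixel regressions: median R^2 = 0.920
mean climate contribution to NDVI change: 64.9% (human 35.1%; sums to 100 at every pixel)

scenario map (% of analyzed area):
  CDI   Climate-driven grassland improvement                     10.9%
  BDI   Both drivers effected grassland improvement              29.0%
  HDSR  Human activities-driven slight degradation or re-growing  7.1%
  CDMD  Climate-driven moderate degradation                      23.8%
  HDMD  Human activities-driven moderate degradation             21.7%
  ...

agreement with generator ground truth: 93.4% of labelled pixels
```

The selection stage rejects the three decoy variables (wind, radiation,
sunshine carry no NDVI response in the scene), the per-pixel regressions
recover the prescribed linear climate response, and 93% of pixels end up in
their true scenario; with observation noise switched off the agreement is
exact. The other examples cover scene simulation (`01`), trend mapping
(`02`), degradation levels and hot plots (`03`) and the Hurst forecast
(`05`); each prints what its numbers mean.

A thin CLI wraps the same library for shell use:

```bash
grasstrend run-all --config examples/run_config.yaml --seed 7
```

writes every stage product (coded maps with code tables, area summaries,
selection report) plus a checksummed manifest; re-running with the same
config and seed reproduces identical checksums.

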