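# greensar

Street-level urban greenspace and drive-by air pollution: metrics, spatial
diagnostics, and maximum-likelihood spatial-autoregressive effect estimation.

## The problem

Mobile (drive-by) air-quality campaigns produce pollutant concentrations —
PM2.5, NO2, NO (µg/m³), CO, CO2 (mg/m³) — at thousands of points along a
city's road network. Epidemiologists want to know whether street-level
greenery is associated with lower pollution, and at which spatial scale the
association operates. Such data are strongly spatially autocorrelated:
ordinary least squares understates uncertainty and can bias the association,
so the field uses simultaneous-autoregressive (SAR) regression instead.

This package implements that full analysis chain as a tested library:

- **Green View Index (GVI)** — the percentage of green pixels pooled over six
  segmented street-view images per location (60° viewing intervals):
  `GVI = 100 · Σᵢ Area_gᵢ / Σᵢ Area_tᵢ`, range 0–100.
- **NDVI** — `(NIR − R)/(NIR + R)` from near-infrared and red reflectance
  rasters (cloud-masked cells become missing), extracted at the exact point
  locations; range −1 to 1.
- **GVI:NDVI ratio** — the quotient of min-max-normalized GVI and NDVI,
  contrasting street-level with overhead greenery.
- **Exposure scales** — the point scale (nearest greenspace point) and buffer
  zones of radius 100/300/500/1000/2000 m (unweighted in-radius means).
- **Spatial weights** — sparse kernel matrix with adaptive bandwidths
  (distance to the (k+1)-th nearest neighbor) and a triangular kernel
  `w_ij = max(0, 1 − d_ij/h_i)`, row-standardized.
- **Diagnostics** — Moran's I (analytic randomization moments and permutation
  inference), the four Anselin Lagrange-multiplier tests (lag/error, robust
  variants), and multivariate outlier screening (z-score, Mahalanobis
  distance, skewness/kurtosis report).
- **Models** — ML estimation of the spatial lag model (SLM)
  `y = ρWy + Xβ + ε` and the spatial error model (SEM)
  `y = Xβ + u, u = λWu + ε`, with the log-determinant `log|I − ρW|` computed
  exactly (eigenvalues or sparse LU) and the likelihood concentrated in the
  spatial coefficient. Model choice follows Moran's I of the residuals.
- **Effects** — spillover total effect `T_ef = β₁/(1 − ρ)` with delta-method
  CI, and associations reported as percentage difference in pollution per
  interquartile-range (IQR) increase in greenspace:
  `pct = 100·(exp(β₁·IQR) − 1)` for log-scale pollutant models.

Because real campaigns of this kind are proprietary, the package ships a
**synthetic-city generator** with known ground truth (jittered 50 m road
grid over a ~10 km domain, spatially smooth greenspace and covariate fields,
segmented masks and band rasters that round-trip exactly through the metric
code, and pollution drawn from a SAR process with configurable ρ and a
negative greenspace coefficient), so every stage is testable end to end.

## Worked example

```sh
python analysis/01_simulate_city.py
python analysis/04_fit_sar_models.py
```

The second script fits all 90 models (5 pollutants × 3 metrics × 6 scales)
on a default city of 2,000 points and prints, among other things:

```
90 effect rows (0 skips); SLM chosen in 100% of fits

NO2 ~ GVI across spatial scales (% difference per IQR):
 scale    iqr  pct_diff  ci_low  ci_high   rho
 point 12.898   -23.329 -24.953  -21.669 0.474
 100 m 12.800   -23.138 -24.768  -21.474 0.475
 300 m 10.151   -22.147 -24.061  -20.184 0.423
 500 m  6.944   -15.341 -17.571  -13.051 0.513
1000 m  3.776    -4.041  -6.293   -1.736 0.684
2000 m  1.384    -1.485  -3.473    0.544 0.708
```

Read a row as: an IQR increase in GVI (12.9 percentage points at the point
scale) is associated with a 23.3% [95% CI −25.0, −21.7] lower NO2
concentration, conditional on temperature, precipitation, population density
and traffic, with spatial feedback ρ̂ ≈ 0.47. Buffer averaging over larger
radii shrinks the exposure contrast (IQR) and attenuates the estimated
association — the scale dependence the analysis is designed to reveal.
`analysis/05_effect_summary.py` tabulates sign and significance across all
90 fits.

The same pipeline is scriptable via the CLI
(`greensar simulate|greenspace|diagnose|fit|run`), driven by a YAML config
mirroring `StudyConfig` / `SyntheticCityConfig` fields, e.g.:

```yaml
simulate:
  n_points: 2000
  rho_true: 0.5
k_weights: 15
n_perm: 999
alpha: 0.05
seed: 1
```

## Layout

- `src/greensar/` — the library (synthetic city, greenspace metrics, spatial
  weights, diagnostics, SAR models, pipeline, CLI).
- `analysis/01…05_*.py` — narrative analysis scripts writing to `results/`
  (large raw tables go to `scratch/`).
- `docs/methods.md` — model assumptions, parameter choices, numerical
  details, and limitations.
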