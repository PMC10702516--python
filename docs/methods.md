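# Methods

## Study design being emulated

The package models a drive-by air-quality study: pollutant concentrations
measured at points along a city's road network, regressed on street-level
greenspace while controlling for meteorology, population density and
traffic. The regression units are the pollution points; greenspace is
measured on its own point set and aggregated to each unit at six spatial
scales (nearest point, and buffers of 100/300/500/1000/2000 m). All
quantities live in projected planar coordinates (meters).

## Greenspace metrics

**GVI.** Per location, six binary label masks (1 = green pixel) at 60°
viewing intervals are pooled: GVI = 100 · Σ green / Σ total. Pooling pixels
equals averaging per-image fractions when the images share a size and
remains well defined when they do not. Masks are validated to be exactly
six, non-empty, and binary.

**NDVI.** (NIR − R)/(NIR + R) per raster cell; cells flagged by the cloud
mask, or with NIR + R = 0, become missing rather than raising. Point
extraction uses the cell containing each point under the half-open,
top-left-origin convention (a point on a shared edge belongs to the
left/top cell); points outside the extent yield missing values with a
warning.

**Normalization and ratio.** GVI and NDVI are min-max normalized over the
units of a given spatial scale — each scale's regression is then
self-consistent, since its exposure variable is defined relative to the
variation present at that scale. The GVI:NDVI ratio is the quotient of the
normalized metrics; units where the normalized NDVI is 0 (by construction
the scale's minimum) are missing. Ratios above 1 occur whenever
GVI_norm > NDVI_norm and are retained: clipping would silently distort the
quotient's distribution.

**IQR.** Q3 − Q1 with linear-interpolation sample quantiles (configurable);
effects are reported per IQR so that estimates are comparable across
metrics with different units.

## Spatial weights

A kernel weight matrix with adaptive bandwidths and a triangular kernel:
h_i is the distance from i to its (k+1)-th nearest neighbor, and
w_ij = max(0, 1 − d_ij/h_i), giving exactly k positive weights per row in
generic position. Using the (k+1)-th distance (not the k-th) keeps the k-th
neighbor's weight strictly positive. Rows are standardized to sum to one.
The matrix is left asymmetric: adaptive bandwidths are inherently
asymmetric and row standardization breaks symmetry anyway. Default k = 15,
local neighborhoods of roughly the nearest 750 m of road at 50 m spacing;
the right k is data-dependent and exposed in every config. Duplicate
coordinates are rejected by id, since they would force a zero bandwidth.

## Diagnostics

**Moran's I** uses the standard small-sample moments; the variance defaults
to the randomization assumption (robust to non-Gaussian y; the normality
variant is available). Permutation inference (default 999 relabelings,
seeded) uses the two-sided rule counting permuted |I − E[I]| ≥ observed.
The descriptive ±0.3 strong/weak label sometimes used in applied work is
reported as a string only; inference rests on the p-values.

**LM tests** are the four Anselin score statistics from OLS residuals
(lag, error, and the robust variants), each referred to χ²(1). Degenerate
robust denominators (J ≤ T) return 0 rather than a negative statistic.

**Outlier screening** flags rows with any per-column |z| > 3 or squared
Mahalanobis distance above the χ²(p) 0.975 quantile (both configurable; the
screen's variable set defaults to the pollutant columns). Skewness and
excess kurtosis are reported per variable but never trigger automatic
transformations. Near-singular covariance (condition number > 1e12) is an
error suggesting variable removal.

## SAR estimation

Both models are estimated by maximum likelihood with the spatial
coefficient concentrated out: for each candidate ρ (λ), β and σ² have
closed-form profiles, leaving a bounded scalar maximization over
(−0.999, 0.999) (Brent, xatol 1e−9) — valid because row standardization
bounds the spectrum so (I − ρW) is nonsingular on (−1, 1). The Jacobian
term log|I − ρW| is exact: complex eigenvalues of W, precomputed once and
reused (O(n) per evaluation), or a sparse LU factorization per evaluation.
The default crossover is n = 1500, but any workflow that fits many models
against one W (the 90-fit pipeline) precomputes eigenvalues regardless —
a 2000×2000 eigendecomposition costs a few seconds once, versus hundreds
of LU factorizations per fit for the optimizer plus the Hessian.

Standard errors come from the numerically differentiated Hessian of the
full log-likelihood in (spatial coefficient, β, σ²) at the optimum
(central differences, relative step 1e−5). Covariates are standardized
internally for conditioning and the estimates and covariance are mapped
back to the original scale through the corresponding linear transform, so
users never see the standardized parametrization. Non-convergence or a
non-positive-definite Hessian flags the fit rather than raising; a spatial
coefficient within 1e−4 of the search boundary warns.

**Model choice.** SLM vs SEM by Moran's I of the residuals: the model whose
residual autocorrelation is non-significant (analytic p > α) is chosen; if
both or neither qualify, the smaller |z| wins, with exact ties going to the
SLM (the lag model is the substantive model of interest — its coefficient
feeds the spillover effect). Selection aborts loudly if either fit failed.

**Effects.** The spillover total effect is T_ef = β₁/(1 − ρ), its variance
by the delta method from the joint (ρ, β₁) covariance. Pollutants are
modeled on the natural-log scale, so β₁·IQR is a log-difference and
pct = 100·(exp(β₁·IQR) − 1) is exact, with the CI obtained by applying the
same monotone transform to the Wald interval; the headline uses the direct
coefficient β₁ with T_ef reported alongside (a `use_total` flag swaps
them), and a linear-scale alternative pct = 100·β₁·IQR/ȳ sits behind
`scale="linear"`. The log link is a modeling choice: percentage-difference
reporting presumes multiplicative effects, and the log-scale SAR model is
the internally consistent way to obtain them.

## Synthetic city

The generator's defaults are the package's study conditions.

- **Geometry.** n = 2000 points on a jittered 50 m grid over a
  10 km × 10 km domain. Cells are sampled sparsely, as road midpoints
  sample a real city; the domain is ~5× the largest buffer radius so the
  2000 m scale still measures a local exposure. Jitter is uniform within
  ±spacing/4 per axis, which guarantees a minimum pairwise distance of
  spacing/2.
- **Fields.** Greenspace and covariates are Gaussian-kernel-smoothed white
  noise (length scale field_range/2 = 200 m, truncated at 2·field_range),
  normalized to unit marginal variance — a Gaussian-process stand-in at
  O(n·k) cost that induces the distance-decaying correlation the analysis
  assumes without exact GP sampling. GVI (mean 14.15%, SD 9.94) and NDVI
  (mean 0.12, SD 0.07) share a latent field (correlation 0.7) and are
  clipped to their physical ranges; covariates are positive by
  construction (temperature ~10.6 °C, monthly precipitation ~62 mm,
  log-normal population density and traffic PCU around urban magnitudes).
- **Imagery.** Segmented masks place round(GVI/100 · 6HW) green pixels at
  seeded-random positions, so the pooled fraction reproduces the GVI to
  the pixel quantum 100/(6HW). Band rasters set NIR = (1+v)/2,
  R = (1−v)/2 at each point's 10 m cell (background NDVI 0.1), making
  NDVI extraction an exact round trip; |v| = 1 is clipped to 1 − 1e−6
  with a warning, and two points sharing a cell is an error rather than a
  silent overwrite.
- **Pollution.** log y = (I − ρW)⁻¹(Xβ + ε) via sparse LU solve, with
  X = (1, GVI, standardized covariates), ρ_true = 0.5, σ_ε = 0.3, and a
  default greenspace coefficient β₁ = −0.02 per GVI percentage point
  (≈ −23% per point-scale IQR) — a strong but plausible urban association;
  the per-pollutant intercept centers concentrations near realistic means.
  Concentrations are the exponential of the field, hence log-normal-like
  and right-skewed as drive-by data are.

What the generator does **not** emulate: road-network topology (points are
grid-jittered, not on streets), measurement error in the segmentation or
the reflectances, temporally varying meteorology, plume-like pollution
structure from individual sources, and the many-to-one mismatch between a
dense greenspace point set and sparser pollution segments (both sets
coincide here). Passing tests therefore demonstrate correctness of the
estimators under a known SAR truth with smooth confounding — not that any
particular real-city effect size is recoverable.

## Problem sizes in tests and scripts

Unit tests use cities of 100–400 points; the recovery study uses 20 cities
of n = 900; the calibration studies use 400–500 replicates at n = 100–200;
the full-pipeline check runs 10 complete 90-fit studies at n = 2000. These
sizes give stable Monte-Carlo bands (binomial SE ≈ 1 percentage point for
the calibration rates) while keeping the whole suite in a couple of
minutes on one core.

## Known limitations

- No spatial Durbin/SARAR/GMM estimators and no heteroskedasticity-robust
  standard errors; the SEM total effect is not defined (its β is already
  the total effect).
- The LM tests and Moran moments assume the weight matrix is fixed and
  exogenous; k is not selected from data.
- The concentrated likelihood is assumed unimodal on (−1, 1); the bounded
  scalar search will find a local optimum if it is not (grid-search
  agreement is part of the test suite).
- Min-max normalization makes the ratio metric sensitive to the sample
  extremes at each scale; at coarse buffer scales its exposure contrast is
  largely noise, and effect estimates there are correspondingly unstable.
- The permutation test permutes values, not residuals; for regression
  residual diagnostics only the analytic p is used.
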