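# Methods

`vegcarbon` estimates the vegetation carbon balance of a region from
gridded monthly climate and vegetation data, then dissects where, how fast
and why the balance changes. This note records the models, the defaults
and the reasoning behind the genuinely open design choices.

## Productivity model

Net primary productivity follows the light-use-efficiency decomposition

```
NPP(x, t) = APAR(x, t) · ε(x, t)          [g C m⁻² month⁻¹]
APAR      = SOL · FPAR · 0.5              [MJ m⁻²]
ε         = Tε1 · Tε2 · Wε · ε_max        [g C MJ⁻¹]
```

with `x` a pixel and `t` a month. The factor 0.5 is the photosynthetically
active fraction of incident shortwave radiation. The sub-models are the
canonical CASA forms, with every constant in configuration
(`CasaConfig`), not code:

* **FPAR** is linear in NDVI between per-vegetation-type bounds
  `(NDVI_min, NDVI_max)` and capped at 0.95; at or below the bare-soil
  minimum FPAR is exactly 0, so sparse months contribute zero (never
  negative) productivity.
* **Tε1 = 0.8 + 0.02·T_opt − 0.0005·T_opt²** (clipped to [0, 1]) depends
  only on the pixel's optimum temperature, taken as the temperature of the
  month with maximal NDVI, averaged over years. It peaks at exactly 1 when
  T_opt = 20 °C.
* **Tε2** is the standard double-logistic penalty for months whose
  temperature departs from the optimum, normalised to ≤ 1.
* **Wε = 0.5 + 0.5·(E/Ep)** with the evapotranspiration ratio approximated
  by `clip(R / demand, 0, 1)`, where `demand` is a configurable monthly
  atmospheric moisture demand (default 120 mm). This is a deliberately
  coarse moisture proxy: it floors the scalar at 0.5 in fully dry months
  and saturates once precipitation meets demand. Anything finer (soil
  water budgets, Thornthwaite PET) is out of scope.
* **ε_max** defaults: forest 0.65, shrub/grassland 0.45, cropland
  0.55 g C MJ⁻¹ — subtropical-order values chosen so the default synthetic
  scenario lands in a realistic productivity range (annual NPP of order
  500–800 g C m⁻²).

Estimated productivity is validated by sampling `n` valid pixels without
replacement (seeded) and computing the Pearson correlation, R² and a
two-sided p (t transform, n−2 df) against a reference layer. For synthetic
scenarios no external product exists, so the pipeline writes a clearly
labelled synthetic reference (`npp_reference_synthetic.tif`): a rescaled,
noise-perturbed copy of the estimate.

## Heterotrophic respiration and NEP

Soil heterotrophic respiration uses the empirical monthly form

```
Rh = 0.22 · (exp(0.0913·T) + ln(0.3145·R) + 1) · 30 · 0.465
```

with T in °C and R in mm month⁻¹. The printed constants are applied
literally: the day factor is exactly 30 (not month-length aware) and the
carbon fraction exactly 0.465. The formula is applied **monthly** and
summed to annual Rh; the monthly-vs-annual choice is isolated in
`compute_rh_stack` so the alternative is one function away. Cells with
R ≤ 0 leave the logarithm undefined; they are masked for that month and
counted in a diagnostics record rather than clamped or zeroed.

`NEP = NPP − Rh` per month, summed to annual. A pixel with positive annual
NEP is a carbon sink, negative a source, exactly zero neutral (the strict
inequalities define only sink and source; zero is assigned its own class
to keep maps total). Regional totals multiply NEP by the pixel area from
the transform (10⁶ m² on the default 1 km equal-area grid) and are
reported in Tg C a⁻¹, split by sign; the net total equals the unsplit sum
by construction.

## Trend analysis

Per pixel, the slope of annual NEP over the time index i = 1..n comes from
the closed least-squares summation form; significance from
F = r²(n−2)/(1−r²) on (1, n−2) df. Five classes: extremely significant
increase (p < 0.01, slope > 0), significant increase (0.01 ≤ p < 0.05),
stable (p ≥ 0.05), and the mirrored decrease classes. Boundary p-values
(exactly 0.01 or 0.05) fall to the less-significant class — the class
intervals as printed are open, so the boundaries had to be assigned; this
choice is stated here once and applied everywhere. A constant series gets
slope 0 and p = 1 so maps stay total; series shorter than 3 years are
masked.

## Climate attribution

For each pixel's annual series (NEP, T, P, S) — annual mean temperature,
annual precipitation total, annual radiation total, matching the annual
resolution of the NEP trend — the second-order partial correlation of NEP
with each climate factor (controlling the other two) is computed from the
inverse Ω of the 4×4 correlation matrix, `r = −Ω_yx/√(Ω_yy·Ω_xx)`, with a
t-test on n−4 df. If NEP and a factor coincide up to an affine transform
the matrix is singular and the partial correlation is ±1 by continuity;
any other singularity (collinear inputs, constant series) masks the pixel
with a reason. The joint effect is the multiple correlation R of NEP on
(T, P, S) with intercept, tested by F = (R²/3)/((1−R²)/(n−4)).

The nine driving types are a **reconstruction** — the classification the
underlying criteria produce is cited in the literature but not printed
anywhere we could adopt verbatim. The decision table: a pixel whose
multiple correlation is not significant (p ≥ 0.05) is *non-climatic*;
otherwise the set of individually significant partials (p < 0.05) selects
the single-factor types (exactly one significant), the two-factor types
(exactly two), *strongly driven by T, P, S* (all three) or *weakly driven
by T, P, S* (none individually, yet jointly significant). This is the only
partition consistent with the nine published type names.

## Optimal-parameter GeoDetector

The q-statistic of a stratification is `q = 1 − Σ_h N_h σ_h² / (N σ²)`
with population variances, the share of spatial variance the strata
explain. Significance uses the noncentral-F transformation
`F = (N−L)/(L−1) · q/(1−q)` with noncentrality
`λ = [Σ ȳ_h² − (Σ √N_h ȳ_h)²/N]/σ²`; a seeded permutation test is provided
as an independent cross-check (`significance="permutation"`).

Continuous factors are discretized by five classifiers — equal interval,
quantile, Fisher–Jenks natural breaks, geometric interval, standard
deviation — over stratum counts 3..10 (both config-exposed), and the
(method, L) pair maximising q is kept. Candidates with any stratum smaller
than `min_stratum_size` (default 2) are discarded; ties resolve to the
smaller L, then to the earlier method in the list. The full search table is
retained in the result. Natural breaks uses the exact O(L·n²) dynamic
program; above 2000 samples the break points are computed on a
deterministic order-statistic subsample, the standard practice in GIS
class-interval routines. Native categorical factors (the change-type
layers) skip discretization.

Interaction detection computes q on the cross-classification of two
factors (small cross-strata merged into the nearest stratum by mean
response, merges logged) and classifies: q12 > q1+q2 nonlinear
enhancement; max < q12 ≤ q1+q2 linear (bivariate) enhancement;
|q12 − (q1+q2)| < 10⁻⁶ independence; min ≤ q12 ≤ max linear (univariate)
weakening; q12 < min nonlinear weakening. Note a genuine cross-partition
refines both factors, and the structure-preserving merge keeps that
property, so the weakening regimes cannot arise from this estimator on
shared samples except through aggressive merging; the classification rules
still cover externally supplied q triples.

The risk detector reports per-stratum mean response, the optimal
(maximum-mean) and minimal strata, and Welch t-tests between all stratum
pairs; singleton strata keep their mean but are excluded from testing.

## Synthetic scenarios and ground truth

The generator emulates a subtropical monsoon province on a 1 km equal-area
grid; the default desk scenario is 100×100 pixels × 24 years (seed 0):

| process | default |
|---|---|
| temperature | mean 16.5 °C, seasonal half-amplitude 11 °C, N→S gradient 3 °C, noise sd 1 °C, trend +0.02 °C a⁻¹ |
| precipitation | mean 128 mm month⁻¹, amplitude 60, gradient −25, noise sd 18, floor 0, trend +0.1 mm a⁻¹ |
| solar radiation | mean 385 MJ m⁻² month⁻¹, amplitude 150, gradient −30, noise sd 20 |
| NDVI | baseline 0.62 ± 0.08 smooth field, coupling 0.06/0.05 per anomaly sd of T/R, greening +0.002 a⁻¹, noise sd 0.02, clipped to [−0.2, 1] |
| drivers | elevation/slope/nighttime light/population density as smooth fields; categorical change layers with 3/6/12/4 strata |
| injected effects | impervious-change strata shift NEP by {100, 300, 500} g C m⁻² a⁻¹; all other drivers null; surface noise sd 10 |

NDVI couples to *standardised climate anomalies about the deterministic
seasonal expectation*, so it carries both the spatial climate gradient and
interannual fluctuations — per-month spatial standardisation would cancel
the shared signal that attribution is supposed to detect. Every injected
quantity (trend slopes, stratum effects and means, coupling coefficients)
is recorded in a `TruthRecord`; tests read truth from there, never from
re-derived constants. Randomness derives from one master seed through
named substreams, so adding a layer never perturbs existing ones and
identical scenario+seed is bit-identical.

The time-constant driver-effect surface is added to annual NEP before the
downstream stages: it gives the OPGD stage a recoverable stratified signal
while leaving trends and climate correlations untouched (a per-pixel
constant shifts neither a slope nor a correlation).

What the generator does **not** emulate: sensor artifacts, cloud gaps and
compositing, spatial autocorrelation of noise, lagged climate responses,
land-cover change over time. Passing tests therefore demonstrate
correctness and calibration of the estimators under a known generating
process — not that the CASA parameterisation is accurate for any
particular real region.

## Numerical choices and degenerate inputs

* Grid convention: cell-centre registration, row 0 = north, rectilinear
  transforms only; bilinear resampling for continuous layers, nearest
  neighbour for categorical, and a nodata cell never contaminates a valid
  output cell (zero-weight neighbours are ignored, non-zero-weight nodata
  masks the target).
* GeoTIFF I/O is implemented directly over TIFF tags
  (ModelPixelScale/ModelTiepoint/GeoKeyDirectory/GDAL_NODATA), with band
  labels "YYYY-MM" for temporal stacks; files are readable by standard GIS
  software.
* Constant series: trend → (0, 1); correlation stages mask the pixel with
  a reason; zero total variance makes q undefined (error, not 0).
* Exact-fit guards: r² is clipped to [0, 1]; p = 0 when a relation is
  exact.
* Independence tolerance for interaction typing: 10⁻⁶ on q12 − (q1+q2).
* All reported proportions are over valid (unmasked) pixels and sum to 1.

## Problem sizes

The default desk scenario (100×100 × 24 years) runs the full pipeline in
well under a minute on one CPU; the statistical acceptance checks use
1000–2000 pixels for error-rate calibration, 100 seeded repeats for
recovery rates, and 10⁴ random pairs for formula-oracle agreement. These
sizes were chosen as the smallest at which the tested rates are stable.

## Known limitations

* The light-use-efficiency refinements of the model family this follows
  are published in calibrated forms we do not attempt to reproduce; the
  canonical decomposition with config-exposed constants stands in.
* Rh depends only on monthly T and R — no substrate, soil or land-cover
  dependence.
* q-statistic significance ignores spatial autocorrelation, which inflates
  effective sample size on smooth rasters (visible as non-trivial q for
  null drivers at desk scale).
* The nine-type attribution table and the boundary-p assignments are
  reasonable reconstructions, stated above, not established conventions.
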