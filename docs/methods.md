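# Methods

This note documents the statistical procedures the package implements,
the choices made where the design was genuinely open, the synthetic
data generator's assumptions, and known limitations.

## 1. From hunting bags to growth rates

The growth-rate proxy is λ_t = bag_t / bag_{t−1} per region.  Records
with bag density below `min_density` (default 0.01 animals shot/km²)
are removed **before** λ is formed, so a removed year cancels both the
ratio into it and the ratio out of it; λ is only computed across
consecutive surviving years.  A user-supplied (region, census-year)
exclusion list (e.g. war periods) is applied to the bag rows before the
ratios.  Exclusion order: density filter → listed years → λ formation →
5-year density-proxy completeness → seasonal-climate completeness, each
step appending to a ledger (region, year, rule, detail) so that row
accounting is auditable.

Seasonal temperature means are weighted by days per month (leap
February = 29).  Winter straddles the year boundary and is assigned to
the census year of its January/February; this is configurable only in
the sense that the season table is a plain function that can be
replaced.  Long-term climate is the mean over an inclusive year window,
1973–2002 by default; when the supplied climate does not cover that
window (short synthetic runs) the window falls back to the full
available span.  Missing months invalidate only the seasons that need
them.

Density enters as the mean bag density over the five consecutive years
preceding the census year — a five-year average rather than the single
previous year, to damp regression-to-the-mean artefacts.  Beech mast
enters as the previous-year rank (multiple measurements per region-year
averaged), binary-coded 1 for rank ≥ 3 (pollination ≥ 70 %); trend
analyses use three classes: failure (rank ≤ 1), moderate (1 < rank ≤ 3),
full (rank > 3).

All continuous predictors are standardized to mean 0, SD 0.5 (division
by twice the sample SD, ddof = 1); binary predictors are centred but
not rescaled, which the two-SD convention makes commensurable with the
continuous terms.  A flag allows scaling binaries like continuous terms
instead; the default (centred only) is what the mast main effect's
magnitude is calibrated to.  Transforms are stored so standardized
coefficients can be back-converted (slope_raw = slope_std / 2·SD).

## 2. Linear mixed models

Gaussian models are fitted by **maximum likelihood** (not REML):
AICc-based comparison across fixed-effect structures requires
likelihoods that remain comparable when the fixed part changes.  For
random-intercept structures the likelihood is profiled: with variance
ratios γ_g = τ²_g/σ² fixed, V₀ = I + Σ_g γ_g Z_g Z_gᵀ gives closed-form
GLS fixed effects and residual variance, so only the γ's are optimized
(Nelder–Mead on log γ, tolerance 1e−8, fixed start 0.1 with restarts at
0.001 and 1.0; estimates below 1e−8 are treated as the boundary 0 and
retained).  All quantities are evaluated from cached cross-product
matrices through the Woodbury identity, making one likelihood
evaluation O(q³) in the number of random levels and independent of n —
the property that makes exhaustive model-set fitting affordable (a
40-model set on n ≈ 2100 fits in well under a second; the full 14-term
European vocabulary, 4160 models, in about a minute).

Nesting is expressed by labelling: the inner factor's levels are made
unique within the outer factor (region labels carry their country).
The Austrian model adds the census-year mast category as a third
random-intercept factor (accounting for mast effects on hunting
success); the indicator-block formulation handles this without special
casing.  Parameter count k = fixed effects + variance components +
residual variance, the convention needed for comparable AICc.  Wald
p-values use the normal approximation z = β/SE.  SEs for ordinary
least squares (`fit_lm`) use the unbiased residual variance (n − p)
as conventional regression output does, while its log-likelihood and
AICc remain ML-based.

Binomial random-intercept models maximize the marginal likelihood with
adaptive Gauss–Hermite quadrature: per group, the integrand is centred
at the conditional mode (Newton steps) and scaled by its curvature;
15 nodes by default, 1 node = Laplace.  At the τ → 0 boundary the
numeric Hessian is singular in log τ, so fixed-effect SEs fall back to
the plain-logistic Fisher information.  Suspected separation (exploding
coefficients or optimizer failure) flags the fit non-converged.

## 3. Multi-model averaging

All subsets of the maximal fixed-term set are enumerated under
marginality (an interaction requires both parent main effects; the
intercept-only model is included) with a guard at 20 base terms and a
configurable cap on the subset count.  Weights are Akaike weights on
AICc, computed min-shifted for numerical stability.  Per term:

* RVI = Σ weights of models containing the term;
* natural average = weighted mean over models containing the term,
  weights renormalized within that subset (avoids shrinkage toward
  zero);
* zero method = weighted mean over all models with absent terms
  contributing 0, so estimate_zero = estimate_natural × RVI exactly —
  kept as a regression identity in the tests;
* unconditional SE = Σ w̃_i √(se_i² + (β_i − β̄)²), the revised
  Burnham–Anderson form (the squared-form variant would be an easy
  swap; the revised form is the default in current model-averaging
  practice);
* averaged p = two-sided normal on estimate / unconditional SE.

The conditional rule runs in two passes.  Pass 1 averages over the
full set and classifies each interaction significant or not at α
(default 0.05).  Pass 2 re-averages every main effect involved in
interactions: for a significant interaction, only members where that
interaction is present **and** itself Wald-significant; for a
non-significant one, members lacking it plus members where it is
non-significant.  Multiple interactions sharing a main combine
conjunctively.  Weights are renormalized within each selected subset
(the natural-average convention); an empty subset falls back to the
full-set average with a logged warning.  Interaction terms themselves
and uninvolved mains keep their pass-1 values.  Non-converged members
are dropped from the set with weight renormalization.

## 4. Random-forest screen

A hand-built regression forest: bootstrap samples (with replacement,
size n), recursive binary splitting minimizing within-node response
variance, `mtry` candidate predictors per split (default 4), nodes of
at most `min_node` = 5 rows left unsplit, 2000 trees by default.
Split points are midpoints of sorted distinct values; ties in variance
reduction break by lowest predictor index then lowest threshold, so a
seeded forest is fully deterministic.  The primary importance metric is
OOB permutation importance (mean OOB MSE increase when one predictor's
OOB values are shuffled, averaged over trees); impurity importance
(mean summed variance reduction) is reported secondarily.  The default
screening rule keeps the temperature group when every precipitation
importance ranks below every retained temperature importance; a
keep-top-k rule is available.

## 5. Diagnostics and validation

Empirical semivariograms γ(h) = Σ(z_i − z_j)²/(2|N(h)|) are available
spatially (50 km bins up to half the maximum pairwise distance),
temporally (1-year lags) and jointly.  Purely temporal variograms of
multi-region residuals compare only within-region pairs — cross-region
pairs sit at the sill for every lag and would mask any structure.  The
residuals fed in are the weight-averaged conditional residuals of the
model set.  A Spearman screen over the first lags flags monotone
trends.  Station distances use great circles on a sphere of 6371 km.
Bag validity correlates national bag totals with accident counts
divided by registered vehicles, on levels and on year-to-year ratios;
both correlations are invariant to rescaling accidents or vehicles.
The normality summary (skewness, excess kurtosis, a QQ RMS deviation)
is advisory and never gates the pipeline.

## 6. The synthetic-data generator

The generator emulates the study conditions: 60 regions in 12
countries with bag series 1972–2013 (36 analysed growth rates per
region after the 5-year density burn-in), long-term winter means
spanning −4 to +6 °C; the Austrian preset uses 6 regions with mast
series (100 analysed years per region for the recovery study, 23 for
the real-subset scale of n ≈ 135).  The generating model is

λ_rt = λ₀ + Σ_k β_k x_krt + u_country + u_region + ε_rt,

with λ floored at 0.05, bags updated multiplicatively and rounded
(never below 1), and the predictors standardized exactly as the
pipeline standardizes them.  Monthly temperatures are a regional
climatology (winter level plus a smooth cycle to a summer about 15 °C
warmer) plus one i.i.d. anomaly per region × season-year (SD 1.2 °C),
so seasonal predictors are mutually near-independent; precipitation is
positive gamma noise unrelated to growth.  Mast ranks follow a
proportional-odds scheme whose P(rank ≥ 3) is logistic in year; the
failure class is then exactly logistic with the negated trend slope,
which is what the trend-recovery study checks.  Body mass is linear in
long-term winter temperature with a sex offset; accidents are
proportional to national bag totals times a geometrically growing
vehicle count times log-normal noise.

Three design points deserve explanation:

* **Baseline drift.**  A mean-one multiplicative update declines almost
  surely (E log λ ≈ −Var(λ)/2).  Over a century that drives simulated
  densities under the exclusion threshold and selects the retained rows
  on their own noise history.  The default baseline λ₀ therefore
  compensates the drift so E log λ ≈ 0; `mean_log_growth` adds
  deliberate exponential growth where the emulated scenario calls for
  it (e.g. the accident-validation study, which belongs to the era of
  strongly growing populations).
* **Persistent density heterogeneity.**  Initial regional densities are
  log-normal around `density_init` (SD 1.5 on the log scale, half the
  variation tied to regional winter climate — denser populations in
  milder regions).  Real regional densities span orders of magnitude;
  without this, the density proxy's variance would be almost entirely
  accumulated growth noise.
* **Self-referential standardization.**  The density proxy and the set
  of rows surviving the exclusions both depend on the simulated bags,
  while the coefficients act on the standardized scale.  The generator
  therefore runs three passes with an identical pre-drawn noise stream,
  each time re-standardizing every predictor (and re-centring the
  density proxy) over exactly the rows the pipeline will retain.  The
  remaining generating-vs-recovered scale discrepancy is second order.

One master seed drives named, independently derived substreams
(climate, mast, population, effects, accidents, body mass), so adding a
component never perturbs the others and equal seeds give bit-identical
bundles.

What the generator does **not** emulate: spatial correlation of climate
between regions, age/sex structure, harvest-effort feedback, observation
noise on bags distinct from process noise, and mast synchrony across
regions.  Passing recovery tests therefore demonstrates that the
inference chain is correct under its own assumptions, not that those
assumptions hold for any particular real data set.

## 7. Validation studies and problem sizes

`boargrowth.studies` packages the replicate experiments used by the
test suite and `scripts/acceptance.py`:

* European recovery: 50 bundles at 60 regions × 36 analysed years,
  candidate set = the six generating terms (replicated runs use this
  reduced vocabulary; single demonstration runs can use the full
  14-term set), conditional-average estimates; per-term 2-SE coverage.
* Austrian recovery: 50 bundles at 6 × 100 (and 6 × 23) analysed
  years; sign and significance of the mast × winter interaction.
* Type-I calibration: 200 all-null bundles at 60 regions × 10 years
  (n = 600, keeping the emulated data set's region count — terms with
  between-region character have roughly as many effective degrees of
  freedom as regions); per-term significance rate vs α.  Note the
  averaged z statistic is mildly under-dispersed under the null
  (SD ≈ 0.9), so weak terms test conservatively (~0.03), and a single
  200-replicate binomial measurement of such a rate has non-trivial
  probability of falling below 0.02.
* Forest screen: 20 runs at 30 regions × 20 years, 200 trees
  (the 2000-tree default is exercised once in the test suite's
  stability check).
* Mast trend: 50 replicates at 6 regions × 38 mast years.
* Semivariogram behaviour: 20 simulations of 8 series × 40 years,
  i.i.d. vs AR(1) with φ = 0.7.
* Validation and body mass: single bundles (growing populations for
  the accident comparison; 22 regions, noise-free, for the cline).

## 8. Known limitations

* **Endogenous density proxy.**  Because λ shocks are permanent in a
  multiplicative population and the density proxy is a function of past
  bags, the density coefficient carries a small-sample (Nickell-type)
  attenuation-or-inflation bias that grows with the residual variance
  and with the share of density variance contributed by accumulated
  noise.  The generator defaults (residual SD 0.25, region SD 0.03,
  country SD 0.02, density spread 1.5) keep this bias below about half
  an SE at the European problem size; under stronger noise or purely
  homogeneous initial densities it reaches several SEs.  Any real
  analysis of this design inherits the same caveat.
* The conditional averaging rule is a procedure, not an estimator with
  known sampling theory; its p-values are approximate, and the type-I
  study shows mild anticonservatism (rates up to ~0.07 at α = 0.05).
* The GLMM supports a single random-intercept factor; the LMM supports
  random intercepts only (no random slopes, no REML) — deliberate
  non-goals.
* Semivariogram bin widths (50 km / 1 year) and the variogram trend
  screen are pragmatic defaults; no variogram model is fitted.
* λ is modelled on its natural scale (residual diagnostics on the
  emulated data show no serious non-normality); a log-λ response is a
  one-line change in the model frame but is not the default anywhere.
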