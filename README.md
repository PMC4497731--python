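# boargrowth

Climate, food availability and density effects on wild boar (*Sus
scrofa*) population growth, estimated from regional hunting-bag time
series.

## The problem and who this is for

Hunting bags — the number of animals shot per region and year — are
often the only long-term, large-scale index of wild boar abundance.
This package implements, as a reusable and fully tested pipeline, the
inference chain that links the annual growth rate derived from such
bags to winter severity, long-term regional climate, beech masting and
population density.  It is aimed at quantitative ecologists who want to
run this style of analysis on their own harvest data, or to study the
statistical behaviour of its components (multi-model averaging, nested
random intercepts, harvest-index preprocessing) on synthetic data with
known truth.

## The model

The unit of observation is one region × census year with growth rate

λ<sub>t</sub> = bag<sub>t</sub> / bag<sub>t−1</sub>,

computed after excluding bags below 0.01 animals shot/km² and
non-consecutive years.  The core model is a linear mixed model fitted
by maximum likelihood:

λ = β₀ + Σ<sub>k</sub> β<sub>k</sub> x<sub>k</sub> + u<sub>country</sub> + u<sub>region</sub> + ε,

where the x<sub>k</sub> are day-weighted seasonal temperatures of the
census and prior year, 30-year (1973–2002) long-term regional means,
a 5-year mean prior hunting-bag density, the previous-year beech-mast
code (1 = pollination ≥ 70 %), and selected interactions — all
standardized to mean 0 and SD 0.5 (binary terms centred only), so
coefficients are directly comparable.  Country and region enter as
nested random intercepts.

Inference is by AICc multi-model averaging over **all nested
sub-models** obeying marginality: Akaike weights
w<sub>i</sub> ∝ exp(−Δ<sub>i</sub>AICc/2), relative variable importance
(RVI) = summed weight of models containing a term, natural-average and
zero-method estimates (the identity *zero = natural × RVI* holds
exactly), unconditional SEs by the revised Burnham–Anderson formula,
and a conditional re-averaging rule for main effects involved in
significant interactions.  Around this core sit a random-forest
variable screen (bootstrap regression trees, OOB permutation
importance), binomial random-intercept models for mast-frequency
trends (adaptive Gauss–Hermite quadrature), an averaged linear model
for the body-mass–climate cline, semivariogram residual diagnostics,
and a validity check of bags against vehicle-corrected traffic
accident counts.

Because the original agency data are not redistributable, the package
ships a synthetic-data generator whose defaults emulate the study
conditions (60 regions in 12 countries, ~36 analysed years each;
an Austrian subset of 6 regions with mast series) with generating
coefficients equal to the published significant effects, e.g. winter
temperature +0.180, long-term winter temperature −0.252 and the
mast × winter interaction −0.926 on the standardized scale.

## Worked example

```python
from boargrowth import analyses, studies, synthetic
from boargrowth.model_averaging import format_table

cfg = synthetic.europe_config(seed=2, n_regions=30, n_countries=6, years=(1990, 2013))
climate = synthetic.simulate_climate(cfg)
bags = synthetic.simulate_population(cfg, climate)
result = analyses.run_europe(bags, climate, terms=studies.EUROPE_REDUCED_TERMS,
                             lt_window=cfg.lt_window())
print(format_table(result.report()))
```

prints (n = 538 region-years, 40 candidate models):

```
term                                                     estimate      SE       P   RVI
prior autumn temperature                                    0.231   0.055  <0.001  1.00 *
long-term winter temperature                               -0.352   0.083  <0.001  1.00 *
winter temperature                                          0.193   0.059   0.001  0.99 *
population density                                         -0.025   0.025   0.323  0.35
winter temperature: long-term winter temperature           -0.057   0.053   0.276  0.34
summer temperature                                         -0.009   0.049   0.860  0.27
```

against the generating truth (winter 0.180, long-term winter −0.252,
prior autumn 0.179, density −0.065, summer −0.050, interaction −0.059):
every coefficient lies within two unconditional SEs of truth at this
reduced problem size, and the weak terms are correctly reported as
uncertain (low RVI).  The signs reproduce the headline pattern — milder
winters raise growth, most strongly in regions whose winters are
generally cold.

The `examples/` directory holds one short script per capability
(synthetic bundles, preprocessing, the European and Austrian averages,
the forest screen, mast trends and body mass, validation/diagnostics);
each prints what it computes and what the numbers mean.  A thin CLI
(`boargrowth simulate | preprocess | screen | fit-europe | fit-austria |
mast-trends | bodymass | validate | diagnose`) wraps the same functions
for shell use.

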