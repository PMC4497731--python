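"""The European growth-rate multi-model average on synthetic data.

Fits every admissible nested linear mixed model (nested country/region
random intercepts), weights by AICc, and reports natural-average
estimates with the interaction-conditional selection rule -- the same
procedure used for the real European data set.  Because the data are
synthetic, the printed estimates can be compared with the generating
truth.
"""

from boargrowth import analyses, studies, synthetic
from boargrowth.model_averaging import build_table, format_table

cfg = synthetic.europe_config(seed=2, n_regions=30, n_countries=6, years=(1990, 2013))
climate = synthetic.simulate_climate(cfg)
bags = synthetic.simulate_population(cfg, climate)

result = analyses.run_europe(bags, climate, terms=studies.EUROPE_REDUCED_TERMS,
                             lt_window=cfg.lt_window())

print(f"n = {result.n} region-years, {len(result.model_set.members)} candidate models\n")
print(format_table(result.report()))
print("\ngenerating truth:", dict(cfg.coefficients))
# A positive winter-temperature estimate with a negative long-term
# winter estimate reproduces the region-specific threshold pattern:
# mild winters boost growth most strongly in generally cold regions.
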