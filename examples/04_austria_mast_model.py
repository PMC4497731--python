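"""The Austrian food-availability model: beech mast x winter temperature.

Adds the previous-year mast code (1 = moderate/full mast) and its
interaction with winter temperature, with the census-year mast category
as an extra random factor.  The large negative interaction means mast
years cancel the penalty of cold winters.
"""

from boargrowth import analyses, studies, synthetic
from boargrowth.model_averaging import format_table

cfg = synthetic.austria_config(seed=4, n_census_years=60)
climate = synthetic.simulate_climate(cfg)
mast = synthetic.simulate_mast(cfg)
bags = synthetic.simulate_population(cfg, climate, mast=mast)

result = analyses.run_austria(bags, climate, mast,
                              terms=studies.AUSTRIA_REDUCED_TERMS,
                              lt_window=cfg.lt_window())
print(f"n = {result.n} region-years\n")
print(format_table(result.report()))

bm = result.conditional.estimate("mast_prev")
bi = result.conditional.estimate("mast_prev:winter_t")
print(f"\neffect of a mast year at a cold winter (z = -0.5): {bm + bi * -0.5:+.3f}")
print(f"effect of a mast year at a warm winter (z = +0.5): {bm + bi * +0.5:+.3f}")
# Positive at cold winters, near zero or negative at warm ones: abundant
# beech nuts substitute for the survival benefit of a mild winter.
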