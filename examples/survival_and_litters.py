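"""Known-fate survival and litter-size summaries from simulated demography.

Simulates capture/fate records for 40 bears across a good and a poor food
year (per-interval hazard 0.0002 vs. 0.02), builds 15-interval encounter
histories with staggered entry, fits the 20-model known-fate set, and
prints model-averaged annual survival per gender x age class x food year,
plus the litter summary and Poisson GLM.
"""

from urbanbear import (BearSpec, SimConfig, build_encounter_histories,
                       fit_litter_glm, fit_survival_models, gen_demography,
                       litter_summary)

cfg = SimConfig(seed=6)
bears = [BearSpec(f"B{i:02d}", "M" if i % 2 else "F", 2 + i % 8,
                  [(2008, "good"), (2009, "poor")]) for i in range(40)]
captures, fates, litters = gen_demography(bears, cfg)

histories = build_encounter_histories(captures, fates)
print(f"{len(histories)} bear-year encounter histories")
fits, table = fit_survival_models(histories)
print("\nmodel-averaged annual survival (SE):")
print(table.to_string(index=False, formatters={
    "annual_survival": "{:.3f}".format, "unconditional_se": "{:.3f}".format}))

print("\nlitter summary:", litter_summary(litters))
if len(litters) >= 5:
    coef, means = fit_litter_glm(litters)
    print("\nPoisson litter GLM:")
    print(coef.to_string(index=False))
# Poor-year annual survival drops toward (1 - 0.02)^15 ~ 0.74 while good-year
# survival stays near 1 — the contrast the survival model set is built to rank.
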