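"""All-subsets AICc model selection and averaging on a simulated response.

Simulates ln(home-range area) for 60 bears with a true male-vs-female
contrast of 1.26, fits all 20 candidate mixed models (random intercept per
bear), and prints the top-ranked models and the model-averaged coefficients
with unconditional 95% CIs.
"""

import numpy as np
import pandas as pd

from urbanbear import run_model_selection

rng = np.random.default_rng(4)
rows = []
for i in range(60):
    gender = "M" if i % 2 else "F"
    u = rng.normal(0, 0.5)                       # bear-level random intercept
    for season in ("pre_hyperphagia", "hyperphagia"):
        rows.append(dict(
            bear_id=f"b{i}", gender=gender, age=int(rng.integers(1, 12)),
            season=season, foodyr=rng.choice(["good", "poor"]),
            ln_area=1.47 + 1.26 * (gender == "M") + u + rng.normal(0, 0.8)))
table = pd.DataFrame(rows)

averaged, model_set, fits = run_model_selection(table, "ln_area")
print("top 5 of 20 models by AICc:")
print(model_set.head(5).to_string(index=False,
      formatters={"weight": "{:.3f}".format, "r2": "{:.2f}".format}))
print("\nmodel-averaged coefficients (full-set averaging):")
print(averaged.to_string(index=False))
# The gender term should recover ~1.26 with a CI that excludes zero; terms
# with no generating effect shrink toward zero under full-set averaging.
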