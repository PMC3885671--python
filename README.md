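# urbanbear

Tools for quantifying how strongly black bears (*Ursus americanus*) use a
small urban area, and what drives the variation — built for movement
ecologists and wildlife managers analyzing GPS-collar studies where bears
shift between natural (mast) forage and anthropogenic food depending on how
good the natural food year is.

The package implements the full analysis chain for such a study, plus a
synthetic-data generator that emulates every input stream so each stage is
testable without field data:

* **Telemetry screening** — fixes kept at PDOP ≤ 10 (3D) / ≤ 5 (2D), a 48-h
  post-release exclusion and translocation-absence windows; seasons
  (pre-hyperphagia Apr 16 – Jul 31, hyperphagia Aug 1 – Oct 15) and a
  90%-of-season coverage rule for bear-season eligibility.
* **Home ranges** — fixed-kernel utilization distribution with a full 2×2
  plug-in bandwidth matrix (two-stage, SAMSE pilot); home range = 95%
  superlevel set of the gridded UD; responses `Area` (km²), `HDoverlap`
  (intersection with 50-m-buffered structures, km²) and `HDdensity` (mean
  address density per km² in a 1-km² circular moving window).
* **Diel activity** — seasonal mean head-movement curves (5-min bins) fitted
  with `y = a·sin(bx + c) + d` by bounded multi-start least squares
  (0 ≤ a,d ≤ 255, 0 ≤ b ≤ 5, −π/2 ≤ c ≤ π/2); `b` = activity peaks per 24 h,
  `c` = their timing (c → −π/2 nocturnal, c → π/2 diurnal/crepuscular).
* **Model inference** — all additive subsets of {gender, age, season, food
  year} plus the season×food-year interaction (20 models), random intercept
  per bear, ML fits ranked by AICc, Akaike weights
  `w_m = exp(−Δ_m/2)/Σ exp(−Δ_m/2)`, full-set model-averaged coefficients
  with unconditional SEs `Σ w_m √(var_m + (β_m − β̄)²)` and normal 95% CIs.
* **Demography** — known-fate survival on 15 bi-monthly encounter intervals
  (Apr 16 – Nov 30; denning survival fixed at 1) with staggered entry,
  censoring and re-entry; logit interval survival with the same 20-model
  set; annual survival = Π of the 15 interval survivals, model-averaged;
  Poisson GLM of litter size (1–3 cubs) on sow age and food year; MARK
  known-fate `.inp` writer/reader.

## Worked example

`examples/` holds one short script per capability. For instance
`python examples/diel_activity_fit.py` simulates a bear monitored through a
good and a poor food year and refits the activity model:

```
year food      b       c      a      d  label
2008 good  1.919   1.554   49.7   79.8  crepuscular
2009 poor  1.048  -1.322   50.1   79.7  nocturnal
```

The good year recovers a two-peak dawn/dusk pattern (b ≈ 1.92, c ≈ 1.57)
and the poor year a single nocturnal bout (b ≈ 1.05, c ≈ −1.32).
`python examples/home_range_metrics.py` shows the matching space-use shift:

```
year food n_fixes area_km2 HDoverlap HDdensity
2008 good    1606     8.07     0.000       0.0
2009 poor    1631     8.00     7.074     421.1
```

In the poor year the hyperphagia home range sits on the urban core (mean
address density ≈ 420/km², 7 km² of development overlap); in the good year
it lies in wildland. `examples/survival_and_litters.py` shows the
demographic side: poor-year annual survival drops toward
(1 − 0.02)¹⁵ ≈ 0.74 while good-year survival stays near 1.

The same flow runs end to end from a shell:

```bash
urbanbear run --seed 7 --out my_run       # full report bundle
urbanbear simulate --seed 7 --out data/   # synthetic data streams only
```

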