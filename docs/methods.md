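# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Study structure being modeled

The package targets a multi-year GPS-collar study of black bears around a
small urban center embedded in productive wildland. The central covariate
is a binary **food-year** label (good/poor natural mast production, a
study-wide input, not estimated here). Two seasons are analyzed:
**pre-hyperphagia** (den emergence, Apr 16, to mast fruiting, Jul 31) and
**hyperphagia** (Aug 1 to pre-denning lethargy, Oct 15). The scientific
question is whether urban use — larger overlap with development, higher
address density in the home range, nocturnal activity, altered survival —
tracks the food year and reverses when natural food returns.

## Telemetry screening

3D fixes are retained at PDOP ≤ 10 and 2D fixes at PDOP ≤ 5; fixes in the
48 h after a release, or while a bear is absent after translocation, are
dropped. Every removed row carries a machine-readable reason, and the
report separates PDOP losses from handling exclusions, since a headline
"fraction removed" can mean either. Screening is idempotent and can only
shrink a table.

A bear-season is eligible when the inclusive first-to-last-fix calendar
span covers ≥ 90% of the season. "Spanning" is deliberately the calendar
span, not the fraction of days with data: it matches the plain meaning of
the word and is robust to fix-rate variation. Dates are compared in local
study time; no timezone arithmetic is done. The hyperphagia window starts
Aug 1, the day after the pre-hyperphagia window ends.

## Home ranges

**Bandwidth.** The utilization distribution uses a bivariate Gaussian
kernel with a full, unconstrained 2×2 bandwidth matrix selected by a
two-stage plug-in with the SAMSE pilot:

1. Pre-sphere the fixes by the sample covariance (this makes the selector
   exactly affine-equivariant and lets normal-reference derivatives
   factorize).
2. Take the sixth-order integrated density-derivative functionals ψ_r
   (|r| = 6) at their normal-reference values.
3. Choose the isotropic pilot g minimizing the summed squared asymptotic
   bias of all fourth-order functional estimators (the SAMSE criterion),
   by bounded scalar minimization on log g.
4. Estimate the five ψ_r with |r| = 4 by kernel double sums with pilot
   g²I (O(n²), chunked; ~4 s at n = 5000).
5. Minimize the asymptotic MISE approximation
   PI(H) = n⁻¹(4π)⁻¹|H|^(−1/2) + ¼ vech(H)ᵀ Ψ̂₄ vech(H)
   over symmetric positive-definite H via a log-Cholesky parameterization
   (Nelder–Mead, relative tolerance 10⁻⁶, normal-scale start
   H = n^(−1/3) Σ̂).

On bivariate-normal test data the selected H sits ~3–4% (Frobenius) from
the closed-form normal-scale optimum; tests allow 15%. Degenerate inputs
(collinear, < 10 distinct points) are rejected by name. No autocorrelation
correction is applied (deliberately: the estimator family is the classic
fixed-kernel one), so fix-rate thinning is the user's control for temporal
dependence.

**Surface and isopleth.** The UD is evaluated as the *exact* kernel sum at
every cell center of a square grid (default 400×400, margin 3 kernel SDs),
so the surface equals a brute-force evaluation to machine precision — that
equivalence is a test, not an aspiration. The 95% home range is the
smallest superlevel set of cells whose summed mass reaches the level;
polygons are the union of the included cell squares. This grid-mass
convention makes the enclosed probability exactly auditable (it lies in
[level, level + one-cell mass]) at the cost of slightly blocky polygon
boundaries. A warning fires when cells exceed half the smallest kernel SD.

**Responses.** `Area` is the polygon area. `HDoverlap` intersects the
polygons with the union of 50-m disks around structure points (buffers at
32 quadrant segments, so disk-area error is negligible). `HDdensity`
rasterizes the home range at 50 m and averages, over *all* home-range
cells, the count of addresses within a 564.19-m radius (a circle of area
exactly 1 km²), converted to per-km². Averaging over all cells (not only
cells containing addresses) is the documented choice.

## Diel activity

Counts (0–255 head movements per 5 min) are averaged into 288 time-of-day
bins across the season; empty bins are flagged and excluded, never
imputed. The model y = a·sin(bx + c) + d is fitted by bounded nonlinear
least squares with x = 2π·(minutes since midnight)/1440 — midnight maps
to 0, a convention the package fixes once and applies to both simulation
and fitting. Bounds: a, d ∈ [0, 255], b ∈ [0, 5], c ∈ [−π/2, π/2].

The bounded objective is multimodal in (b, c), so the fit multi-starts
over b₀ ∈ {0.5, 1.0, …, 5.0} × c₀ ∈ {−π/2, 0, π/2} (30 starts) with
a₀ = half the data range and d₀ = the data mean; the lowest SSE wins and
exact ties break toward smaller b, then smaller |c|. A flat curve is
reported as a degenerate fit (a < 10⁻⁶) rather than an arbitrary (b, c).
Note the c bound cannot represent every phase for every b; parameters are
interpreted relative to the midnight anchor and are not re-phased. The
nocturnal/crepuscular labels (|b−1| ≤ 0.25 with c ≤ −π/4; |b−2| ≤ 0.25
with c ≥ π/4) are reporting conveniences, not estimated quantities.

## Mixed models and multimodel inference

Responses: ln Area, ln HDoverlap, ln HDdensity, b, c. Space-use responses
are natural-logged for variance stabilization; zero overlap observations
get ln(x + ε) with ε = half the smallest positive observation (the guard
is applied at modeling time, never inside the metric).

Each candidate model is a linear mixed model with a random intercept per
bear. Fits use **ML, not REML**, because AICc comparisons span different
fixed-effect structures. The fitter profiles the likelihood down to a 1-D
search over the variance ratio λ = σ²_bear/σ²_resid (closed GLS forms per
λ via Woodbury; compound-symmetric V per bear), which is deterministic,
exact at the λ = 0 boundary (where the fit is OLS, flagged), and agrees
with a general-purpose mixed-model optimizer to ~10⁻¹⁰ in log-likelihood
(asserted in tests). AICc counts k = fixed effects + 2 variance
parameters; models with n ≤ k + 1 get infinite penalty. R² is the squared
correlation of fitted (including predicted random intercepts) and
observed values.

Averaging is **full-set** by default: every term is averaged over all 20
models with β = 0 where absent, SE(β̄) = Σ w_m √(var_m + (β_m − β̄)²), and
95% CI = β̄ ± 1.96·SE (no df correction). Natural averaging (renormalized
over models containing the term) is available via `full_set=False`.

## Known-fate survival

The year is cut into 15 bi-monthly intervals (Apr 16–30, then the 1st–15th
and 16th–end of each month through Nov 16–30); the denning period Dec 1 –
Apr 15 contributes survival 1 and no intervals. Exactly where the
bi-monthly cuts fall is underdetermined by "bi-monthly, Apr 16 – Nov 30,
15 intervals"; the 15th/16th split is the package's fixed convention.
Intervals starting on or before Jul 31 are labeled pre-hyperphagia, later
ones hyperphagia (including the post-Oct-15 pre-denning intervals — a
labeling choice the calendar cannot avoid).

Encounter histories support staggered entry (entry at the capture
interval), censoring (collar drop, disappearance, translocation out) and
re-entry (recapture/return). A censored interval contributes nothing to
the likelihood — the standard known-fate convention for mid-interval
censoring. The likelihood is Σ ln S_i over survived at-risk intervals plus
ln(1 − S_i) at the death interval, with S_i = logit⁻¹(x_iᵀβ); it is fitted
by Newton–Raphson with an analytic Hessian. Data with zero deaths are
separable: iteration stops at the S → 1 boundary and the fit is flagged
(its Wald SEs are not meaningful there; the annual estimate is still
reported). Age enters as a class (subadult 1–3, adult ≥ 4), fixed at
entry for the year, matching how survival is conventionally stratified.

Annual survival for a profile is the product of its 15 interval survivals,
with a delta-method SE on the log scale
(∂ ln S_annual/∂β = Σ_i (1 − S_i) x_i); the candidate set mirrors the
space-use set (20 models) and annual estimates are model-averaged with the
same unconditional-SE form. AICc's n is the number of at-risk
bear-intervals (the Bernoulli sample size of the likelihood).

Litter sizes (1–3 cubs) are modeled by a Poisson log-link GLM on sow age
and food year at conception; raw means per food year are reported
alongside because truncated counts this small carry most of their
information in the means.

## Synthetic-data generator

The generator defines the conditions every downstream test runs under.

* **Landscape**: addresses are an inhomogeneous Poisson process with
  Gaussian-decay intensity from the urban core (scale 900 m), thinned from
  a homogeneous process at the ceiling rate 865/km² — so the moving-window
  density never exceeds the ceiling in expectation. Structures are a
  p = 0.8 thinning of addresses. Planar meters on a local grid; no
  geodesy, terrain, or vegetation.
* **Movement**: a discrete-time biased random walk; each 30-min step pulls
  the bear 12% of the way toward the active attractor plus isotropic
  N(0, 300 m) noise. The attractor is the urban core during hyperphagia of
  poor years and the wildland center otherwise. This is plumbing chosen
  for controllable home-range geometry, not a mechanistic movement model;
  its parameters were set once to produce an unambiguous good/poor
  contrast and plausible seasonal range sizes (~5–10 km²).
* **Fix quality**: a two-component pass/fail mixture (11% of fixes drawn
  beyond the PDOP thresholds, 85% of clean fixes 3D), not a physical GPS
  model.
* **Activity**: counts are the food year's sine template (good:
  a = 50, b = 1.92, c = 1.57, d = 80; poor: a = 50, b = 1.05, c = −1.32,
  d = 80) plus Gaussian noise (default SD 12), rounded and clipped to
  0–255. Templates are validated against the fit bounds and the sensor
  range at configuration time.
* **Demography**: staggered entry uniform over intervals 1–15, geometric
  time-to-death under a per-interval hazard (defaults 0.0002 good / 0.02
  poor, i.e., annual ~1.0 vs. ~0.74), independent per-interval censoring
  (0.01), and litters drawn from a Poisson truncated to {1, 2, 3} with
  mean 2.4 (good) / 2.0 (poor) at conception.
* **Randomness**: one study seed keys everything through SeedSequence
  spawning (generator label → CRC32 spawn key → one child stream per
  bear-year), so outputs are bit-identical under a fixed seed and any
  sub-stream is reproducible in isolation.

What the generator does *not* emulate — and hence what green tests do not
demonstrate about field data: temporal autocorrelation structure beyond
the random walk, habitat selection, collar fix-failure geometry (fix loss
is independent of position), observation gaps, multi-bear interaction,
cause-specific mortality, and age effects on movement or activity.
Parameter-recovery results on this generator show the estimators are
correct under their assumptions, not that field data meet them.

## Problem sizes and runtime

Test and acceptance runs scale the simulations to desk size as a package
choice: bandwidth oracle checks at n = 5000, pipeline-contrast replicates
with 2-h fixes and 80×80 grids (20 seeded replicates), model-averaging
coverage at 25 replicates × 40 bears, noise-monotonicity at 8 replicates ×
3 noise levels. The full suite runs in a few minutes on one CPU; the
acceptance script in well under a minute.
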