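# Methods

## Model

A vertebra's degradation state is the osteophyte ratio index (ORI), a
dimensionless ratio of anterior osteophyte length to vertebral body width.
The model has two independent stages:

1. **Formation.** The age τ (years) at which an osteophyte first appears is
   Weibull(a, b): scale a > 0 in years, shape b > 0 dimensionless. The
   Weibull is the standard flexible law for ages at onset of degenerative
   disease; its mean is a·Γ(1+1/b).
2. **Growth.** Conditional on τ, the ORI is a drifted Wiener process
   started at (τ, 0): X(t|τ) ~ N(μ(t−τ), σ²(t−τ)), μ > 0 in ORI/year,
   σ > 0 in ORI/√year. Increments over disjoint intervals are independent,
   so aperiodic visit schedules pose no difficulty, and sample paths may
   transiently decrease (remeasurement of an irregular contour can shrink
   the recorded length); the process is not reflected at 0.

Pain onset is the first passage of X through a threshold c ∈ (0, 1] (the
maximum clinically acceptable ORI). For a drifted Brownian motion the
elapsed first-passage time is inverse-Gaussian, (T−τ) ~ IG(c/μ, c²/σ²),
with survival

    H(c|t,τ) = Φ((c−μs)/(σ√s)) − exp(2μc/σ²)·Φ(−(c+μs)/(σ√s)),  s = t−τ.

All population-level quantities marginalise τ by quadrature: the ORI
density h(x|t), the onset-age density g(t|c), the pain-free survival
R(t|c) = ∫₀ᵗ H f dτ + (1−F(t)), and the closed-form mean onset age
MTTOOP = c/μ + a·Γ(1+1/b).

Two readings of the conditional survival H exist because the defining
equation leaves it implicit: the IG first-passage survival used here, and
the naive state probability P(X(t|τ) ≤ c). Only the first-passage reading
makes the survival function and the onset-age density describe the same
event (R = 1 − ∫g holds exactly under it); the naive variant is available
behind the `naive_state` flag of `survival_function` for comparison and is
always ≥ the first-passage value.

Vertebrae are pooled as statistically independent, including multiple
vertebrae from the same patient — the likelihoods factorise over vertebrae.
This is a modelling assumption, not a verified property of spinal anatomy.

## Estimation

* **Formation ages.** The exact formation age is never observed (radiographs
  are discrete events). For each vertebra with ≥ 2 positive-ORI visits, the
  straight line through the first and last positive observations is
  extended to ORI = 0; the crossing is the backcast formation age τ̂.
  Zero-ORI visits are excluded from the line (they carry no length
  information). Guard rails: a crossing after the first positive visit is
  impossible (slope > 0 and a positive intercept guarantee this); a
  crossing earlier than half the first-positive age triggers a warning (the
  two-point line is extrapolating far outside the data); a crossing at or
  before age 0 is physically impossible — `interpolate_formation_time`
  clamps it to a small epsilon with a warning, while the cohort-level
  assembly (`formation_data_from_cohort`) excludes such series from the
  event set entirely, with a logged count. The exclusion matters: in
  lumbar-like simulations ~2% of series produce non-positive crossings, and
  feeding epsilon ages into the Weibull MLE collapses the fitted shape.
* **Weibull MLE.** Right-censored log-likelihood (osteophyte-free vertebrae
  contribute −(τ_k/a)^b at their last-visit age), maximised by BFGS in
  (log a, log b) with the analytic gradient, gradient tolerance 1e-8,
  started from Gumbel moment-matching on log event ages. Standard errors
  come from the central-difference observed-information matrix; they are
  reported but nothing downstream consumes them. With the shape fixed
  (`fix_shape`), the scale has the closed form (Στ^b/N)^(1/b) — at b = 1
  this is the exponential total-time-on-test estimator.
* **Wiener MLE.** Closed forms μ̂ = ΣΔx/ΣΔt and
  σ̂² = (1/n)Σ(Δx−μ̂Δt)²/Δt over post-formation increments. By default the
  first increment of each series is anchored at (τ̂, 0) — the backcast
  formation age is treated as an exact zero-ORI epoch, preserving the
  strongest drift information; `anchor_at_formation=False` disables this
  for sensitivity analysis. Negative increments are retained (the model
  permits them; flooring would bias σ̂ downward). σ̂ is the biased
  (divide-by-n) maximiser; an unbiased variant sits behind a flag.
* **Censor-time split.** `extract_increments` can hold out observations
  more than a fixed elapsed time after τ̂ (defaults in the CLI: 4 years
  cervical, 6 lumbar) as a validation set for band-coverage checks.
  Caveat found in simulation: with a split, the retained increments are
  dominated by each series' anchor segment, whose endpoints are selected
  (first *positive* observation) rather than randomly sampled; at n = 300
  lumbar-like this biases μ̂ up ~15% and σ̂ down ~20%. Parameter-recovery
  and end-to-end validation runs therefore fit growth on all
  post-formation data; the split remains available for the held-out
  band-coverage workflow it was designed for.

## Synthetic cohorts

The generator reproduces exactly the structure the estimators assume:
Weibull formation ages; Wiener growth sampled at aperiodic visits (gaps
uniform in 0.5–2.0 years by default) inside an observation window (default
ages 35–80); at least three visits per vertebra; vertebrae forming after
their last visit appear as all-zero (right-censored) series. Default
parameter sets mirror the published cohorts: cervical-like
(n=29, a=52.5216, b=5.7469, μ=0.0145553, σ=0.0113259) and lumbar-like
(n=103, a=54.9779, b=2.3443, μ=0.012836, σ=0.024040). The window start of
35 years sits just below the youngest observed first-visit ages of those
cohorts; the end of 80 years covers the oldest.

What it does **not** emulate: reader/measurement error beyond an optional
additive Gaussian noise term (default 0, kept separate from σ so the two
sources remain distinguishable); visibility limits of small osteophytes (a
path value of 1e-4 counts as an observed osteophyte, which real imaging
would miss); multi-stage growth, disc-height or other covariates; and
correlation between vertebrae of one patient. Passing tests therefore
demonstrate internal consistency of model + estimators under the model's
own assumptions, not robustness to these real-data features.

Clamping of negative path values at 0 (`clamp_negative`) is **off** by
default so that recorded values are exactly the process the growth
likelihood models; the unreflected path keeps MLE checks exact. Container
validation allows the resulting small negatives only for
simulator-constructed series; cohort files read from disk must be
nonnegative.

## Validation against Kaplan–Meier

Observed onset ages are read off each series as the age of the first visit
with ORI ≥ c (a linear-interpolated crossing variant exists behind
`interpolate_crossing`); series never reaching c are right-censored at
their last visit. The Kaplan–Meier estimate and its 95% band come from
lifelines (the band is the exponential-Greenwood log(−log) construction,
automatically within [0, 1] and containing the point estimate).

Two systematic artifacts of this comparison were identified in simulation
and are handled by `validate_against_km`:

* **Left truncation.** A vertebra already at/above c at its first visit
  crossed at an unknown earlier age; recording it as an event at study
  entry piles spurious onsets at the window start (~14% of lumbar-like
  vertebrae with a window starting at 35). The standard treatment is
  applied by default: prevalent cases are excluded, remaining series enter
  the KM risk sets at their first-visit age (delayed entry), and the model
  curve is conditioned on pain-free survival to the earliest entry age t0,
  i.e. R(t|c)/R(t0|c) — the quantity a left-truncated KM estimates.
* **Detection delay.** A visit grid with mean gap ~1.1 years detects the
  crossing late: excursions above c between visits are missed (effective
  barrier shift ≈ 0.583σ√Δ̄) and the recorded age snaps to the next visit,
  together ≈ 1.7 years for lumbar parameters. This shifts the KM up by up
  to ~0.03 in survival; it is inherent to comparing a continuous-passage
  model with discretely monitored data and is left uncorrected (the model
  curve is not adjusted to the visit process).

Overlay metrics (sup-distance, band-containment fraction) are evaluated at
the KM *step* times — ages where the estimate actually drops — not at every
timeline entry the fitter tabulates. The empirical mean onset age is the
mean of event ages conditional on the event being observed; censored
vertebrae are not imputed. The percentage difference convention is
|model − empirical|/empirical × 100.

## Agreement statistics

Observer agreement for paired ORI measurement vectors uses the intraclass
correlation coefficient in the two-way random-effects, absolute-agreement,
single-measurement form (ICC(2,1), computed by pingouin, F-based 95% CI) —
the standard choice for test–retest and inter-rater reliability of a
continuous measurement; the consistency form ICC(3,1) sits behind a flag.
Qualitative bands: ≤0.50 poor, ≤0.75 moderate, ≤0.90 good, else excellent.
The percentage difference is |a−b|/|a|·100 per item (first vector =
baseline), averaged across items; zero-baseline items are excluded with a
logged count.

## Numerical choices

* Quadrature: adaptive Gauss–Kronrod (scipy `quad`), absolute tolerance
  1e-8, relative 1e-6. The h(x|t) integrand's 1/√(t−τ) endpoint behaviour
  as τ → t is removed by the substitution u = √(t−τ) before integration.
* H is evaluated in log space (log Φ + exponent) so the exp(2μc/σ²)
  prefactor cannot overflow for small σ.
* Improper time integrals (onset-density normalisation, MTTOOP-as-
  ∫R identity) truncate at the Weibull (1−1e-10) quantile plus the IG mean
  plus 12 IG standard deviations; the discarded tail is far below the 1e-4
  check tolerances.
* Survival curves tabulated on a grid absorb quadrature jitter by a
  running minimum before the monotonicity invariant is enforced.
* Decision-support epochs (ages at which remaining-onset survival crosses
  clinician cut-points) are found by Brent root-finding to 1e-4 years on a
  default 10-year horizon; unreached cut-points report +inf.
* Patient-level conditioning treats the measured current ORI x₀ as the
  exact process state; by stationary independent increments the remaining
  passage time is IG((c−x₀)/μ, (c−x₀)²/σ²) with mean (c−x₀)/μ.

## Problem sizes

Simulation-backed checks use cohorts of 300–500 vertebrae (20 seeds for
parameter recovery, 3 for the KM overlay), 10⁴ generative draws for the
mean-onset check, and 10⁶ draws for the Monte-Carlo oracles (the
first-passage oracle uses a Brownian-bridge-corrected Euler scheme, step
0.25 years, whose per-step crossing probability
exp(−2(c−x₀)(c−x₁)/(σ²Δt)) makes discrete monitoring exact for the
barrier). These sizes give Monte-Carlo standard errors comfortably below
the tolerances asserted.

## Known limitations

* The two-point backcast of formation ages is noisy (error SD ≈ 6 years in
  lumbar-like simulations) and mildly selection-biased; an
  interval-censored likelihood would be cleaner but is deliberately not
  implemented — the backcast is the procedure the model pipeline defines.
* Single-stage growth with population-level (μ, σ); no per-patient drift
  heterogeneity or covariates.
* The KM comparison inherits the detection-delay artifact described above.
* Formation and growth parameters are estimated from separate likelihood
  factors; joint estimation (propagating τ̂ uncertainty into the growth
  fit) is not attempted.
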