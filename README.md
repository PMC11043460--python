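# osteotrack

Stochastic modelling of anterior vertebral osteophyte formation and growth
from longitudinal radiographic follow-up, with survival metrics for the age
at pain onset and a patient-level decision-support workflow.

## The problem and the model

Anterior osteophytes — bony outgrowths at the edges of cervical and lumbar
vertebral bodies — grow slowly over decades and cause neck/back pain once
they mechanically compress surrounding structures. Radiographic follow-up
yields sparse, aperiodic measurements of the **osteophyte ratio index**
(ORI = osteophyte length / vertebral body width on the same lateral view, a
dimensionless, scale-plate-independent quantity). `osteotrack` implements a
two-stage stochastic degradation model of this process:

* the **formation age** τ of an osteophyte on a vertebra is
  Weibull-distributed, τ ~ Weibull(a, b), with density f and CDF F;
* after formation the ORI follows a **Wiener process** with drift μ
  (ORI/year) and diffusion σ (ORI/√year):
  X(t | τ) ~ N(μ(t−τ), σ²(t−τ));
* **pain onset** is the first passage of X through a clinical threshold c
  (the maximum acceptable ORI, e.g. 10 mm over the mean anteroposterior
  vertebral diameter: c = 0.52 cervical, 0.22 lumbar); conditional on τ,
  the elapsed passage time is inverse-Gaussian,
  (T − τ) ~ IG(c/μ, c²/σ²).

Marginalising τ by quadrature gives the population quantities

* ORI density `h(x|t) = ∫₀ᵗ f(τ) N(x; μs, σ²s) dτ` (s = t−τ),
* onset-age density `g(t|c) = ∫₀ᵗ f(τ) ig(t−τ) dτ`,
* pain-free survival `R(t|c) = ∫₀ᵗ H(c|t,τ) f(τ) dτ + (1 − F(t))`
  with H the IG first-passage survival,
* mean time to onset of pain `MTTOOP = c/μ + a·Γ(1 + 1/b)`.

Estimation from censored, aperiodic follow-up tables: each vertebra's
formation age is backcast by the two-point line through its first and last
positive-ORI observations; the Weibull law is fitted by right-censored MLE
(osteophyte-free vertebrae enter at their last-visit age); the Wiener
drift/diffusion are the closed-form maximisers
μ̂ = ΣΔx/ΣΔt, σ̂² = (1/n)Σ(Δx−μ̂Δt)²/Δt of the aperiodic increment
likelihood. Validation overlays the model survival curve on the
Kaplan–Meier curve of observed onset ages (left-truncation-aware; see
`docs/methods.md`).

## Worked example

```python
import osteotrack as ot

# 1. simulate a lumbar-like cohort and refit it
design = ot.SimulationDesign(n_vertebrae=300, params=ot.LUMBAR_PARAMS,
                             study_start_age=35, study_end_age=80, seed=0)
cohort, truth = ot.simulate_cohort(design)
fit = ot.fit_cohort(cohort)
print(fit.formation.a_, fit.formation.b_, fit.growth.mu_, fit.growth.sigma_)
# 57.482  2.307  0.01276  0.02305   (truth: 54.978, 2.344, 0.012836, 0.024040)

# 2. population survival metrics at the lumbar threshold
thr = ot.PainThreshold(0.15)
print(round(ot.mttoop(thr, ot.LUMBAR_PARAMS), 2))   # 60.4 years
print(round(ot.survival_function(60.0, thr, ot.LUMBAR_PARAMS), 3))  # 0.479

# 3. patient-level plan: ORI 0.15 now, lumbar threshold 0.22
state = ot.PatientState(0.15, 55.0, ot.PainThreshold(0.22),
                        ot.LUMBAR_PARAMS.wiener)
print(round(ot.remaining_ttoop_distribution(state).mean, 2))  # 5.45 years
print(ot.survival_epochs(state, (0.8, 0.5)))
# {0.8: 2.28, 0.5: 4.16} -> years until survival drops to 80% / 50%
```

The fitted numbers say the cohort's formation ages are consistent with a
Weibull law centred near 49 years, ORI grows ~0.013/year, and half of
lumbar vertebrae would reach the validation threshold 0.15 by about age 60;
the patient with margin 0.07 to threshold has ~5.5 pain-free years in
expectation.

The same stages are exposed as a CLI:
`osteotrack simulate|fit-formation|fit-growth|predict|validate|agreement|plan`.

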