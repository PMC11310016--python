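# Methods

This note documents the statistical models, the numerical choices, and the
limits of what the test suite demonstrates.  Time is measured in months
throughout; hazards are events per patient-month.

## Synthetic trial programs

The generator emulates the evidence base the pipeline is built for:
two-arm randomized trials with a latent PD-L1 subgroup.

* **Event model.** Piecewise-constant hazards per (arm × subgroup) cell,
  sampled by inverse-CDF on the piecewise-linear cumulative hazard.  A
  delayed treatment effect replaces the experimental hazard with the
  control hazard before the onset time, reproducing the late curve
  separation characteristic of checkpoint blockade.
* **Between-trial heterogeneity.** One mean-1 gamma multiplier with
  variance θ per trial, shared by both arms — the same family the
  shared-frailty analysis model assumes, so parameter recovery is a fair
  test of the estimator, not of a modeling mismatch.
* **Censoring.** Uniform accrual over `accrual_months`; administrative
  censoring at `admin_censor_month` after trial start (per-patient censor =
  horizon − entry), plus an independent exponential dropout hazard.  This
  produces the right-tail sparsity of real KM figures.
* **Defaults** (one mid-size first-line trial): 300 patients/arm, 40%
  PD-L1 < 1% (the bundled 49-trial registry averages 39.6%), control
  median 12 months, 18 months accrual, 36-month horizon, dropout
  0.002/month.  Simulation studies in the tests use control medians of
  12–14 months and HRs between 0.5 and 1.2, the range spanned by the
  registry's literature.
* **Rendering.** The digitized-figure renderer samples the exact KM step
  function at every drop time plus a regular grid, optionally perturbs
  survival values with truncated Gaussian noise of sd `jitter_sd`, and
  re-projects to a monotone non-increasing curve (pool-adjacent-violators).
  Risk tables hold exact counts still at risk at multiples of the risk
  interval.  What the renderer does **not** emulate: pixel quantization,
  axis-calibration error, plotting artifacts at curve crossings, and
  reader disagreement — so passing tests show algorithmic correctness
  under controllable noise, not robustness to every real digitization
  pathology.

## KM reconstruction

Within each interval between consecutive published at-risk times, the
decoder walks the curve coordinates, assigning `d_k = n_k (1 − S_k /
S_{k−1})` events to each drop; interval censoring is spread uniformly over
the interval (placed after the drop at the interval's start when one
exists) and the censor total is iterated with the event solution until the
count at the next published time matches (fixed-point cap: 25 iterations,
after which the closest match is accepted and the deviation recorded in the
diagnostics).  Event counts are real-valued during solving and rounded by
largest remainder within the interval, so interval totals are integers and
events + censorings always equal the initial count.  After the last
published time, events continue to follow the drops and the remaining
patients are censored at the last coordinate; a published total event count,
when available, rescales the assignment in a final pass.  With noiseless
input and at-risk entries at least as dense as the coordinates, the decoded
KM curve reproduces every input coordinate to 10⁻⁶ (tested); with quarterly
risk tables the residual error is bounded by integer rounding, about half a
patient per drop.

## Subgroup subtraction

Matching is per randomized arm, never across arms.  The cost of pairing a
known-subgroup patient with an overall-population patient is
`|Δ time| + penalty · [event status differs]`, with the penalty defaulting
to 10× the maximum observed follow-up: cross-status matches are a last
resort rather than forbidden, so degenerate status counts still solve.
The assignment is solved exactly (rectangular Hungarian algorithm); ties
break deterministically via a stable pre-sort on time.  Optimality is
verified against brute-force enumeration on small instances.  The
Monte-Carlo error-limit routine repeats simulate → render → reconstruct →
subtract with fresh seeds from an explicit trial template and reports the
mean absolute log-HR deviation and its 2.5/97.5 percentile interval;
subtraction uncertainty is reported this way and deliberately not
propagated into downstream confidence intervals.

## One-stage pooled analysis

* **Marginal Cox.** `lifelines` partial-likelihood fit, Efron tie
  handling (reconstruction places events on grid times, so ties are heavy),
  sandwich standard errors clustered on trial whenever more than one trial
  is present.
* **Gamma shared frailty.** Authored here because no installed Python
  package provides it.  Inner loop: EM — the E-step sets each trial's
  frailty to its posterior mean `(1/θ + D_i)/(1/θ + Λ_i)` given the Breslow
  cumulative hazard, the M-step refits a Newton partial-likelihood solver
  (Efron ties, log-frailty offsets).  Outer loop: bounded scalar
  maximization of the profile marginal likelihood over log θ
  (θ ∈ [10⁻⁴, 5]; an optimum at the lower bound is reported as θ̂ = 0).
  Reported standard errors condition on the estimated frailties (the usual
  penalized-likelihood convention, slightly anti-conservative for small
  trial counts).  The treatment coefficient and its SE agree with
  R `survival::coxph(.. + frailty.gamma(trial))` to four decimals in the
  oracle test; θ estimates differ between criteria (that routine solves a
  moment-style equation rather than maximizing the marginal likelihood), so
  θ recovery is tested against simulation truth instead.
* **Covariate coding.** Trial-level factors (cancer type, drug class,
  control treatment) are dummy-coded with the most frequent category as
  reference (alphabetical tie-break); the coding is recorded in
  `HRResult.adjusted_for`.
* **Subgroup differences.** Cochran's Q on per-level log-HRs with
  inverse-variance weights, χ² with (levels − 1) df — the standard
  forest-plot interaction test, chosen because the source literature
  reports "p for subgroup difference" without naming one.  Levels with no
  events are reported as inestimable and excluded from Q.

## Bayesian time-varying hazard ratio

Follow-up is truncated at 60 months and split at 3-month boundaries into
counting-process rows, aggregated to (trial, arm, segment) cells with event
counts and exposure, giving the Poisson-equivalent likelihood
`Σ d_c η_c − E_c e^{η_c}` with
`η_c = b_s + treat·β_s + x'γ + σ z_trial` (non-centered random intercept).
Priors are explicit, weakly informative stand-ins: Normal(0, 2.5²) on β_s
and γ, Normal(0, 5²) on b_s, half-Normal(0, 1) on σ.  Segments with zero
exposure are flagged and left prior-dominated.

The sampler is blocked Metropolis-within-Gibbs guided by a Laplace
approximation at the posterior mode: one (b_s, β_s) block per segment, one
block per trial intercept, one for log σ, plus a dedicated move along the
soft ridge that trades a common baseline shift against the intercepts
(that direction is only weakly identified with few trials).  Block proposal
covariances come from the conditional precision of the Laplace Hessian;
per-block scales adapt toward 35% acceptance during warm-up only, so the
retained chains are a valid Markov chain.  A global independence proposal
was tried first and rejected: low-event segments have visibly skewed
log-rate posteriors, and in ~50 dimensions the resulting mismatch collapses
acceptance.  Defaults: 4 chains × 1,000 retained draws after 500 warm-up
sweeps (2 sweeps per retained draw), split-chain R̂ per parameter via
`arviz`, pass iff max R̂ < 1.1.

The average HR is the per-draw weighted geometric mean of segment HRs;
weights default to observed events per segment (segments nobody reaches
contribute nothing) with an equal-weight option, and the choice is recorded
in the output.

## RMST, grading, predictive value

RMST is the exact rectangle sum under the KM step function; its variance is
the standard KM-integral estimator `Σ A_i² d_i / (n_i (n_i − d_i))` with
`A_i` the area from `t_i` to τ, and differences use a normal-approximation
CI.  Truncation defaults to 24 months (OS) / 12 months (PFS), shortened to
the smaller arm-wise maximum observed time.  The benefit grade applies the
simplified scale exactly as stated: control median ≤ 12 → ≥ 2-month gain;
(12, 24] → ≥ 3-month gain; medians not reached → ≥ 10 **absolute**
percentage points in 2-year OS; always requiring the HR's upper 95% limit
below 1.  Meaningful outcomes carry the single label "grade 3
(meaningful)" — the printed scale cannot distinguish grades 3 and 4, and no
grade-4 rule is invented.  A control median above 24 months with medians
reached is outside the stated bands and returns "rule undefined" rather
than an extrapolation.  The scale is defined for OS; grading PFS requires
an explicit override flag.  The predictive value is `ln(HR_low / HR_high)`,
antisymmetric by construction.

## Aggregate meta-analysis

DerSimonian–Laird was chosen as the heterogeneity estimator (the field
default for this literature; alternatives like REML are out of scope).
SEs derive from CIs as `(ln U − ln L)/(2·1.96)`.  IPD-derived effects enter
the two-stage pooling as per-trial marginal Cox HRs.  Egger's test is the
weighted regression of standardized effect on precision; with all studies
identical the regression is degenerate and the intercept is reported as 0
with p = 1.  The IPD-representativeness check compares the pooled IPD-subset
HR against the pooled all-trial HR with a between-group Q test; the subsets
overlap, which makes the test conservative — adequate for its screening
role.  Significance is two-tailed at 0.05.

## Pipeline and reproducibility

One global seed derives per-stage substreams keyed by stage name (CRC-32 of
the name into a `SeedSequence`), so rerunning a single stage never perturbs
another stage's randomness.  Every artifact records the seed and a config
hash in `manifest.json`; identical config + seed reproduce all outputs
bit-identically, including MCMC summaries.

## Problem sizes used in validation

The test suite and acceptance script run at desk scale, chosen to make
every stochastic check decisively pass or fail within minutes: 20 trials ×
300/arm for reconstruction fidelity, 20 trials × 300/arm (θ = 0.25) for
frailty recovery, 10 trials × 200/arm for the TVHR convergence check, and
Monte-Carlo error limits at 20–100 iterations.  The published workflow this
package operationalizes used 1,000 Monte-Carlo iterations for error limits;
`estimate_error_limits` defaults to 1,000 and the tests dial it down purely
for turnaround.

## Known limitations

* Reconstruction assumes non-informative censoring and no cure fraction;
  no competing risks anywhere in the package.
* No patient-level covariates (age, sex) — they are not recoverable from
  published curves; adjustment is trial-level only.
* Frailty SEs condition on θ̂; CIs do not propagate θ uncertainty.
* The TVHR sampler's Laplace preconditioning assumes a log-concave-ish
  posterior; with pathological data (e.g., a segment with one event in one
  trial) mixing may degrade — R̂ is always reported and failure is flagged,
  never silently accepted.
* Subtraction error limits describe the workflow's noise under the stated
  template, not the uncertainty of any single derived subgroup.
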