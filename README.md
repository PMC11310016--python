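# icimeta

One-stage individual-patient-data (IPD) meta-analysis of randomized
immune-checkpoint-inhibitor trials, focused on the question the published
figures usually leave unanswered: **do patients whose tumors express no
PD-L1 (PD-L1 < 1%) benefit from first-line PD-1/PD-L1 blockade?**

Most phase-3 trials report Kaplan–Meier curves for the intention-to-treat
and PD-L1-positive populations only.  `icimeta` provides every stage needed
to answer the subgroup question from published material alone, plus a
synthetic trial-program generator with known ground truth so the whole
chain can be validated end to end:

1. **Reconstruction** — decode per-patient times and event flags from
   digitized KM coordinates and number-at-risk tables (Guyot-type
   inversion: within each at-risk interval, events follow the curve's drops
   and interval censoring is iterated until the published at-risk count is
   matched exactly).
2. **Subtraction** — derive the unreported PD-L1 < 1% subgroup by removing
   the published PD-L1 ≥ 1% subgroup from the overall population via
   minimal-cost bipartite matching on follow-up time and event status, with
   Monte-Carlo limits of error.
3. **One-stage pooling** — log-rank test, marginal Cox with cluster-robust
   (sandwich) errors, and a gamma shared-frailty Cox model
   `h_ij(t) = w_i · h_0(t) · exp(x_ij'β)` with `w_i ~ Gamma(1/θ, θ)` shared
   within trial *i*, fitted by EM with profile marginal likelihood for θ.
4. **Time-varying hazard ratio** — Bayesian hierarchical piecewise-
   exponential model: hazards constant on 3-month segments up to 60 months,
   each segment with its own baseline log-hazard and treatment log-HR
   `β_s`, trial random intercepts, MCMC with split-chain R̂ diagnostics and
   an event-weighted average HR.
5. **RMST** — restricted mean survival time differences
   `∫₀^τ [S₁(t) − S₀(t)] dt` (τ = 24 months for OS, 12 for PFS, shortened
   to the common follow-up), including a scan for the earliest τ with a
   significant absolute benefit.
6. **Benefit grading & predictive value** — a simplified ESMO-MCBS-style
   rule (grade 3 = meaningful) and the predictive value of PD-L1,
   `ln(HR_{<1%} / HR_{≥1%})`.
7. **Aggregate meta-analysis** — DerSimonian–Laird random-effects pooling
   of per-trial HRs, Egger's asymmetry test, and an IPD-representativeness
   comparison.

The package bundles a 49-trial registry (trial id, cancer type, regimen,
drug class, assay clone, scoring method, and PD-L1 < 1% counts) covering
37,036 randomized patients across 13 cancer types.

## Worked example

Recover a subgroup that was never published (`examples/subtract_unreported_subgroup.py`):

```python
import numpy as np, pandas as pd
from icimeta import (HazardSpec, TrialSimSpec, cox_marginal, reconstruct_ipd,
                     render_km, simulate_trial, subtract_subgroup)

spec = TrialSimSpec(n_per_arm=600, subgroup_fraction=0.4,
                    hazard=HazardSpec.exponential(np.log(2)/12, hr_lt1=0.7, hr_ge1=1.0))
ipd = simulate_trial(spec, seed=7)            # ground truth, hidden from the pipeline

rec_overall, rec_known = [], []
for arm in ("experimental", "control"):
    cell = ipd[ipd["arm"] == arm]
    c, r = render_km(cell.assign(subgroup="overall"), risk_interval=3.0)
    rec_overall.append(reconstruct_ipd(c, r).observations)
    c, r = render_km(cell[cell["subgroup"] == "pdl1_ge1"], risk_interval=3.0)
    rec_known.append(reconstruct_ipd(c, r).observations)

remainder = subtract_subgroup(pd.concat(rec_overall), pd.concat(rec_known))
print(cox_marginal(remainder, cluster=None).hr)
```

Running the full example prints

```
derived PD-L1<1% HR 0.592 (0.472-0.742)
hidden truth    HR 0.596 (0.476-0.748)   [generating HR 0.7]
```

— the hazard ratio of the never-observed subgroup, recovered purely from
the two "published" figures, agrees with the Cox fit on the hidden truth to
the second decimal (both sit below the generating HR of 0.7 because of
ordinary sampling noise in a 600-patients-per-arm trial).

The other scripts in `examples/` each demonstrate one capability:
simulation + pooled frailty Cox, the time-varying-HR fit on a
delayed-effect program, RMST scanning with benefit grading, and the
aggregate meta-analysis.

A thin CLI runs the whole chain on a YAML config:

```bash
icimeta all --config config.yaml --seed 1 --out results/
```

Each stage writes its artifacts plus a `manifest.json` recording inputs,
parameters, seed and config hash; the same config and seed reproduce all
outputs bit-identically.

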