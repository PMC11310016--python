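"""Fit the Bayesian piecewise time-varying hazard-ratio model.

Simulates a delayed-treatment-effect program (no benefit before month 12,
HR 0.6 after — the late curve separation typical of immunotherapy trials)
and prints the per-segment posterior HRs and the event-weighted average HR.
"""

import numpy as np

from icimeta import (
    HazardSpec, TrialSimSpec, average_hr, check_convergence,
    fit_piecewise_tvhr, simulate_program,
)

specs = [
    TrialSimSpec(
        trial_id=f"D{i}", n_per_arm=300,
        hazard=HazardSpec.exponential(np.log(2) / 14.0, 0.6),
        delayed_effect_month=12.0, admin_censor_month=40.0,
    )
    for i in range(6)
]
prog = simulate_program(specs, seed=11)
fit = fit_piecewise_tvhr(prog.ipd, chains=4, iterations=1000, warmup=500, seed=3)

print("segment        HR   95% credible    events")
for s in range(len(fit.beta_mean)):
    if fit.events_per_segment[s] == 0:
        continue
    lo, hi = np.exp(fit.beta_ci[s])
    print(f"[{fit.segment_bounds[s]:4.0f},{fit.segment_bounds[s+1]:3.0f})  "
          f"{np.exp(fit.beta_mean[s]):5.2f}  ({lo:4.2f}-{hi:4.2f})  "
          f"{int(fit.events_per_segment[s]):6d}")

avg, (lo, hi) = average_hr(fit)
diag = check_convergence(fit)
print(f"\naverage HR (event-weighted): {avg:.3f} ({lo:.3f}-{hi:.3f})")
print(f"max split-chain Rhat: {diag['rhat_max']:.3f}  converged: {diag['passed']}")
# early segments sit near HR 1, post-onset segments near 0.6 — the
# signature of a delayed effect that a single Cox HR would average away
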