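"""Decode individual patient data from a published-style KM figure.

Builds a tiny digitized curve plus number-at-risk table by hand, runs the
reconstruction, and prints the decoded event/censoring assignment.
"""

import numpy as np

from icimeta import DigitizedCurve, RiskTable, km_estimate, reconstruct_ipd

# a 40-patient arm: survival halves by month 9, plateaus, tail censoring
curve = DigitizedCurve(
    trial_id="DEMO", arm="control", endpoint="OS", subgroup="overall",
    times=np.array([0.0, 3.0, 6.0, 9.0, 12.0, 18.0, 24.0]),
    survival=np.array([1.0, 0.85, 0.65, 0.50, 0.45, 0.40, 0.35]),
)
risk = RiskTable(
    trial_id="DEMO", arm="control", endpoint="OS", subgroup="overall",
    times=np.array([0.0, 6.0, 12.0, 18.0, 24.0]),
    n_at_risk=np.array([40, 26, 16, 10, 4]),
)

result = reconstruct_ipd(curve, risk)
print(f"decoded {result.n_events_assigned} events, "
      f"{result.n_censored_assigned} censored "
      f"(max at-risk deviation {result.max_at_risk_deviation})")

km = km_estimate(result.observations)
for t in curve.times:
    s = km.survival_at(float(t))[0]
    print(f"  t={t:5.1f} months  published S={curve.survival[list(curve.times).index(t)]:.2f}  decoded S={s:.2f}")
# the decoded KM curve re-traces the published coordinates; residual
# differences reflect integer patient counts, not algorithmic bias
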