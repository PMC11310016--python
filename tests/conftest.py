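import numpy as np
import pandas as pd
import pytest

from icimeta import HazardSpec, TrialSimSpec, simulate_program, simulate_trial


def make_ipd(times_exp, events_exp, times_ctl, events_ctl, trial_id="T1",
             endpoint="OS", subgroup="overall"):
    """Hand-built two-arm IPD frame."""
    rows = []
    for arm, times, events in (
        ("experimental", times_exp, events_exp),
        ("control", times_ctl, events_ctl),
    ):
        for t, e in zip(times, events):
            rows.append((trial_id, arm, endpoint, subgroup, float(t), int(e)))
    return pd.DataFrame(
        rows,
        columns=["trial_id", "arm", "endpoint", "subgroup", "time_months", "event"],
    )


@pytest.fixture(scope="session")
def exp_trial_ipd():
    """One mid-size trial, exponential hazards, true HR 0.7."""
    spec = TrialSimSpec(
        n_per_arm=250, subgroup_fraction=0.0,
        hazard=HazardSpec.exponential(np.log(2) / 12.0, 0.7),
        accrual_months=12.0, admin_censor_month=30.0, dropout_rate=0.005,
    )
    return simulate_trial(spec, 11)


@pytest.fixture(scope="session")
def frailty_program():
    """20 trials with shared gamma frailty (theta = 0.25), true HR 0.8."""
    specs = [
        TrialSimSpec(
            trial_id=f"t{i:02d}", n_per_arm=300,
            hazard=HazardSpec.exponential(np.log(2) / 12.0, 0.8),
            frailty_variance=0.25,
        )
        for i in range(20)
    ]
    return simulate_program(specs, 42)
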