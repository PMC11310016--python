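import subprocess
import sys

import numpy as np
import pandas as pd
import pytest

from icimeta import (
    HazardSpec,
    TrialSimSpec,
    cox_marginal,
    cox_shared_frailty,
    km_estimate,
    logrank_test,
    registry_frame,
    simulate_program,
    simulate_trial,
    subgroup_analysis,
)
from tests.conftest import make_ipd


class TestKM:
    def test_all_censored_survival_stays_one(self):
        ipd = make_ipd([], [], [5, 8, 12], [0, 0, 0])
        km = km_estimate(ipd)
        assert (km.survival == 1.0).all()
        assert km.median is None

    def test_hand_product_limit(self):
        ipd = make_ipd([], [], [6, 6, 12, 12], [1, 1, 0, 0])
        km = km_estimate(ipd)
        assert km.survival_at(6.0)[0] == pytest.approx(0.5)
        assert km.median == pytest.approx(6.0)

    def test_single_patient_event(self):
        ipd = make_ipd([], [], [3], [1])
        km = km_estimate(ipd)
        assert km.survival_at(3.0)[0] == 0.0

    def test_km_equals_product_over_event_times(self, exp_trial_ipd):
        sub = exp_trial_ipd[exp_trial_ipd["arm"] == "control"]
        km = km_estimate(sub)
        t = sub["time_months"].to_numpy()
        e = sub["event"].to_numpy()
        prod = 1.0
        for u in np.unique(t[e == 1]):
            n_at = (t >= u).sum()
            d = ((t == u) & (e == 1)).sum()
            prod *= 1 - d / n_at
        last = np.unique(t[e == 1]).max()
        assert km.survival_at(last)[0] == pytest.approx(prod, rel=1e-10)

    def test_greenwood_ci_brackets_estimate(self, exp_trial_ipd):
        km = km_estimate(exp_trial_ipd)
        s, lo, hi = km.survival_at(12.0)
        assert lo <= s <= hi
        assert 0.0 <= lo and hi <= 1.0


class TestLogrank:
    def test_identical_arms_statistic_zero(self):
        base = [3, 5, 8, 12, 15]
        ipd = make_ipd(base, [1, 1, 0, 1, 0], base, [1, 1, 0, 1, 0])
        stat, p = logrank_test(ipd)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_matches_hand_hypergeometric_computation(self):
        # arm A events at 1, 2; arm B events at 3, 4; no censoring
        ipd = make_ipd([1, 2], [1, 1], [3, 4], [1, 1])
        # observed - expected for arm A: at t=1 n=4, nA=2, E=0.5; t=2 n=3,
        # nA=1, E=1/3; later events occur with nA=0
        o_minus_e = (1 - 0.5) + (1 - 1 / 3)
        v = (2 * 2 / 16) * 1 + (1 * 2 / 9) * 1  # hypergeometric variances
        expected_stat = o_minus_e**2 / v
        stat, _ = logrank_test(ipd)
        assert stat == pytest.approx(expected_stat, rel=1e-6)

    def test_empty_arm_rejected(self):
        ipd = make_ipd([1, 2], [1, 1], [], [])
        with pytest.raises(ValueError):
            logrank_test(ipd)


class TestCoxMarginal:
    def test_recovers_true_hr(self):
        spec = TrialSimSpec(
            n_per_arm=4000, hazard=HazardSpec.exponential(np.log(2) / 12, 0.8),
        )
        ipd = simulate_trial(spec, 8)
        res = cox_marginal(ipd, cluster=None)
        assert res.hr == pytest.approx(0.8, abs=0.05)
        assert res.ci_low < res.hr < res.ci_high

    def test_permuted_treatment_is_null(self, exp_trial_ipd):
        rng = np.random.default_rng(1)
        ipd = exp_trial_ipd.copy()
        ipd["arm"] = rng.permutation(ipd["arm"].to_numpy())
        res = cox_marginal(ipd, cluster=None)
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_cluster_robust_close_to_model_se_single_trial(self):
        spec = TrialSimSpec(n_per_arm=2000)
        ipd = simulate_trial(spec, 15)
        robust = cox_marginal(ipd)  # single trial: falls back to model SE
        naive = cox_marginal(ipd, cluster=None)
        assert robust.se_log_hr == pytest.approx(naive.se_log_hr, rel=0.2)


class TestSharedFrailty:
    def test_degenerate_frailty_matches_marginal_cox(self):
        specs = [TrialSimSpec(trial_id=f"s{i}", n_per_arm=200) for i in range(5)]
        prog = simulate_program(specs, 3)
        f = cox_shared_frailty(prog.ipd)
        m = cox_marginal(prog.ipd, cluster=None)
        assert f.theta <= 0.02
        assert f.hr == pytest.approx(m.hr, abs=0.03)

    def test_parameter_recovery_theta_quarter(self, frailty_program):
        f = cox_shared_frailty(frailty_program.ipd)
        assert 0.1 <= f.theta <= 0.45
        assert f.ci_low <= 0.8 <= f.ci_high

    def test_single_trial_rejected(self, exp_trial_ipd):
        with pytest.raises(ValueError, match="2 trials"):
            cox_shared_frailty(exp_trial_ipd)

    def test_theta_fixed_near_zero_reproduces_unadjusted_cox(self, exp_trial_ipd):
        f = cox_shared_frailty(exp_trial_ipd, theta=1e-6)
        m = cox_marginal(exp_trial_ipd, cluster=None)
        assert np.log(f.hr) == pytest.approx(np.log(m.hr), abs=1e-4)

    def test_agrees_with_r_survival_oracle(self, tmp_path):
        # independent implementation check: R survival::coxph gamma frailty
        specs = [TrialSimSpec(trial_id=f"t{i}", n_per_arm=150,
                              hazard=HazardSpec.exponential(np.log(2) / 12, 0.75),
                              frailty_variance=0.3) for i in range(8)]
        prog = simulate_program(specs, 17)
        csv = tmp_path / "ipd.csv"
        prog.ipd.to_csv(csv, index=False)
        f = cox_shared_frailty(prog.ipd)
        rscript = (
            'suppressMessages(library(survival));'
            f'd <- read.csv("{csv}");'
            'd$treat <- as.integer(d$arm == "experimental");'
            'fit <- coxph(Surv(time_months, event) ~ treat + frailty.gamma(trial_id), data=d);'
            'cat(coef(fit)["treat"], sqrt(fit$var[1,1]))'
        )
        try:
            out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                                 text=True, timeout=240, check=True)
        except (FileNotFoundError, subprocess.CalledProcessError) as exc:
            pytest.skip(f"Rscript unavailable: {exc}")
        beta_r, se_r = map(float, out.stdout.split())
        assert np.log(f.hr) == pytest.approx(beta_r, abs=0.01)
        assert f.se_log_hr == pytest.approx(se_r, rel=0.05)


class TestSubgroupAnalysis:
    @pytest.fixture(scope="class")
    def homogeneous_program(self):
        specs = [
            TrialSimSpec(trial_id=f"h{i}", n_per_arm=800,
                         hazard=HazardSpec.exponential(np.log(2) / 12, 0.8),
                         cancer_type=["NSCLC", "SCLC"][i % 2])
            for i in range(4)
        ]
        return simulate_program(specs, 12)

    def test_homogeneous_levels_small_q(self, homogeneous_program):
        reg = registry_frame(homogeneous_program.registry)
        table = subgroup_analysis(homogeneous_program.ipd, reg, "cancer_type")
        assert table.p_difference > 0.2

    def test_distinct_levels_detected(self):
        specs = [
            TrialSimSpec(trial_id="a", n_per_arm=2000,
                         hazard=HazardSpec.exponential(np.log(2) / 12, 0.6),
                         cancer_type="NSCLC"),
            TrialSimSpec(trial_id="b", n_per_arm=2000,
                         hazard=HazardSpec.exponential(np.log(2) / 12, 1.0),
                         cancer_type="SCLC"),
        ]
        prog = simulate_program(specs, 14)
        table = subgroup_analysis(prog.ipd, registry_frame(prog.registry), "cancer_type")
        assert table.p_difference < 0.05
        assert table.levels["NSCLC"].hr < table.levels["SCLC"].hr

    def test_single_level_flags_omitted_test(self, exp_trial_ipd):
        reg = pd.DataFrame({
            "trial_id": ["trial-1"], "cancer_type": ["NSCLC"],
        }).set_index("trial_id", drop=False)
        table = subgroup_analysis(exp_trial_ipd, reg, "cancer_type")
        assert table.p_difference is None
        assert any("omitted" in f for f in table.flags)
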