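import numpy as np
import pandas as pd
import pytest

from icimeta import (
    DigitizedCurve,
    HazardSpec,
    RiskTable,
    TrialSimSpec,
    cox_marginal,
    km_estimate,
    preprocess_curve,
    reconstruct_ipd,
    render_km,
    simulate_trial,
    summarize_ipd,
    validate_reconstruction,
)


def _curve(times, surv, **kw):
    meta = dict(trial_id="T1", arm="control", endpoint="OS", subgroup="overall")
    meta.update(kw)
    return DigitizedCurve(meta["trial_id"], meta["arm"], meta["endpoint"],
                          meta["subgroup"], np.asarray(times, float),
                          np.asarray(surv, float))


def _risk(times, counts, **kw):
    meta = dict(trial_id="T1", arm="control", endpoint="OS", subgroup="overall")
    meta.update(kw)
    return RiskTable(meta["trial_id"], meta["arm"], meta["endpoint"],
                     meta["subgroup"], np.asarray(times, float),
                     np.asarray(counts, int))


class TestPreprocess:
    def test_valid_curve_unchanged(self):
        c = preprocess_curve(_curve([0, 6, 12], [1.0, 0.6, 0.4]))
        np.testing.assert_allclose(c.times, [0, 6, 12])
        np.testing.assert_allclose(c.survival, [1.0, 0.6, 0.4])

    def test_pav_projection_of_nonmonotone_digitization(self):
        c = preprocess_curve(_curve([0, 3, 6, 9], [1.0, 0.62, 0.64, 0.50]))
        np.testing.assert_allclose(c.survival, [1.0, 0.63, 0.63, 0.50])

    def test_overshoot_clamped_to_one(self):
        c = preprocess_curve(_curve([0, 2, 4], [1.03, 0.9, 0.8]))
        assert c.survival[0] == 1.0
        assert c.survival.max() <= 1.0

    def test_duplicate_times_collapse_to_min_survival(self):
        c = preprocess_curve(_curve([0, 5, 5, 8], [1.0, 0.8, 0.7, 0.6]))
        np.testing.assert_allclose(c.times, [0, 5, 8])
        np.testing.assert_allclose(c.survival, [1.0, 0.7, 0.6])

    def test_fewer_than_two_distinct_times_rejected(self):
        with pytest.raises(ValueError):
            preprocess_curve(_curve([0, 0], [1.0, 0.9]))


class TestReconstruct:
    def test_hand_km_inversion_unique_solution(self):
        curve = _curve([0, 6, 12], [1.0, 0.5, 0.5])
        risk = _risk([0, 12], [4, 2])
        res = reconstruct_ipd(curve, risk)
        assert res.n_events_assigned == 2
        assert res.n_censored_assigned == 2
        ev = res.observations[res.observations["event"] == 1]
        assert (ev["time_months"] == 6.0).all()

    def test_flat_curve_all_censored_at_end(self):
        curve = _curve([0, 12], [1.0, 1.0])
        risk = _risk([0, 12], [10, 10])
        res = reconstruct_ipd(curve, risk)
        assert res.n_events_assigned == 0
        assert res.n_censored_assigned == 10
        assert (res.observations["time_months"] == 12.0).all()

    def test_rising_risk_table_rejected(self):
        curve = _curve([0, 6, 12], [1.0, 0.8, 0.7])
        risk = _risk([0, 6, 12], [10, 12, 5])
        with pytest.raises(ValueError, match="non-increasing|rises"):
            reconstruct_ipd(curve, risk)

    def test_count_conservation_across_random_cohorts(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            spec = TrialSimSpec(
                n_per_arm=60 + 20 * seed, subgroup_fraction=0.0,
                hazard=HazardSpec.exponential(np.log(2) / 10, 0.9),
            )
            ipd = simulate_trial(spec, seed)
            cell = ipd[ipd["arm"] == "control"].assign(subgroup="overall")
            c, r = render_km(cell, risk_interval=4.0, jitter_sd=0.01, rng=rng)
            res = reconstruct_ipd(c, r)
            assert res.n_events_assigned + res.n_censored_assigned == len(cell)

    def test_round_trip_recovers_median_and_hr(self):
        spec = TrialSimSpec(
            n_per_arm=250, subgroup_fraction=0.0,
            hazard=HazardSpec.exponential(np.log(2) / 12.0, 0.7),
            accrual_months=12.0, admin_censor_month=30.0, dropout_rate=0.005,
        )
        ipd = simulate_trial(spec, 11)
        rec = []
        for arm in ("experimental", "control"):
            cell = ipd[ipd["arm"] == arm].assign(subgroup="overall")
            c, r = render_km(cell, risk_interval=3.0, jitter_sd=0.0)
            rec.append(reconstruct_ipd(c, r).observations)
        rec = pd.concat(rec, ignore_index=True)
        for arm in ("experimental", "control"):
            med_true = km_estimate(ipd[ipd["arm"] == arm]).median
            med_rec = km_estimate(rec[rec["arm"] == arm]).median
            assert med_rec == pytest.approx(med_true, abs=0.5)
        lhr_true = np.log(cox_marginal(ipd, cluster=None).hr)
        lhr_rec = np.log(cox_marginal(rec, cluster=None).hr)
        assert lhr_rec == pytest.approx(lhr_true, abs=0.05)

    def test_exact_recovery_on_gridded_noiseless_input(self):
        # event/censor times on a 0.5-month grid with a risk-table entry at
        # every grid point: the decoded KM must match every coordinate
        spec = TrialSimSpec(
            n_per_arm=80, subgroup_fraction=0.0,
            hazard=HazardSpec.exponential(np.log(2) / 10.0, 1.0),
            accrual_months=6.0, admin_censor_month=24.0, dropout_rate=0.01,
        )
        ipd = simulate_trial(spec, 21)
        cell = ipd[ipd["arm"] == "control"].copy()
        cell["time_months"] = np.ceil(cell["time_months"] * 2) / 2
        cell["subgroup"] = "overall"
        c, r = render_km(cell, risk_interval=0.5, coordinate_step=0.5)
        res = reconstruct_ipd(c, r)
        km = km_estimate(res.observations)
        for t, s in zip(c.times, c.survival):
            assert km.survival_at(t)[0] == pytest.approx(s, abs=1e-6)
        assert res.max_at_risk_deviation == 0

    def test_total_events_rescaling(self):
        curve = _curve([0, 6, 12], [1.0, 0.5, 0.25])
        risk = _risk([0], [8])
        res = reconstruct_ipd(curve, risk, total_events=4)
        assert res.n_events_assigned == 4
        assert any("rescaled" in f for f in res.flags)

    def test_reconstruction_error_degrades_with_jitter(self):
        # averaged over seeds, digitization noise cannot improve accuracy
        errs = {0.0: [], 0.02: []}
        for seed in range(4):
            spec = TrialSimSpec(
                n_per_arm=200, subgroup_fraction=0.0,
                hazard=HazardSpec.exponential(np.log(2) / 12, 0.75),
            )
            ipd = simulate_trial(spec, 100 + seed)
            lhr_true = np.log(cox_marginal(ipd, cluster=None).hr)
            for jit in errs:
                rng = np.random.default_rng(seed)
                rec = []
                for arm in ("experimental", "control"):
                    cell = ipd[ipd["arm"] == arm].assign(subgroup="overall")
                    c, r = render_km(cell, risk_interval=3.0, jitter_sd=jit, rng=rng)
                    rec.append(reconstruct_ipd(c, r).observations)
                lhr = np.log(cox_marginal(pd.concat(rec), cluster=None).hr)
                errs[jit].append(abs(lhr - lhr_true))
        assert np.mean(errs[0.0]) <= np.mean(errs[0.02]) + 1e-6


class TestValidateReconstruction:
    def test_identity_comparison_is_perfect(self, exp_trial_ipd):
        sums = [summarize_ipd(exp_trial_ipd)] * 3
        report = validate_reconstruction(sums, sums)
        assert all(abs(d) < 1e-12 for devs in report.deviations.values() for d in devs)
        assert report.min_pearson_r == pytest.approx(1.0)

    def test_two_pairs_omit_correlation_with_flag(self, exp_trial_ipd):
        sums = [summarize_ipd(exp_trial_ipd)] * 2
        report = validate_reconstruction(sums, sums)
        assert all(v is None for v in report.pearson.values())
        assert report.flags
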