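import itertools

import numpy as np
import pandas as pd
import pytest

from icimeta import (
    HazardSpec,
    MatchSpec,
    TrialSimSpec,
    cox_marginal,
    estimate_error_limits,
    km_estimate,
    reconstruct_ipd,
    render_km,
    simulate_trial,
    subtract_subgroup,
)
from icimeta.subtract import _match_one_arm
from tests.conftest import make_ipd


def _frame(times, events, arm="control", subgroup="overall"):
    return pd.DataFrame({
        "trial_id": "T1", "arm": arm, "endpoint": "OS", "subgroup": subgroup,
        "time_months": np.asarray(times, float), "event": np.asarray(events, int),
    })


class TestSubtract:
    def test_empty_subgroup_returns_overall(self):
        overall = _frame([1, 2, 3], [1, 0, 1])
        out = subtract_subgroup(overall, overall.iloc[:0])
        assert len(out) == 3
        assert (out["subgroup"] == "pdl1_lt1").all()

    def test_identical_subgroup_annihilates(self):
        overall = _frame([1, 2, 3, 4], [1, 0, 1, 0])
        out = subtract_subgroup(overall, overall.copy())
        assert out.empty

    def test_oversized_subgroup_rejected(self):
        overall = _frame([1, 2], [1, 1])
        sub = _frame([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError, match="larger than overall"):
            subtract_subgroup(overall, sub)

    def test_mismatched_trial_rejected(self):
        overall = _frame([1, 2], [1, 1])
        sub = _frame([1], [1]).assign(trial_id="OTHER")
        with pytest.raises(ValueError, match="trial_id"):
            subtract_subgroup(overall, sub)

    @pytest.mark.parametrize("seed", range(4))
    def test_count_conservation_per_arm(self, seed):
        rng = np.random.default_rng(seed)
        n_over = rng.integers(10, 40)
        n_sub = rng.integers(0, n_over + 1)
        rows = []
        for arm in ("experimental", "control"):
            rows.append(_frame(rng.exponential(10, n_over),
                               rng.integers(0, 2, n_over), arm=arm))
        overall = pd.concat(rows, ignore_index=True)
        sub_rows = []
        for arm in ("experimental", "control"):
            arm_rows = overall[overall["arm"] == arm].sample(
                n_sub, random_state=seed)
            sub_rows.append(arm_rows.assign(subgroup="pdl1_ge1"))
        known = pd.concat(sub_rows, ignore_index=True)
        out = subtract_subgroup(overall, known)
        for arm in ("experimental", "control"):
            assert (out["arm"] == arm).sum() == n_over - n_sub

    @pytest.mark.parametrize("seed", range(5))
    def test_matching_optimality_vs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_over = int(rng.integers(3, 8))
        n_sub = int(rng.integers(1, n_over + 1))
        over = _frame(rng.uniform(0, 20, n_over), rng.integers(0, 2, n_over))
        sub = _frame(rng.uniform(0, 20, n_sub), rng.integers(0, 2, n_sub))
        penalty = 200.0
        _, cost = _match_one_arm(over, sub, penalty)
        t_o = over["time_months"].to_numpy()
        e_o = over["event"].to_numpy()
        t_s = sub["time_months"].to_numpy()
        e_s = sub["event"].to_numpy()
        best = min(
            sum(abs(t_s[i] - t_o[j]) + penalty * (e_s[i] != e_o[j])
                for i, j in enumerate(perm))
            for perm in itertools.permutations(range(n_over), n_sub)
        )
        assert cost == pytest.approx(best, rel=1e-12)

    def test_km_dominance_when_subgroup_uniformly_worse(self):
        # known subgroup holds the earliest events; remainder must lie at or
        # above the overall curve everywhere
        times = [1, 2, 3, 10, 12, 14, 20, 22]
        events = [1, 1, 1, 1, 1, 0, 0, 0]
        rows = []
        for arm in ("experimental", "control"):
            rows.append(_frame(times, events, arm=arm))
        overall = pd.concat(rows, ignore_index=True)
        known = pd.concat([
            _frame([1, 2, 3], [1, 1, 1], arm=a) for a in ("experimental", "control")
        ], ignore_index=True).assign(subgroup="pdl1_ge1")
        remainder = subtract_subgroup(overall, known)
        km_over = km_estimate(overall)
        km_rem = km_estimate(remainder)
        for t in times:
            assert km_rem.survival_at(t)[0] >= km_over.survival_at(t)[0] - 1e-12

    def test_mixture_recovery_through_full_chain(self):
        # 40% PD-L1<1% with true subgroup HR 0.7; render overall + known
        # subgroup, reconstruct, subtract: remainder HR ~ truth-IPD HR
        spec = TrialSimSpec(
            n_per_arm=600, subgroup_fraction=0.4,
            hazard=HazardSpec.exponential(np.log(2) / 12, hr_lt1=0.7, hr_ge1=1.0),
        )
        ipd = simulate_trial(spec, 29)
        rec_over, rec_known = [], []
        for arm in ("experimental", "control"):
            cell = ipd[ipd["arm"] == arm]
            c, r = render_km(cell.assign(subgroup="overall"), 3.0)
            rec_over.append(reconstruct_ipd(c, r).observations)
            c, r = render_km(cell[cell["subgroup"] == "pdl1_ge1"], 3.0)
            rec_known.append(reconstruct_ipd(c, r).observations)
        remainder = subtract_subgroup(
            pd.concat(rec_over, ignore_index=True),
            pd.concat(rec_known, ignore_index=True),
        )
        truth = ipd[ipd["subgroup"] == "pdl1_lt1"]
        lhr_rem = np.log(cox_marginal(remainder, cluster=None).hr)
        lhr_true = np.log(cox_marginal(truth, cluster=None).hr)
        assert lhr_rem == pytest.approx(lhr_true, abs=0.15)
        assert lhr_rem == pytest.approx(np.log(0.7), abs=0.3)


class TestErrorLimits:
    TEMPLATE = TrialSimSpec(
        n_per_arm=400, subgroup_fraction=0.4,
        hazard=HazardSpec.exponential(np.log(2) / 12, hr_lt1=0.7, hr_ge1=1.0),
    )

    def test_single_iteration_collapses_interval(self):
        lim = estimate_error_limits(self.TEMPLATE, n_iterations=1, seed=1)
        lo, hi = lim.deviation_interval_95
        assert lo == pytest.approx(hi)
        assert lim.n_iterations == 1

    def test_pure_subgroup_template_rejected(self):
        bad = TrialSimSpec(n_per_arm=50, subgroup_fraction=0.0)
        with pytest.raises(ValueError, match="subgroup_fraction"):
            estimate_error_limits(bad, n_iterations=2, seed=1)

    def test_noiseless_chain_error_is_small(self):
        template = TrialSimSpec(
            n_per_arm=2000, subgroup_fraction=0.4,
            hazard=HazardSpec.exponential(np.log(2) / 12, hr_lt1=0.7, hr_ge1=1.0),
        )
        lim = estimate_error_limits(template, n_iterations=20, seed=2)
        assert lim.mean_abs_log_hr_deviation < 0.05
        lo, hi = lim.deviation_interval_95
        assert lo <= 0.0 <= hi
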