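import math

import numpy as np
import pytest

from icimeta import (
    AggregateEffect,
    compare_ipd_vs_total,
    eggers_test,
    pool_random_effects,
)


def eff(trial, hr, lo, hi, endpoint="OS"):
    return AggregateEffect(trial, endpoint, hr, lo, hi)


def dl_oracle(studies):
    """Spreadsheet-style DerSimonian–Laird from (hr, lo, hi) tuples."""
    z = 1.959963984540054
    y = [math.log(h) for h, _, _ in studies]
    se = [(math.log(u) - math.log(l)) / (2 * z) for _, l, u in studies]
    w = [1 / s**2 for s in se]
    ybar = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
    q = sum(wi * (yi - ybar) ** 2 for wi, yi in zip(w, y))
    denom = sum(w) - sum(wi**2 for wi in w) / sum(w)
    tau2 = max(0.0, (q - (len(y) - 1)) / denom)
    wr = [1 / (s**2 + tau2) for s in se]
    mu = sum(wi * yi for wi, yi in zip(wr, y)) / sum(wr)
    return math.exp(mu), tau2


class TestPooling:
    def test_identical_studies_pool_to_themselves(self):
        effects = [eff("a", 0.80, 0.70, 0.91), eff("b", 0.80, 0.70, 0.91)]
        res = pool_random_effects(effects)
        assert res.hr == pytest.approx(0.80, abs=1e-6)
        assert res.tau2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_dersimonian_laird(self):
        studies = [(0.7, 0.55, 0.89), (0.9, 0.75, 1.08), (1.1, 0.85, 1.42)]
        effects = [eff(t, *s) for t, s in zip("abc", studies)]
        res = pool_random_effects(effects)
        hr_expected, tau2_expected = dl_oracle(studies)
        assert res.hr == pytest.approx(hr_expected, abs=5e-4)
        assert res.tau2 == pytest.approx(tau2_expected, abs=5e-4)

    def test_order_invariance(self):
        effects = [eff("a", 0.7, 0.5, 0.95), eff("b", 1.1, 0.9, 1.35),
                   eff("c", 0.85, 0.6, 1.2)]
        a = pool_random_effects(effects)
        b = pool_random_effects(effects[::-1])
        assert a.hr == pytest.approx(b.hr, rel=1e-12)
        assert a.tau2 == pytest.approx(b.tau2, rel=1e-12)

    def test_weights_sum_to_one(self):
        effects = [eff("a", 0.7, 0.5, 0.95), eff("b", 1.1, 0.9, 1.35),
                   eff("c", 0.85, 0.6, 1.2)]
        res = pool_random_effects(effects)
        assert sum(res.weights.values()) == pytest.approx(1.0)

    def test_adding_study_at_pooled_value_is_consistent(self):
        # the estimate may shift slightly because tau^2 is re-estimated, but
        # it must stay bracketed by the component studies and close to the
        # previous pooled value relative to its standard error
        effects = [eff("a", 0.7, 0.55, 0.89), eff("b", 0.9, 0.75, 1.08)]
        base = pool_random_effects(effects)
        hr = base.hr
        extra = eff("c", hr, hr * 0.8, hr / 0.8)
        res = pool_random_effects(effects + [extra])
        assert 0.7 <= res.hr <= 0.9
        se_pooled = (np.log(base.ci_high) - np.log(base.ci_low)) / (2 * 1.96)
        assert abs(np.log(res.hr) - np.log(hr)) < 0.25 * se_pooled

    def test_zero_heterogeneity_reduces_to_fixed_effect_mean(self):
        # Q < k-1 forces tau^2 = 0; pooled = inverse-variance mean
        studies = [(0.80, 0.70, 0.914), (0.82, 0.70, 0.96), (0.81, 0.68, 0.965)]
        effects = [eff(t, *s) for t, s in zip("abc", studies)]
        res = pool_random_effects(effects)
        assert res.tau2 == 0.0
        z = 1.959963984540054
        y = [math.log(h) for h, _, _ in studies]
        se = [(math.log(u) - math.log(l)) / (2 * z) for _, l, u in studies]
        w = [1 / s**2 for s in se]
        fe = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
        assert np.log(res.hr) == pytest.approx(fe, abs=1e-12)

    def test_homogeneous_strata_no_subgroup_difference(self):
        effects = [eff(t, 0.8, 0.65, 0.98) for t in "abcd"]
        strata = {"a": "x", "b": "x", "c": "y", "d": "y"}
        res = pool_random_effects(effects, stratify_by=strata)
        assert res.subgroup_p > 0.9
        assert set(res.by_stratum) == {"x", "y"}

    def test_single_effect_rejected(self):
        with pytest.raises(ValueError):
            pool_random_effects([eff("a", 0.8, 0.7, 0.9)])

    def test_degenerate_ci_rejected(self):
        with pytest.raises(Exception):
            pool_random_effects([eff("a", 0.8, 0.9, 0.7), eff("b", 0.8, 0.7, 0.9)])


class TestEgger:
    def test_symmetric_construction_gives_zero_intercept(self):
        # effects mirrored about the mean with matched SEs: no asymmetry
        ses = [0.1, 0.2, 0.3]
        z = 1.959963984540054
        effects = []
        for i, s in enumerate(ses):
            for sign, tag in ((1, "p"), (-1, "m")):
                y = sign * s  # standardized offset proportional to se
                hr = math.exp(y)
                effects.append(eff(f"{tag}{i}", hr, math.exp(y - z * s), math.exp(y + z * s)))
        rep = eggers_test(effects)
        assert rep.intercept == pytest.approx(0.0, abs=1e-8)
        assert rep.p_value > 0.05

    def test_two_effects_rejected(self):
        with pytest.raises(ValueError):
            eggers_test([eff("a", 0.8, 0.7, 0.9), eff("b", 0.8, 0.7, 0.9)])

    def test_identical_effects_degenerate_symmetry(self):
        effects = [eff(t, 0.8, 0.7, 0.91) for t in "abc"]
        rep = eggers_test(effects)
        assert rep.intercept == 0.0
        assert rep.p_value == 1.0


class TestIPDRepresentativeness:
    def test_all_ipd_subsets_identical(self):
        effects = [eff(t, 0.8, 0.6, 1.05) for t in "abcd"]
        flags = {t: True for t in "abcd"}
        rep = compare_ipd_vs_total(effects, flags)
        assert rep["p_between"] == pytest.approx(1.0)
        assert rep["comparable"]

    def test_random_ipd_availability_rarely_differs(self):
        rng = np.random.default_rng(7)
        z = 1.959963984540054
        n_ok = 0
        reps = 100
        for _ in range(reps):
            effects = []
            flags = {}
            for i in range(12):
                se = rng.uniform(0.08, 0.3)
                y = rng.normal(np.log(0.8), se)
                tid = f"t{i}"
                effects.append(eff(tid, math.exp(y), math.exp(y - z * se),
                                   math.exp(y + z * se)))
                flags[tid] = bool(rng.random() < 0.6)
            if sum(flags.values()) < 2:
                flags["t0"] = flags["t1"] = True
            rep = compare_ipd_vs_total(effects, flags)
            n_ok += rep["p_between"] > 0.05
        assert n_ok >= 0.90 * reps

    def test_empty_ipd_subset_rejected(self):
        effects = [eff(t, 0.8, 0.6, 1.05) for t in "abc"]
        with pytest.raises(ValueError):
            compare_ipd_vs_total(effects, {})
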