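"""Two-stage random-effects meta-analysis and publication-bias diagnostics.

Aggregate hazard ratios (with 95% CIs) are pooled on the log scale with
DerSimonian–Laird heterogeneity: standard errors derive from the CIs as
(ln U - ln L) / (2 * 1.96), the between-study variance tau^2 is the DL
moment estimator, and weights are inverse total variance.  Trials with
reconstructed IPD enter the same pooling through their per-trial marginal
Cox HRs, which is how IPD and aggregate-only evidence are combined.

Egger's regression (standardized effect on precision, weighted) tests
funnel asymmetry; the IPD-representativeness check compares the pooled HR
of the IPD-available subset against the pooled HR of all trials with a
between-group Q test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .data_model import AggregateEffect

__all__ = [
    "MetaResult",
    "BiasReport",
    "effects_from_hr_results",
    "pool_random_effects",
    "eggers_test",
    "compare_ipd_vs_total",
]

_Z = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass
class MetaResult:
    hr: float
    ci_low: float
    ci_high: float
    tau2: float
    weights: dict[str, float]
    q_statistic: float
    q_p_value: float
    n_studies: int
    by_stratum: dict[str, "MetaResult"] | None = None
    subgroup_q: float | None = None
    subgroup_p: float | None = None


@dataclass
class BiasReport:
    intercept: float
    ci_low: float
    ci_high: float
    p_value: float
    funnel: list[tuple[str, float, float]]  # (trial, log hr, se)


def _log_scale(effects: Sequence[AggregateEffect]):
    y = np.array([np.log(e.hr) for e in effects])
    se = np.array([(np.log(e.ci_high) - np.log(e.ci_low)) / (2 * _Z) for e in effects])
    if np.any(se <= 0):
        bad = [e.trial_id for e, s in zip(effects, se) if s <= 0]
        raise ValueError(f"degenerate CI (upper <= lower) for {bad}")
    return y, se


def _dl_pool(y: np.ndarray, se: np.ndarray):
    """DerSimonian–Laird pooled mean, CI half-widths and tau^2 on log scale."""
    w = 1.0 / se**2
    ybar_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - ybar_fe) ** 2))
    k = len(y)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (se**2 + tau2)
    mu = float(np.sum(w_re * y) / np.sum(w_re))
    se_mu = float(np.sqrt(1.0 / np.sum(w_re)))
    return mu, se_mu, tau2, q, w_re


def pool_random_effects(
    effects: Sequence[AggregateEffect],
    stratify_by: dict[str, str] | None = None,
) -> MetaResult:
    """Random-effects (DerSimonian–Laird) pooled HR.

    ``stratify_by`` maps trial_id to a stratum label; per-stratum pooling is
    then reported together with a between-stratum Q difference test on the
    stratum means.
    """
    if len(effects) < 2:
        raise ValueError("pooling needs at least 2 effects")
    effects = sorted(effects, key=lambda e: e.trial_id)  # order-invariant
    y, se = _log_scale(effects)
    mu, se_mu, tau2, q, w_re = _dl_pool(y, se)
    res = MetaResult(
        hr=float(np.exp(mu)),
        ci_low=float(np.exp(mu - _Z * se_mu)),
        ci_high=float(np.exp(mu + _Z * se_mu)),
        tau2=float(tau2),
        weights={e.trial_id: float(wi / w_re.sum()) for e, wi in zip(effects, w_re)},
        q_statistic=q,
        q_p_value=float(stats.chi2.sf(q, len(y) - 1)),
        n_studies=len(effects),
    )
    if stratify_by is not None:
        strata: dict[str, list[AggregateEffect]] = {}
        for e in effects:
            strata.setdefault(stratify_by[e.trial_id], []).append(e)
        by = {}
        mus, vars_ = [], []
        for label in sorted(strata):
            group = strata[label]
            if len(group) >= 2:
                by[label] = pool_random_effects(group)
                mus.append(np.log(by[label].hr))
                vars_.append(((np.log(by[label].ci_high) - np.log(by[label].ci_low)) / (2 * _Z)) ** 2)
            else:
                gy, gse = _log_scale(group)
                by[label] = MetaResult(
                    hr=float(np.exp(gy[0])),
                    ci_low=float(np.exp(gy[0] - _Z * gse[0])),
                    ci_high=float(np.exp(gy[0] + _Z * gse[0])),
                    tau2=0.0, weights={group[0].trial_id: 1.0},
                    q_statistic=0.0, q_p_value=1.0, n_studies=1,
                )
                mus.append(gy[0])
                vars_.append(gse[0] ** 2)
        wg = 1.0 / np.asarray(vars_)
        mbar = np.sum(wg * mus) / np.sum(wg)
        qb = float(np.sum(wg * (np.asarray(mus) - mbar) ** 2))
        res.by_stratum = by
        res.subgroup_q = qb
        res.subgroup_p = float(stats.chi2.sf(qb, len(by) - 1)) if len(by) > 1 else None
    return res


def effects_from_hr_results(hr_results: dict[str, "HRResult"], endpoint: str = "OS"):
    """Per-trial Cox results (survival module) as aggregate effects for pooling."""
    out = []
    for trial_id, r in hr_results.items():
        out.append(AggregateEffect(
            trial_id=trial_id, endpoint=endpoint,
            hr=r.hr, ci_low=r.ci_low, ci_high=r.ci_high, weight_n=r.n,
        ))
    return out


def eggers_test(effects: Sequence[AggregateEffect]) -> BiasReport:
    """Egger regression asymmetry test with funnel-plot coordinates.

    Weighted regression of the standardized effect y/se on precision 1/se;
    the intercept estimates small-study asymmetry, tested two-tailed against
    the t distribution with k - 2 df.
    """
    if len(effects) < 3:
        raise ValueError("Egger's test needs at least 3 effects")
    y, se = _log_scale(effects)
    snd = y / se
    precision = 1.0 / se
    if np.ptp(precision) == 0 and np.ptp(snd) == 0:
        # identical studies: perfectly symmetric funnel, no asymmetry signal
        return BiasReport(0.0, 0.0, 0.0, 1.0,
                          [(e.trial_id, float(yi), float(si))
                           for e, yi, si in zip(effects, y, se)])
    X = sm.add_constant(precision)
    fit = sm.OLS(snd, X).fit()
    intercept = float(fit.params[0])
    ci = fit.conf_int()[0]
    return BiasReport(
        intercept=intercept,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(fit.pvalues[0]),
        funnel=[(e.trial_id, float(yi), float(si)) for e, yi, si in zip(effects, y, se)],
    )


def compare_ipd_vs_total(
    effects: Sequence[AggregateEffect],
    ipd_flags: dict[str, bool],
) -> dict:
    """Representativeness check: IPD-available subset vs all trials.

    Pools each group and compares the pooled log-HRs with a between-group
    Q test (1 df); the subsets overlap, so the test is conservative.
    Verdict "comparable" iff p > 0.05.
    """
    ipd = [e for e in effects if ipd_flags.get(e.trial_id, False)]
    if not ipd:
        raise ValueError("IPD subset is empty")
    if len(ipd) < 2 or len(effects) < 2:
        raise ValueError("need >= 2 effects in each group")
    pool_ipd = pool_random_effects(ipd)
    pool_all = pool_random_effects(effects)
    mus = np.array([np.log(pool_ipd.hr), np.log(pool_all.hr)])
    vars_ = np.array([
        ((np.log(p.ci_high) - np.log(p.ci_low)) / (2 * _Z)) ** 2
        for p in (pool_ipd, pool_all)
    ])
    w = 1.0 / vars_
    mbar = np.sum(w * mus) / np.sum(w)
    qb = float(np.sum(w * (mus - mbar) ** 2))
    p = float(stats.chi2.sf(qb, 1))
    return {
        "hr_ipd": pool_ipd.hr,
        "hr_total": pool_all.hr,
        "q_between": qb,
        "p_between": p,
        "comparable": p > 0.05,
        "n_ipd": len(ipd),
        "n_total": len(effects),
    }
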