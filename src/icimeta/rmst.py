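"""Restricted mean survival time, clinical-benefit grading, predictive value.

RMST at truncation time tau is the area under the KM curve on [0, tau] —
the mean event-free time over the first tau months — and its between-arm
difference is a proportional-hazards-free measure of absolute benefit.
Truncation defaults follow trial-reporting practice for this literature:
24 months for overall survival, 12 for progression-free survival, shortened
to the minimum over arms of the largest observed time when follow-up is
shorter.

The clinical-benefit grade is a simplified ESMO-MCBS-style rule for OS:
with control median <= 12 months a >= 2-month median gain is meaningful;
with control median in (12, 24] a >= 3-month gain; with medians not
reached, a >= 10-percentage-point gain in 2-year OS; in every case the
upper 95% CI limit of the HR must be below 1.  Meaningful outcomes carry
the single label "grade 3 (meaningful)".

The predictive value of PD-L1 expression is ln(HR_low / HR_high) between
the PD-L1 < 1% and >= 1% populations: positive values mean the drug works
better in PD-L1-expressing disease.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RMSTResult",
    "BenefitGrade",
    "PredictiveValue",
    "choose_truncation",
    "rmst_single",
    "rmst_difference",
    "rmst_scan",
    "grade_benefit",
    "predictive_value",
]

_TAU_DEFAULT = {"OS": 24.0, "PFS": 12.0}


@dataclass
class RMSTResult:
    tau: float
    rmst_experimental: float
    se_experimental: float
    rmst_control: float
    se_control: float
    difference: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class BenefitGrade:
    meaningful: bool
    grade_label: str  # "grade 3 (meaningful)" | "not meaningful" | "rule undefined"
    rule_applied: str  # median_le12 | median_12to24 | os_rate_2yr | undefined
    inputs: dict


@dataclass(frozen=True)
class PredictiveValue:
    pv: float
    hr_low: float
    hr_high: float


def choose_truncation(observations: pd.DataFrame, endpoint: str) -> float:
    """Truncation time: min(default, min over arms of max observed time).

    Default 24 months for OS, 12 for PFS.
    """
    if endpoint not in _TAU_DEFAULT:
        raise ValueError("endpoint must be OS or PFS")
    maxima = []
    for arm in ("experimental", "control"):
        sub = observations[observations["arm"] == arm]
        if sub.empty:
            raise ValueError(f"{arm} arm is empty")
        maxima.append(float(sub["time_months"].max()))
    return float(min(_TAU_DEFAULT[endpoint], min(maxima)))


def rmst_single(time, event, tau: float) -> tuple[float, float]:
    """RMST (area under KM on [0, tau]) with the standard KM-integral SE.

    Variance: sum over event times t_i <= tau of
    A_i^2 * d_i / (n_i * (n_i - d_i)), where A_i is the area under the
    curve from t_i to tau.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if tau > time.max() + 1e-9:
        raise ValueError("tau exceeds the arm's largest observed time")
    uniq = np.unique(time[event == 1])
    uniq = uniq[uniq <= tau]
    n_at = np.array([(time >= u).sum() for u in uniq], dtype=float)
    d = np.array([((time == u) & (event == 1)).sum() for u in uniq], dtype=float)
    surv = np.cumprod(1.0 - d / n_at)
    # step integral of S over [0, tau]
    steps_t = np.concatenate([[0.0], uniq, [tau]])
    steps_s = np.concatenate([[1.0], surv])
    widths = np.diff(steps_t)
    rmst = float(np.sum(steps_s * widths))
    # areas from each event time to tau
    tail_areas = np.cumsum((steps_s * widths)[::-1])[::-1]
    A = tail_areas[1:]  # area from t_i (just after the drop) to tau
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(n_at > d, d / (n_at * (n_at - d)), 0.0)
    var = float(np.sum(A**2 * inc))
    return rmst, float(np.sqrt(var))


def rmst_difference(observations: pd.DataFrame, tau: float) -> RMSTResult:
    """Between-arm RMST difference with normal-approximation CI and p."""
    out = {}
    for arm in ("experimental", "control"):
        sub = observations[observations["arm"] == arm]
        if sub.empty:
            raise ValueError(f"{arm} arm is empty")
        out[arm] = rmst_single(sub["time_months"], sub["event"], tau)
    diff = out["experimental"][0] - out["control"][0]
    se = float(np.hypot(out["experimental"][1], out["control"][1]))
    z = stats.norm.ppf(0.975)
    p = float(2 * stats.norm.sf(abs(diff / se))) if se > 0 else 1.0
    return RMSTResult(
        tau=tau,
        rmst_experimental=out["experimental"][0], se_experimental=out["experimental"][1],
        rmst_control=out["control"][0], se_control=out["control"][1],
        difference=float(diff), ci_low=float(diff - z * se), ci_high=float(diff + z * se),
        p_value=p,
    )


def rmst_scan(
    observations: pd.DataFrame, taus: Sequence[float]
) -> tuple[float | None, list[RMSTResult]]:
    """Earliest truncation time whose RMST-difference CI excludes zero.

    Returns (first significant tau or None, all per-tau results).
    """
    taus = list(taus)
    if not taus:
        raise ValueError("empty truncation grid")
    results = [rmst_difference(observations, float(t)) for t in taus]
    for res in results:
        if res.ci_low > 0 or res.ci_high < 0:
            return res.tau, results
    return None, results


def grade_benefit(
    control_median: float | None,
    experimental_median: float | None,
    hr_ci_upper: float,
    two_year_os: tuple[float, float] | None = None,
    endpoint: str = "OS",
    allow_pfs: bool = False,
) -> BenefitGrade:
    """Simplified clinical-benefit grade for an OS comparison.

    ``None`` medians mean "not reached".  ``two_year_os`` is
    (control, experimental) 2-year survival, required when a median is not
    reached.  The scale is defined for OS; grading PFS requires
    ``allow_pfs=True``.
    """
    if endpoint != "OS" and not allow_pfs:
        raise ValueError("the benefit scale is defined for OS; "
                         "set allow_pfs=True to override")
    inputs = {
        "control_median": control_median,
        "experimental_median": experimental_median,
        "hr_ci_upper": hr_ci_upper,
        "two_year_os": two_year_os,
    }
    hr_ok = hr_ci_upper < 1.0
    if control_median is None or experimental_median is None:
        if two_year_os is None:
            raise ValueError("two_year_os required when a median is not reached")
        ctrl_os, exp_os = two_year_os
        gain_ok = (exp_os - ctrl_os) >= 0.10  # 10 absolute percentage points
        rule = "os_rate_2yr"
    elif control_median <= 12.0:
        gain_ok = (experimental_median - control_median) >= 2.0
        rule = "median_le12"
    elif control_median <= 24.0:
        gain_ok = (experimental_median - control_median) >= 3.0
        rule = "median_12to24"
    else:
        return BenefitGrade(False, "rule undefined", "undefined", inputs)
    meaningful = bool(gain_ok and hr_ok)
    label = "grade 3 (meaningful)" if meaningful else "not meaningful"
    return BenefitGrade(meaningful, label, rule, inputs)


def predictive_value(hr_low: float, hr_high: float) -> PredictiveValue:
    """ln(HR in PD-L1<1% / HR in PD-L1>=1%); antisymmetric in its arguments."""
    if hr_low <= 0 or hr_high <= 0:
        raise ValueError("hazard ratios must be positive")
    return PredictiveValue(pv=float(np.log(hr_low / hr_high)),
                           hr_low=float(hr_low), hr_high=float(hr_high))
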