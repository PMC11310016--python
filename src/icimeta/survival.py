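"""One-stage pooled survival analysis: KM, log-rank, Cox and frailty models.

The marginal Cox model uses a partial-likelihood fit (Efron ties) with
standard errors robust to within-trial clustering.  Between-study
heterogeneity is handled by a gamma shared-frailty Cox model: a mean-1
gamma-distributed multiplicative random effect with variance theta is shared
by all patients of a trial.  The frailty model is fitted by EM — the E-step
computes the posterior frailty means, the M-step refits the partial
likelihood with log-frailty offsets — inside an outer profile maximization
of the marginal likelihood over theta.

Subgroup analyses fit a per-level marginal Cox HR and test for a subgroup
difference with Cochran's Q on the level log-HRs (inverse-variance weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import optimize, special, stats

from .data_model import TrialRecord, registry_frame

__all__ = [
    "KMCurveEstimate",
    "HRResult",
    "SubgroupTable",
    "km_estimate",
    "logrank_test",
    "cox_marginal",
    "cox_shared_frailty",
    "subgroup_analysis",
    "build_covariates",
]

SUBGROUP_FACTORS = (
    "cancer_type", "drug_class", "regimen", "control_type",
    "assay_clone", "scoring_method",
)
DEFAULT_ADJUSTMENT = ("cancer_type", "drug_class", "control_type")


# ---------------------------------------------------------------------------
# Kaplan–Meier

@dataclass
class KMCurveEstimate:
    """Product-limit estimate with Greenwood variance and log–log CIs."""

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    median: float | None
    n: int
    n_events: int

    def survival_at(self, t: float, alpha: float = 0.05) -> tuple[float, float, float]:
        """S(t) with a log–log transformed Greenwood confidence interval."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0, 1.0, 1.0
        s = float(self.survival[idx])
        v = float(self.variance[idx])
        if s <= 0.0 or s >= 1.0 or v <= 0.0:
            return s, s, s
        z = stats.norm.ppf(1 - alpha / 2)
        # variance of log(-log S) by the delta method
        se_cloglog = np.sqrt(v) / abs(s * np.log(s))
        lo = s ** np.exp(z * se_cloglog)
        hi = s ** np.exp(-z * se_cloglog)
        return s, float(lo), float(hi)


def km_estimate(observations: pd.DataFrame) -> KMCurveEstimate:
    """Kaplan–Meier estimate of one cohort (any arm mix the caller chose)."""
    if observations.empty:
        raise ValueError("need at least one observation")
    t = observations["time_months"].to_numpy(dtype=float)
    e = observations["event"].to_numpy(dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    tab = kmf.event_table
    d = tab["observed"].to_numpy(dtype=float)
    n_at = tab["at_risk"].to_numpy(dtype=float)
    times = tab.index.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where((n_at > 0) & (n_at > d), d / (n_at * (n_at - d)), np.where(d > 0, np.inf, 0.0))
    surv = kmf.survival_function_.iloc[:, 0].reindex(tab.index).to_numpy()
    var = surv**2 * np.cumsum(inc)
    var = np.where(np.isfinite(var), var, 0.0)
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KMCurveEstimate(times=times, survival=surv, variance=var,
                           median=median, n=len(t), n_events=int(e.sum()))


def logrank_test(observations: pd.DataFrame) -> tuple[float, float]:
    """Two-sample log-rank chi-square (1 df) between experimental and control."""
    a = observations[observations["arm"] == "experimental"]
    b = observations[observations["arm"] == "control"]
    if a.empty or b.empty:
        raise ValueError("log-rank test needs both arms non-empty")
    if a["event"].sum() + b["event"].sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = _ll_logrank(
        a["time_months"], b["time_months"],
        event_observed_A=a["event"], event_observed_B=b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox models

@dataclass
class HRResult:
    """Treatment hazard ratio with CI, p, and model provenance."""

    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str
    adjusted_for: tuple[str, ...] = ()
    theta: float | None = None
    n: int = 0
    n_events: int = 0
    se_log_hr: float = float("nan")


def build_covariates(
    observations: pd.DataFrame,
    registry: Sequence[TrialRecord] | pd.DataFrame | None,
    covariates: Sequence[str],
) -> pd.DataFrame:
    """Dummy-code trial-level categorical covariates onto the IPD rows.

    Reference level per factor = most frequent category among analyzed rows
    (deterministic; ties broken alphabetically).
    """
    if not covariates:
        return pd.DataFrame(index=observations.index)
    if registry is None:
        raise ValueError("covariate adjustment requires a registry")
    reg = registry if isinstance(registry, pd.DataFrame) else registry_frame(registry)
    cols = []
    for cov in covariates:
        if cov not in reg.columns:
            raise ValueError(f"unknown covariate {cov!r}")
        vals = observations["trial_id"].map(reg[cov])
        if vals.isna().any():
            missing = observations.loc[vals.isna(), "trial_id"].unique()
            raise ValueError(f"trials missing from registry: {list(missing)[:5]}")
        counts = vals.value_counts()
        ref = sorted(counts.index[counts == counts.max()])[0]
        for level in sorted(set(vals)):
            if level == ref:
                continue
            cols.append(pd.Series(
                (vals == level).astype(float), name=f"{cov}[{level}]"
            ))
    return pd.concat(cols, axis=1) if cols else pd.DataFrame(index=observations.index)


def _prep_design(observations, registry, covariates):
    df = pd.DataFrame({
        "time": observations["time_months"].to_numpy(dtype=float),
        "event": observations["event"].to_numpy(dtype=int),
        "treat": (observations["arm"] == "experimental").astype(float).to_numpy(),
    }, index=observations.index)
    X = build_covariates(observations, registry, covariates)
    return pd.concat([df, X], axis=1), list(X.columns)


def cox_marginal(
    observations: pd.DataFrame,
    registry: Sequence[TrialRecord] | pd.DataFrame | None = None,
    covariates: Sequence[str] = (),
    cluster: str | None = "trial_id",
) -> HRResult:
    """Marginal Cox HR for treatment, cluster-robust over trials.

    Ties handled by the Efron approximation; standard errors use the
    clustered sandwich estimator whenever more than one trial is present.
    """
    df, cov_names = _prep_design(observations, registry, covariates)
    use_cluster = (
        cluster is not None
        and cluster in observations.columns
        and observations[cluster].nunique() > 1
    )
    if use_cluster:
        df["_cluster"] = observations[cluster].to_numpy()
    cph = CoxPHFitter()
    try:
        cph.fit(
            df, duration_col="time", event_col="event",
            cluster_col="_cluster" if use_cluster else None,
            robust=use_cluster,
        )
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise RuntimeError(f"marginal Cox fit did not converge: {exc}") from exc
    beta = float(cph.params_["treat"])
    se = float(cph.standard_errors_["treat"])
    z = stats.norm.ppf(0.975)
    p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else float("nan")
    return HRResult(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_value=p,
        model="marginal_cox",
        adjusted_for=tuple(cov_names),
        n=len(df),
        n_events=int(df["event"].sum()),
        se_log_hr=se,
    )


# --- partial-likelihood machinery (Efron ties, offsets) for the frailty EM

def _cox_loglik(beta, X, time, event, offset):
    """Efron partial log-likelihood with gradient and Hessian.

    Rows must be sorted by ascending time.  Returns (loglik, grad, hess).
    """
    n, p = X.shape
    eta = X @ beta + offset
    eta = eta - eta.max()  # overflow guard; the shift cancels between the
    w = np.exp(eta)        # numerator and the log-denominator terms below
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    # suffix sums: risk set of time t = rows with time >= t
    R0 = np.cumsum(w[::-1])[::-1]
    R1 = np.cumsum(wx[::-1], axis=0)[::-1]
    R2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ev_idx = np.flatnonzero(event == 1)
    t_ev = time[ev_idx]  # sorted, since rows are sorted by time
    uniq, inv, counts = np.unique(t_ev, return_inverse=True, return_counts=True)
    firsts = np.searchsorted(time, uniq, side="left")
    m, g = len(ev_idx), len(uniq)
    # tie-group sums (groups are contiguous: events sorted by time) and the
    # Efron fraction l/d per event within its tie group
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    T0 = np.add.reduceat(w[ev_idx], starts)
    T1 = np.add.reduceat(wx[ev_idx], starts, axis=0)
    T2 = np.add.reduceat(wxx[ev_idx], starts, axis=0)
    f = (np.arange(m) - starts[inv]) / counts[inv]

    den0 = R0[firsts][inv] - f * T0[inv]
    den1 = R1[firsts][inv] - f[:, None] * T1[inv]
    den2 = R2[firsts][inv] - f[:, None, None] * T2[inv]
    loglik = float(eta[ev_idx].sum() - np.log(den0).sum())
    grad = X[ev_idx].sum(axis=0) - (den1 / den0[:, None]).sum(axis=0)
    hess = -(
        (den2 / den0[:, None, None]).sum(axis=0)
        - np.einsum("ij,ik,i->jk", den1, den1, 1.0 / den0**2)
    )
    return loglik, grad, hess


def _cox_newton(X, time, event, offset, beta0=None, max_iter=50, tol=1e-9):
    """Newton–Raphson maximization of the Efron partial likelihood."""
    order = np.argsort(time, kind="stable")
    Xs, ts, es, offs = X[order], time[order], event[order], offset[order]
    p = X.shape[1]
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    ll, g, H = _cox_loglik(beta, Xs, ts, es, offs)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-H, g, rcond=None)[0]
        if np.max(np.abs(step)) > 10:  # monotone-likelihood guard
            step = step * (10 / np.max(np.abs(step)))
        new = beta + step
        ll_new, g_new, H_new = _cox_loglik(new, Xs, ts, es, offs)
        halvings = 0
        while ll_new < ll - 1e-12 and halvings < 20:
            step /= 2
            new = beta + step
            ll_new, g_new, H_new = _cox_loglik(new, Xs, ts, es, offs)
            halvings += 1
        delta = np.max(np.abs(new - beta))
        beta, ll, g, H = new, ll_new, g_new, H_new
        if delta < tol:
            break
    else:
        if np.max(np.abs(g)) > 1e-3:
            raise RuntimeError("Cox partial likelihood did not converge "
                               "(possible monotone likelihood)")
    cov = np.linalg.pinv(-H)
    return beta, cov, ll


def _breslow_cumhaz(beta, X, time, event, offset):
    """Breslow baseline hazard increments and per-subject cumulative hazard.

    Returns (event times, dH0, H0 evaluated at each subject's time),
    in the original row order.
    """
    order = np.argsort(time, kind="stable")
    Xs, ts, es, offs = X[order], time[order], event[order], offset[order]
    w = np.exp(Xs @ beta + offs)
    R0 = np.cumsum(w[::-1])[::-1]
    ev_t = ts[es == 1]
    uniq, counts = np.unique(ev_t, return_counts=True)
    firsts = np.searchsorted(ts, uniq, side="left")
    dH0 = counts / R0[firsts]
    cumH0 = np.cumsum(dH0)
    idx = np.searchsorted(uniq, time, side="right")
    H0_at = np.where(idx > 0, cumH0[np.maximum(idx - 1, 0)], 0.0)
    return uniq, dH0, H0_at


def cox_shared_frailty(
    observations: pd.DataFrame,
    registry: Sequence[TrialRecord] | pd.DataFrame | None = None,
    covariates: Sequence[str] = (),
    cluster: str = "trial_id",
    theta_bounds: tuple[float, float] = (1e-4, 5.0),
    theta: float | None = None,
) -> HRResult:
    """Gamma shared-frailty Cox model with trial-level random effects.

    The frailty variance theta is estimated by profile marginal likelihood
    (fixable via ``theta`` for diagnostics).  The treatment HR is adjusted
    for the supplied registry covariates.  Raises for a single trial, where
    theta is unidentifiable.
    """
    groups = observations[cluster].to_numpy()
    uniq_groups, g_idx = np.unique(groups, return_inverse=True)
    if theta is None and len(uniq_groups) < 2:
        raise ValueError("shared-frailty model needs >= 2 trials "
                         "(frailty variance unidentifiable)")
    df, cov_names = _prep_design(observations, registry, covariates)
    X = df[["treat", *cov_names]].to_numpy(dtype=float)
    time = df["time"].to_numpy()
    event = df["event"].to_numpy(dtype=int)
    if len(np.unique(time[event == 1])) < 2:
        raise ValueError("need >= 2 distinct event times")
    D = np.bincount(g_idx, weights=event.astype(float))

    warm: dict = {"beta": None, "logw": np.zeros(len(uniq_groups))}

    def em_fit(th: float):
        a = 1.0 / th
        logw = warm["logw"].copy()
        beta = warm["beta"]
        cov = None
        for _ in range(50):
            offset = logw[g_idx]
            beta, cov, _ = _cox_newton(X, time, event, offset, beta0=beta)
            _, dH0, H0_at = _breslow_cumhaz(beta, X, time, event, offset)
            lam = H0_at * np.exp(X @ beta)  # frailty excluded
            Lam = np.bincount(g_idx, weights=lam)
            new_logw = np.log((a + D) / (a + Lam))
            if np.max(np.abs(new_logw - logw)) < 1e-6:
                logw = new_logw
                break
            logw = new_logw
        warm["beta"], warm["logw"] = beta.copy(), logw.copy()
        # marginal log-likelihood under the profile baseline
        offset = logw[g_idx]
        uniq_t, dH0, H0_at = _breslow_cumhaz(beta, X, time, event, offset)
        lam = H0_at * np.exp(X @ beta)
        Lam = np.bincount(g_idx, weights=lam)
        lmarg = float(np.sum(
            a * np.log(a) - special.gammaln(a)
            + special.gammaln(a + D) - (a + D) * np.log(a + Lam)
        ))
        ev_t = time[event == 1]
        idx = np.searchsorted(uniq_t, ev_t)
        lmarg += float(np.sum(np.log(dH0[idx])) + np.sum((X @ beta)[event == 1]))
        return beta, cov, lmarg

    if theta is not None:
        th_hat = max(float(theta), theta_bounds[0])
        beta, cov, _ = em_fit(th_hat)
        if theta < theta_bounds[0]:
            th_hat = float(theta)
    else:
        res = optimize.minimize_scalar(
            lambda lt: -em_fit(float(np.exp(lt)))[2],
            bounds=(np.log(theta_bounds[0]), np.log(theta_bounds[1])),
            method="bounded",
            options={"xatol": 1e-3},
        )
        th_hat = float(np.exp(res.x))
        beta, cov, _ = em_fit(th_hat)
        if th_hat <= theta_bounds[0] * 1.5:
            th_hat = 0.0
    se = float(np.sqrt(cov[0, 0]))
    b = float(beta[0])
    z = stats.norm.ppf(0.975)
    return HRResult(
        hr=float(np.exp(b)),
        ci_low=float(np.exp(b - z * se)),
        ci_high=float(np.exp(b + z * se)),
        p_value=float(2 * stats.norm.sf(abs(b / se))) if se > 0 else float("nan"),
        model="shared_frailty_cox",
        adjusted_for=tuple(cov_names),
        theta=th_hat,
        n=len(df),
        n_events=int(event.sum()),
        se_log_hr=se,
    )


# ---------------------------------------------------------------------------
# subgroup analysis

@dataclass
class SubgroupTable:
    """Per-level HRs for one trial-level factor plus Cochran's Q difference test."""

    factor: str
    levels: dict[str, HRResult | None]
    q_statistic: float | None
    p_difference: float | None
    flags: list[str] = field(default_factory=list)


def subgroup_analysis(
    observations: pd.DataFrame,
    registry: Sequence[TrialRecord] | pd.DataFrame,
    factor: str,
) -> SubgroupTable:
    """Marginal Cox HR per factor level with a Q test for subgroup difference."""
    if factor not in SUBGROUP_FACTORS:
        raise ValueError(f"factor must be one of {SUBGROUP_FACTORS}")
    reg = registry if isinstance(registry, pd.DataFrame) else registry_frame(registry)
    level_of = observations["trial_id"].map(reg[factor])
    if level_of.isna().any():
        raise ValueError("every trial must map to exactly one factor level")
    levels: dict[str, HRResult | None] = {}
    flags: list[str] = []
    betas, ses = [], []
    for level in sorted(level_of.unique()):
        sub = observations[level_of == level]
        if sub["event"].sum() == 0 or sub["arm"].nunique() < 2:
            levels[level] = None
            flags.append(f"{level}: inestimable (no events or single arm), excluded from Q")
            continue
        try:
            res = cox_marginal(sub)
        except RuntimeError:
            levels[level] = None
            flags.append(f"{level}: Cox fit failed, excluded from Q")
            continue
        levels[level] = res
        betas.append(np.log(res.hr))
        ses.append(res.se_log_hr)
    if len(betas) >= 2:
        w = 1.0 / np.asarray(ses) ** 2
        b = np.asarray(betas)
        bbar = np.sum(w * b) / np.sum(w)
        q = float(np.sum(w * (b - bbar) ** 2))
        p = float(stats.chi2.sf(q, len(betas) - 1))
    else:
        q, p = None, None
        flags.append("fewer than 2 estimable levels: difference test omitted")
    return SubgroupTable(factor=factor, levels=levels, q_statistic=q,
                         p_difference=p, flags=flags)
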