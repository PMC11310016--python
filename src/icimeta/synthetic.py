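"""Synthetic multi-trial survival data with known ground truth.

Emulates the kind of randomized-trial evidence base the pipeline analyzes:
two-arm trials with piecewise-exponential hazards, a latent PD-L1 < 1% /
PD-L1 >= 1% subgroup mixture, a mean-1 gamma per-trial frailty shared by both
arms, uniform accrual with administrative censoring, exponential dropout,
and an optional delayed treatment effect (the experimental hazard equals the
control hazard before the onset time, reproducing the late curve separation
characteristic of checkpoint-inhibitor trials).

:func:`render_km` degrades simulated IPD into published-figure-style
digitized curve coordinates and number-at-risk tables, so that the curve
reconstruction stage can be exercised end-to-end without any external
digitization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (
    ARMS,
    DigitizedCurve,
    RiskTable,
    TrialRecord,
    validate_ipd,
)
from .utils import pav_nonincreasing

__all__ = [
    "HazardSpec",
    "TrialSimSpec",
    "ProgramData",
    "simulate_trial",
    "simulate_program",
    "render_km",
    "render_program",
]

_SUBGROUPS_SIM = ("pdl1_lt1", "pdl1_ge1")


@dataclass(frozen=True)
class HazardSpec:
    """Piecewise-constant hazards per (arm, subgroup) cell.

    ``segment_bounds`` are ascending segment start times beginning at 0
    (the last segment is open-ended); ``rates`` maps ``(arm, subgroup)`` to
    a per-segment vector of hazards in events per patient-month.
    """

    segment_bounds: tuple[float, ...]
    rates: dict[tuple[str, str], tuple[float, ...]]

    def __post_init__(self) -> None:
        b = np.asarray(self.segment_bounds, dtype=float)
        if len(b) == 0 or b[0] != 0 or np.any(np.diff(b) <= 0):
            raise ValueError("segment_bounds must increase strictly from 0")
        for key, r in self.rates.items():
            r = np.asarray(r, dtype=float)
            if len(r) != len(b):
                raise ValueError(f"{key}: need one rate per segment")
            if np.any(r < 0):
                raise ValueError(f"{key}: rates must be >= 0")

    @classmethod
    def exponential(
        cls,
        control_rate: float,
        hr_lt1: float,
        hr_ge1: float | None = None,
        control_rate_ge1: float | None = None,
    ) -> "HazardSpec":
        """Single-segment (exponential) hazards from a control rate and HRs."""
        hr_ge1 = hr_lt1 if hr_ge1 is None else hr_ge1
        c_ge1 = control_rate if control_rate_ge1 is None else control_rate_ge1
        return cls(
            segment_bounds=(0.0,),
            rates={
                ("control", "pdl1_lt1"): (control_rate,),
                ("experimental", "pdl1_lt1"): (control_rate * hr_lt1,),
                ("control", "pdl1_ge1"): (c_ge1,),
                ("experimental", "pdl1_ge1"): (c_ge1 * hr_ge1,),
            },
        )

    def cell_rates(self, arm: str, subgroup: str) -> np.ndarray:
        return np.asarray(self.rates[(arm, subgroup)], dtype=float)


@dataclass(frozen=True)
class TrialSimSpec:
    """Design of one simulated randomized trial.

    Defaults emulate a mid-size first-line trial: 300 patients per arm,
    ~40% of patients in the PD-L1 < 1% stratum (the evidence base averages
    39.6%), 18 months of accrual, database lock 36 months after start, and
    a small non-informative dropout hazard.
    """

    trial_id: str = "trial-1"
    n_per_arm: int = 300
    subgroup_fraction: float = 0.4
    hazard: HazardSpec = field(
        default_factory=lambda: HazardSpec.exponential(np.log(2) / 12.0, 0.8)
    )
    frailty_variance: float = 0.0
    accrual_months: float = 18.0
    admin_censor_month: float = 36.0
    dropout_rate: float = 0.002
    delayed_effect_month: float = 0.0
    endpoint: str = "OS"
    cancer_type: str = "NSCLC"
    regimen: str = "combination"
    drug_class: str = "anti-PD-1"
    control_type: str = "chemo"
    assay_clone: str = "22C3"
    scoring_method: str = "TPS"

    def __post_init__(self) -> None:
        if not 0.0 <= self.subgroup_fraction <= 1.0:
            raise ValueError("subgroup_fraction must be in [0, 1]")
        if self.admin_censor_month <= 0:
            raise ValueError("admin_censor_month must be > 0")
        if self.n_per_arm <= 0:
            raise ValueError("n_per_arm must be positive")
        if min(self.accrual_months, self.dropout_rate, self.delayed_effect_month) < 0:
            raise ValueError("accrual, dropout and delay must be >= 0")


@dataclass
class ProgramData:
    """Output of :func:`simulate_program`: registry, pooled IPD, frailties."""

    registry: list[TrialRecord]
    ipd: pd.DataFrame
    frailties: dict[str, float]


def _piecewise_times(rng, bounds: np.ndarray, rates: np.ndarray, n: int) -> np.ndarray:
    """Inverse-CDF sampling of piecewise-exponential event times.

    Draws E ~ Exp(1) and inverts the piecewise-linear cumulative hazard;
    draws beyond the total hazard mass map to +inf (no event).
    """
    widths = np.diff(np.append(bounds, np.inf))
    cum = np.concatenate([[0.0], np.cumsum(rates[:-1] * widths[:-1])])
    e = rng.exponential(size=n)
    t = np.full(n, np.inf)
    for k in range(len(bounds)):
        lo = cum[k]
        hi = cum[k + 1] if k + 1 < len(cum) else np.inf
        in_seg = (e >= lo) & (e < hi) if np.isfinite(hi) else (e >= lo)
        if rates[k] > 0:
            t[in_seg] = bounds[k] + (e[in_seg] - lo) / rates[k]
        # rate 0: survives the segment; stays +inf unless a later segment catches it
    return t


def _effective_rates(spec: TrialSimSpec, arm: str, subgroup: str, frailty: float):
    """Segment bounds/rates for one cell after delayed effect and frailty."""
    bounds = np.asarray(spec.hazard.segment_bounds, dtype=float)
    rates = spec.hazard.cell_rates(arm, subgroup)
    if arm == "experimental" and spec.delayed_effect_month > 0:
        ctrl = spec.hazard.cell_rates("control", subgroup)
        delay = spec.delayed_effect_month
        merged = np.unique(np.concatenate([bounds, [delay]]))
        idx = np.searchsorted(bounds, merged, side="right") - 1
        new_rates = np.where(merged < delay, ctrl[idx], rates[idx])
        bounds, rates = merged, new_rates
    return bounds, rates * frailty


def simulate_trial(
    spec: TrialSimSpec, seed: int | np.random.SeedSequence, frailty: float = 1.0
) -> pd.DataFrame:
    """Simulate one two-arm trial; returns an IPD frame of 2*n_per_arm rows.

    Event times are drawn from the piecewise-exponential model by
    inverse-CDF; observed time is the minimum of the event time, exponential
    dropout, and the administrative censor (admin_censor_month minus the
    uniform accrual entry time).
    """
    max_rate = max(
        float(np.max(spec.hazard.cell_rates(a, s)))
        for a in ARMS for s in _SUBGROUPS_SIM
    )
    if (
        max_rate * frailty == 0
        and spec.dropout_rate == 0
        and not np.isfinite(spec.admin_censor_month)
    ):
        raise ValueError("no finite observation possible: zero hazards, "
                         "zero dropout, infinite administrative censor")
    rng = np.random.default_rng(seed)
    rows = []
    for arm in ARMS:
        n = spec.n_per_arm
        sub = np.where(
            rng.random(n) < spec.subgroup_fraction, "pdl1_lt1", "pdl1_ge1"
        )
        entry = (
            rng.uniform(0.0, spec.accrual_months, size=n)
            if spec.accrual_months > 0 else np.zeros(n)
        )
        admin = np.maximum(spec.admin_censor_month - entry, 0.0)
        drop = (
            rng.exponential(1.0 / spec.dropout_rate, size=n)
            if spec.dropout_rate > 0 else np.full(n, np.inf)
        )
        t_event = np.full(n, np.inf)
        for sg in _SUBGROUPS_SIM:
            mask = sub == sg
            if not mask.any():
                continue
            bounds, rates = _effective_rates(spec, arm, sg, frailty)
            t_event[mask] = _piecewise_times(rng, bounds, rates, int(mask.sum()))
        t_cens = np.minimum(admin, drop)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        rows.append(pd.DataFrame({
            "trial_id": spec.trial_id,
            "arm": arm,
            "endpoint": spec.endpoint,
            "subgroup": sub,
            "time_months": time,
            "event": event,
        }))
    return validate_ipd(pd.concat(rows, ignore_index=True))


def simulate_program(
    specs: list[TrialSimSpec], seed: int | np.random.SeedSequence
) -> ProgramData:
    """Simulate a program of trials with shared per-trial gamma frailty.

    One mean-1 gamma multiplier (variance = spec.frailty_variance) is drawn
    per trial and applied to both arms' hazards, inducing between-trial
    heterogeneity of the kind a shared-frailty analysis model targets.
    """
    if not specs:
        raise ValueError("need at least one trial spec")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    child_seeds = ss.spawn(len(specs) + 1)
    frailty_rng = np.random.default_rng(child_seeds[0])
    registry: list[TrialRecord] = []
    frames = []
    frailties: dict[str, float] = {}
    for spec, child in zip(specs, child_seeds[1:]):
        theta = spec.frailty_variance
        w = float(frailty_rng.gamma(1.0 / theta, theta)) if theta > 0 else 1.0
        frailties[spec.trial_id] = w
        ipd = simulate_trial(spec, child, frailty=w)
        frames.append(ipd)
        n_total = len(ipd)
        n_low = int((ipd["subgroup"] == "pdl1_lt1").sum())
        registry.append(TrialRecord(
            trial_id=spec.trial_id,
            cancer_type=spec.cancer_type,
            regimen=spec.regimen,
            drug_class=spec.drug_class,
            control_type=spec.control_type,
            assay_clone=spec.assay_clone,
            scoring_method=spec.scoring_method,
            n_low_pdl1=n_low,
            n_total=n_total,
            pct_printed=round(100.0 * n_low / n_total, 1),
            ipd_available=True,
        ))
    return ProgramData(registry, pd.concat(frames, ignore_index=True), frailties)


# ---------------------------------------------------------------------------
# rendering to published-figure-style inputs

def _km_step(time: np.ndarray, event: np.ndarray):
    """Exact product-limit step function; returns (drop times, S after drop)."""
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq = np.unique(t[e == 1])
    n_at = np.array([(t >= u).sum() for u in uniq], dtype=float)
    d = np.array([((t == u) & (e == 1)).sum() for u in uniq], dtype=float)
    surv = np.cumprod(1.0 - d / n_at)
    return uniq, surv


def render_km(
    observations: pd.DataFrame,
    risk_interval: float,
    coordinate_step: float = 1.0,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[DigitizedCurve, RiskTable]:
    """Render one (trial, arm, endpoint, subgroup) cohort to figure-style data.

    The curve is the exact KM step function sampled at every drop time and
    on a regular ``coordinate_step`` grid; ``jitter_sd`` adds truncated
    Gaussian digitization noise, re-projected to a monotone non-increasing
    curve in [0, 1].  The risk table holds exact at-risk counts at multiples
    of ``risk_interval``.
    """
    if risk_interval <= 0:
        raise ValueError("risk_interval must be positive")
    if observations.empty:
        raise ValueError("need at least one observation for the cell")
    for col in ("trial_id", "arm", "endpoint", "subgroup"):
        if observations[col].nunique() != 1:
            raise ValueError(f"render_km expects a single {col}; "
                             "split the frame per cell first")
    meta = observations.iloc[0]
    time = observations["time_months"].to_numpy(dtype=float)
    event = observations["event"].to_numpy(dtype=int)
    tmax = float(time.max())

    drop_t, drop_s = _km_step(time, event)
    grid = np.arange(0.0, tmax + 1e-9, coordinate_step)
    coord_t = np.unique(np.concatenate([[0.0], drop_t, grid, [tmax]]))
    coord_t = coord_t[coord_t <= tmax + 1e-9]
    # right-continuous evaluation of the step function
    idx = np.searchsorted(drop_t, coord_t, side="right")
    surv = np.concatenate([[1.0], drop_s])[idx]

    if jitter_sd > 0:
        rng = np.random.default_rng(rng)
        noisy = surv + rng.normal(0.0, jitter_sd, size=len(surv))
        noisy[0] = 1.0
        noisy = np.clip(noisy, 0.0, 1.0)
        surv = pav_nonincreasing(noisy)
        surv[0] = 1.0

    curve = DigitizedCurve(meta["trial_id"], meta["arm"], meta["endpoint"],
                           meta["subgroup"], coord_t, surv)
    risk_t = np.arange(0.0, tmax + 1e-9, risk_interval)
    n_at = np.array([(time >= rt).sum() for rt in risk_t], dtype=int)
    # published tables count patients still on study AT the timepoint
    n_at[0] = len(time)
    table = RiskTable(meta["trial_id"], meta["arm"], meta["endpoint"],
                      meta["subgroup"], risk_t, n_at)
    table.validate()
    return curve, table


def render_program(
    ipd: pd.DataFrame,
    risk_interval: float = 3.0,
    coordinate_step: float = 1.0,
    jitter_sd: float = 0.0,
    seed: int | None = None,
    by_subgroup: bool = False,
) -> tuple[list[DigitizedCurve], list[RiskTable]]:
    """Render every (trial, arm[, subgroup]) cell of a pooled IPD frame.

    With ``by_subgroup=False`` each cell pools subgroups (the "overall"
    population figure); otherwise one curve per latent subgroup is emitted.
    """
    rng = np.random.default_rng(seed)
    curves, tables = [], []
    keys = ["trial_id", "endpoint", "arm"] + (["subgroup"] if by_subgroup else [])
    for _, cell in ipd.groupby(keys, sort=True):
        if not by_subgroup:
            cell = cell.assign(subgroup="overall")
        c, r = render_km(cell, risk_interval, coordinate_step, jitter_sd, rng)
        curves.append(c)
        tables.append(r)
    return curves, tables
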