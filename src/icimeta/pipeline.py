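"""Configuration-driven orchestration of the full analysis chain.

Stages: simulate -> render -> reconstruct -> subtract -> validate -> pool ->
tvhr -> rmst -> grade -> meta.  Each stage reads only the files named in its
inputs, writes its artifacts into the output directory, and appends an
entry (inputs, parameters, seed, package version) to ``manifest.json``.
One global seed deterministically derives a per-stage substream keyed by
the stage name, so rerunning a single stage never perturbs the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    load_registry,
    read_curves,
    read_ipd,
    read_risk_tables,
    registry_frame,
    write_curves,
    write_ipd,
    write_risk_tables,
)
from .meta import compare_ipd_vs_total, eggers_test, effects_from_hr_results, pool_random_effects
from .reconstruct import reconstruct_ipd, summarize_ipd, validate_reconstruction
from .rmst import choose_truncation, grade_benefit, rmst_difference, rmst_scan
from .subtract import MatchSpec, subtract_subgroup
from .survival import cox_marginal, cox_shared_frailty, km_estimate, logrank_test, subgroup_analysis
from .synthetic import HazardSpec, TrialSimSpec, render_km, simulate_program
from .tvhr import average_hr, check_convergence, fit_piecewise_tvhr
from .utils import substream_seed

__all__ = ["PipelineConfig", "run", "STAGES"]

log = logging.getLogger("icimeta")

STAGES = ("simulate", "render", "reconstruct", "subtract", "validate",
          "pool", "tvhr", "rmst", "grade", "meta")

_ALLOWED_KEYS = {
    "seed": int,
    "out_dir": str,
    "endpoint": str,
    "covariates": list,
    "simulate": {
        "n_trials": int, "n_per_arm": int, "subgroup_fraction": float,
        "control_median_months": float, "hr_lt1": float, "hr_ge1": float,
        "frailty_variance": float, "accrual_months": float,
        "admin_censor_month": float, "dropout_rate": float,
        "delayed_effect_month": float,
    },
    "render": {"risk_interval": float, "coordinate_step": float, "jitter_sd": float},
    "match": {"event_mismatch_penalty": float},
    "mcmc": {"chains": int, "iterations": int, "warmup": int, "thin": int},
    "rmst": {"scan_step": float},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; round-trips through YAML/JSON."""

    seed: int = 0
    out_dir: str = "icimeta_out"
    endpoint: str = "OS"
    covariates: list = field(default_factory=lambda: ["cancer_type", "drug_class", "control_type"])
    simulate: dict = field(default_factory=dict)
    render: dict = field(default_factory=dict)
    match: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)
    rmst: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        for key, val in raw.items():
            if key not in _ALLOWED_KEYS:
                raise ValueError(f"unknown config key: {key!r}")
            spec = _ALLOWED_KEYS[key]
            if isinstance(spec, dict):
                for sub in (val or {}):
                    if sub not in spec:
                        raise ValueError(f"unknown config key: {key}.{sub}")
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _sim_specs(cfg: PipelineConfig) -> list[TrialSimSpec]:
    s = cfg.simulate
    n_trials = int(s.get("n_trials", 6))
    rate = np.log(2) / float(s.get("control_median_months", 12.0))
    return [
        TrialSimSpec(
            trial_id=f"SIM-{i + 1:02d}",
            n_per_arm=int(s.get("n_per_arm", 250)),
            subgroup_fraction=float(s.get("subgroup_fraction", 0.4)),
            hazard=HazardSpec.exponential(
                rate, float(s.get("hr_lt1", 0.8)), float(s.get("hr_ge1", 0.7))
            ),
            frailty_variance=float(s.get("frailty_variance", 0.1)),
            accrual_months=float(s.get("accrual_months", 18.0)),
            admin_censor_month=float(s.get("admin_censor_month", 36.0)),
            dropout_rate=float(s.get("dropout_rate", 0.002)),
            delayed_effect_month=float(s.get("delayed_effect_month", 0.0)),
            endpoint=cfg.endpoint,
            cancer_type=["NSCLC", "SCLC", "ESCC"][i % 3],
            drug_class=["anti-PD-1", "anti-PD-L1"][i % 2],
            control_type=["chemo", "placebo + chemo"][i % 2],
        )
        for i in range(n_trials)
    ]


class _Runner:
    def __init__(self, cfg: PipelineConfig, out_dir: Path):
        self.cfg = cfg
        self.out = out_dir
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text())
            if self.manifest_path.exists() else {}
        )

    def record(self, stage: str, inputs: list[str], outputs: list[str], params: dict):
        self.manifest[stage] = {
            "inputs": inputs,
            "outputs": outputs,
            "params": params,
            "seed": self.cfg.seed,
            "stage_seed": substream_seed(self.cfg.seed, stage),
            "config_hash": self.cfg.config_hash(),
            "version": __version__,
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))

    def _dump(self, name: str, obj) -> str:
        path = self.out / name
        path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonable))
        return name

    # -- stages ------------------------------------------------------------

    def simulate(self):
        specs = _sim_specs(self.cfg)
        prog = simulate_program(specs, substream_seed(self.cfg.seed, "simulate"))
        pd.DataFrame([vars(r) for r in prog.registry]).to_csv(self.out / "registry.csv", index=False)
        write_ipd(prog.ipd, self.out / "ipd_truth.csv")
        self.record("simulate", [], ["registry.csv", "ipd_truth.csv"],
                    {"n_trials": len(specs), "frailties": prog.frailties})
        log.info("simulate: %d trials, %d patients", len(specs), len(prog.ipd))

    def render(self):
        ipd = read_ipd(self.out / "ipd_truth.csv")
        r = self.cfg.render
        curves, tables = [], []
        rng = np.random.default_rng(substream_seed(self.cfg.seed, "render"))
        for _, cell in ipd.groupby(["trial_id", "endpoint", "arm"], sort=True):
            c, t = render_km(cell.assign(subgroup="overall"),
                             float(r.get("risk_interval", 3.0)),
                             float(r.get("coordinate_step", 1.0)),
                             float(r.get("jitter_sd", 0.0)), rng)
            curves.append(c)
            tables.append(t)
            known = cell[cell["subgroup"] == "pdl1_ge1"]
            if not known.empty:
                c, t = render_km(known, float(r.get("risk_interval", 3.0)),
                                 float(r.get("coordinate_step", 1.0)),
                                 float(r.get("jitter_sd", 0.0)), rng)
                curves.append(c)
                tables.append(t)
        write_curves(curves, self.out / "curves.csv")
        write_risk_tables(tables, self.out / "risk.csv")
        self.record("render", ["ipd_truth.csv"], ["curves.csv", "risk.csv"], dict(r))
        log.info("render: %d curves", len(curves))

    def reconstruct(self):
        curves = read_curves(self.out / "curves.csv")
        tables = {(t.trial_id, t.arm, t.endpoint, t.subgroup): t
                  for t in read_risk_tables(self.out / "risk.csv")}
        frames = []
        diags = {}
        for c in curves:
            key = (c.trial_id, c.arm, c.endpoint, c.subgroup)
            res = reconstruct_ipd(c, tables[key])
            frames.append(res.observations)
            diags["/".join(key)] = {
                "n_events": res.n_events_assigned,
                "n_censored": res.n_censored_assigned,
                "max_at_risk_deviation": res.max_at_risk_deviation,
                "flags": res.flags,
            }
        rec = pd.concat(frames, ignore_index=True)
        write_ipd(rec, self.out / "ipd_reconstructed.csv")
        out = [self._dump("reconstruction_diagnostics.json", diags), "ipd_reconstructed.csv"]
        self.record("reconstruct", ["curves.csv", "risk.csv"], out, {})
        log.info("reconstruct: %d rows", len(rec))

    def subtract(self):
        rec = read_ipd(self.out / "ipd_reconstructed.csv")
        spec = MatchSpec(**{k: v for k, v in self.cfg.match.items()})
        frames = []
        for trial_id, group in rec.groupby("trial_id", sort=True):
            overall = group[group["subgroup"] == "overall"]
            known = group[group["subgroup"] == "pdl1_ge1"]
            frames.append(subtract_subgroup(overall, known, spec))
        low = pd.concat(frames, ignore_index=True)
        write_ipd(low, self.out / "ipd_low_pdl1.csv")
        self.record("subtract", ["ipd_reconstructed.csv"], ["ipd_low_pdl1.csv"],
                    {"event_mismatch_penalty": spec.event_mismatch_penalty})
        log.info("subtract: %d low-PD-L1 rows", len(low))

    def validate(self):
        truth = read_ipd(self.out / "ipd_truth.csv")
        low = read_ipd(self.out / "ipd_low_pdl1.csv")
        rec_sums, ref_sums = [], []
        for trial_id in sorted(truth["trial_id"].unique()):
            ref = truth[(truth["trial_id"] == trial_id) & (truth["subgroup"] == "pdl1_lt1")]
            rec = low[low["trial_id"] == trial_id]
            if ref.empty or rec.empty:
                continue
            rec_sums.append(summarize_ipd(rec))
            ref_sums.append(summarize_ipd(ref))
        report = validate_reconstruction(rec_sums, ref_sums)
        payload = {
            "pearson": report.pearson,
            "min_pearson_r": report.min_pearson_r,
            "deviations": report.deviations,
            "flags": report.flags,
        }
        out = [self._dump("qc_report.json", payload)]
        self.record("validate", ["ipd_truth.csv", "ipd_low_pdl1.csv"], out, {})
        log.info("validate: min Pearson r = %.4f", report.min_pearson_r)

    def _low_ipd_and_registry(self):
        low = read_ipd(self.out / "ipd_low_pdl1.csv")
        reg = load_registry(self.out / "registry.csv")
        return low, registry_frame(reg)

    def pool(self):
        low, reg = self._low_ipd_and_registry()
        stat, p = logrank_test(low)
        marginal = cox_marginal(low)
        n_trials = low["trial_id"].nunique()
        frailty = (
            cox_shared_frailty(low, reg, covariates=tuple(self.cfg.covariates))
            if n_trials >= 2 else None
        )
        results = {
            "logrank": {"statistic": stat, "p": p},
            "marginal_cox": vars(marginal),
            "shared_frailty_cox": vars(frailty) if frailty else None,
        }
        subs = {}
        for factor in ("cancer_type", "drug_class", "control_type"):
            table = subgroup_analysis(low, reg, factor)
            subs[factor] = {
                "levels": {k: (vars(v) if v else None) for k, v in table.levels.items()},
                "q": table.q_statistic, "p_difference": table.p_difference,
                "flags": table.flags,
            }
            pd.DataFrame([
                {"level": k, **({"hr": v.hr, "ci_low": v.ci_low, "ci_high": v.ci_high,
                                 "p": v.p_value} if v else {})}
                for k, v in table.levels.items()
            ]).to_csv(self.out / f"subgroup_{factor}.csv", index=False)
        results["subgroups"] = subs
        out = [self._dump("pooled_results.json", results)]
        self.record("pool", ["ipd_low_pdl1.csv", "registry.csv"], out,
                    {"covariates": list(self.cfg.covariates)})
        log.info("pool: marginal HR %.3f", marginal.hr)

    def tvhr(self):
        low, reg = self._low_ipd_and_registry()
        m = self.cfg.mcmc
        fit = fit_piecewise_tvhr(
            low, reg, covariates=tuple(self.cfg.covariates),
            chains=int(m.get("chains", 4)),
            iterations=int(m.get("iterations", 1000)),
            warmup=int(m.get("warmup", 500)),
            thin=int(m.get("thin", 2)),
            seed=substream_seed(self.cfg.seed, "tvhr"),
        )
        avg, ci = average_hr(fit)
        payload = {
            "segment_bounds": fit.segment_bounds,
            "beta_mean": fit.beta_mean,
            "beta_ci": fit.beta_ci,
            "average_hr": {"estimate": avg, "ci": ci, "weighting": "event_weighted"},
            "convergence": check_convergence(fit),
            "events_per_segment": fit.events_per_segment,
            "mcmc": {"chains": fit.n_chains, "iterations": fit.n_iterations,
                     "seed": fit.seed},
        }
        out = [self._dump("tvhr_fit.json", payload)]
        self.record("tvhr", ["ipd_low_pdl1.csv", "registry.csv"], out,
                    {"chains": fit.n_chains, "iterations": fit.n_iterations})
        log.info("tvhr: average HR %.3f, rhat_max %.3f", avg, fit.rhat_max)

    def rmst(self):
        low, _ = self._low_ipd_and_registry()
        tau = choose_truncation(low, self.cfg.endpoint)
        res = rmst_difference(low, tau)
        step = float(self.cfg.rmst.get("scan_step", 1.0))
        grid = np.arange(step, tau + 1e-9, step)
        first_sig, scans = rmst_scan(low, grid)
        pd.DataFrame([{
            "tau": r.tau, "rmst_experimental": r.rmst_experimental,
            "rmst_control": r.rmst_control, "difference": r.difference,
            "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p_value,
        } for r in scans]).to_csv(self.out / "rmst_results.csv", index=False)
        payload = {"tau": tau, "difference": vars(res), "first_significant_tau": first_sig}
        out = [self._dump("rmst_summary.json", payload), "rmst_results.csv"]
        self.record("rmst", ["ipd_low_pdl1.csv"], out, {"scan_step": step})
        log.info("rmst: tau=%.1f diff=%.2f months", tau, res.difference)

    def grade(self):
        low, _ = self._low_ipd_and_registry()
        marginal = cox_marginal(low)
        med = {}
        for arm in ("experimental", "control"):
            km = km_estimate(low[low["arm"] == arm])
            med[arm] = km.median
        two_year = None
        if med["control"] is None or med["experimental"] is None:
            two_year = tuple(
                km_estimate(low[low["arm"] == a]).survival_at(24.0)[0]
                for a in ("control", "experimental")
            )
        g = grade_benefit(med["control"], med["experimental"], marginal.ci_high,
                          two_year, endpoint=self.cfg.endpoint,
                          allow_pfs=self.cfg.endpoint == "PFS")
        out = [self._dump("grades.json", {
            "meaningful": g.meaningful, "grade_label": g.grade_label,
            "rule_applied": g.rule_applied, "inputs": g.inputs,
        })]
        self.record("grade", ["ipd_low_pdl1.csv"], out, {})
        log.info("grade: %s", g.grade_label)

    def meta(self):
        low, reg = self._low_ipd_and_registry()
        per_trial = {}
        for trial_id, group in low.groupby("trial_id", sort=True):
            if group["event"].sum() > 0 and group["arm"].nunique() == 2:
                per_trial[trial_id] = cox_marginal(group, cluster=None)
        effects = effects_from_hr_results(per_trial, self.cfg.endpoint)
        pooled = pool_random_effects(effects)
        bias = eggers_test(effects) if len(effects) >= 3 else None
        ipd_flags = {t: True for t in per_trial}
        comparison = (
            compare_ipd_vs_total(effects, ipd_flags) if len(effects) >= 2 else None
        )
        if bias:
            pd.DataFrame(bias.funnel, columns=["trial_id", "log_hr", "se"]).to_csv(
                self.out / "funnel.csv", index=False)
        payload = {
            "pooled": {"hr": pooled.hr, "ci_low": pooled.ci_low,
                       "ci_high": pooled.ci_high, "tau2": pooled.tau2,
                       "q": pooled.q_statistic, "q_p": pooled.q_p_value},
            "egger": ({"intercept": bias.intercept, "ci": [bias.ci_low, bias.ci_high],
                       "p": bias.p_value} if bias else None),
            "ipd_vs_total": comparison,
        }
        out = [self._dump("meta_results.json", payload), "funnel.csv"]
        self.record("meta", ["ipd_low_pdl1.csv"], out, {})
        log.info("meta: pooled HR %.3f", pooled.hr)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    return str(obj)


def run(command: str, config: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Run one pipeline stage (or ``all``); returns the output directory."""
    if command != "all" and command not in STAGES:
        raise ValueError(f"unknown command {command!r}; choose from {STAGES + ('all',)}")
    out = Path(out_dir) if out_dir is not None else Path(config.out_dir)
    runner = _Runner(config, out)
    stages = STAGES if command == "all" else (command,)
    for stage in stages:
        getattr(runner, stage)()
    return out
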