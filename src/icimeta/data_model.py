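"""Domain types and CSV readers/writers for the trial-level meta-analysis pipeline.

The package works with five tabular interchange schemas, all plain
comma-separated UTF-8 with a mandatory header row:

* ``registry.csv`` — one row per randomized trial (Table-1-style metadata).
* ``ipd.csv`` — reconstructed or simulated individual patient data, one row
  per patient: ``trial_id, arm, endpoint, subgroup, time_months, event``.
* ``curves.csv`` — digitized Kaplan–Meier coordinates.
* ``risk.csv`` — number-at-risk tables.
* ``effects.csv`` — aggregate per-trial hazard ratios with 95% CIs.

Individual patient data are carried as :class:`pandas.DataFrame` objects
with the ``ipd.csv`` column schema (the canonical container downstream);
:func:`validate_ipd` enforces the row invariants.  Time is in months
throughout; :func:`months_to_years` / :func:`years_to_months` convert
explicitly, never implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANCER_TYPES",
    "ASSAY_CLONES",
    "SCORING_METHODS",
    "ARMS",
    "ENDPOINTS",
    "SUBGROUPS",
    "TrialRecord",
    "DigitizedCurve",
    "RiskTable",
    "AggregateEffect",
    "IPD_COLUMNS",
    "load_registry",
    "bundled_registry_path",
    "registry_frame",
    "read_ipd",
    "write_ipd",
    "validate_ipd",
    "read_curves",
    "write_curves",
    "read_risk_tables",
    "write_risk_tables",
    "read_effects",
    "write_effects",
    "months_to_years",
    "years_to_months",
]

CANCER_TYPES = (
    "NSCLC", "SCLC", "ESCC", "GC", "RCC", "TNBC", "OC",
    "HCC", "UC", "HNSCC", "MPM", "NPC", "melanoma",
)
REGIMENS = ("mono", "combination")
DRUG_CLASSES = ("anti-PD-1", "anti-PD-L1")
ASSAY_CLONES = ("22C3", "28-8", "SP142", "SP263", "JS311")
SCORING_METHODS = ("TPS", "IPS", "TPS&IPS", "CPS")
ARMS = ("experimental", "control")
ENDPOINTS = ("OS", "PFS")
SUBGROUPS = ("pdl1_lt1", "pdl1_ge1", "overall")

IPD_COLUMNS = ["trial_id", "arm", "endpoint", "subgroup", "time_months", "event"]


class SchemaError(ValueError):
    """A CSV row or table violates the documented schema or an invariant."""


@dataclass(frozen=True)
class TrialRecord:
    """One registry row: trial metadata plus low-PD-L1 subgroup counts.

    ``pct_printed`` stores the percentage as published; computed
    percentages always derive from ``n_low_pdl1 / n_total`` (counts are the
    primary data, the printed column is retained but unused in computation).
    """

    trial_id: str
    cancer_type: str
    regimen: str
    drug_class: str
    control_type: str
    assay_clone: str
    scoring_method: str
    n_low_pdl1: int
    n_total: int
    pct_printed: float | None = None
    ipd_available: bool = False

    def __post_init__(self) -> None:
        if self.cancer_type not in CANCER_TYPES:
            raise SchemaError(f"unknown cancer_type {self.cancer_type!r}")
        if self.regimen not in REGIMENS:
            raise SchemaError(f"unknown regimen {self.regimen!r}")
        if self.drug_class not in DRUG_CLASSES:
            raise SchemaError(f"unknown drug_class {self.drug_class!r}")
        if self.assay_clone not in ASSAY_CLONES:
            raise SchemaError(f"unknown assay_clone {self.assay_clone!r}")
        if self.scoring_method not in SCORING_METHODS:
            raise SchemaError(f"unknown scoring_method {self.scoring_method!r}")
        if self.n_total <= 0:
            raise SchemaError(f"{self.trial_id}: n_total must be positive")
        if not 0 <= self.n_low_pdl1 <= self.n_total:
            raise SchemaError(
                f"{self.trial_id}: n_low_pdl1 ({self.n_low_pdl1}) outside "
                f"[0, n_total={self.n_total}]"
            )

    @property
    def pct_low_pdl1(self) -> float:
        """Low-PD-L1 share in percent, computed from counts."""
        return 100.0 * self.n_low_pdl1 / self.n_total


@dataclass
class DigitizedCurve:
    """Published-figure-style KM curve coordinates for one (trial, arm) cell.

    Invariants (after :func:`icimeta.reconstruct.preprocess_curve`): times
    strictly increasing, survival within [0, 1] and non-increasing, first
    point (0, 1.0).
    """

    trial_id: str
    arm: str
    endpoint: str
    subgroup: str
    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.shape != self.survival.shape:
            raise SchemaError("times and survival must have equal length")

    def validate(self) -> None:
        if len(self.times) < 2:
            raise SchemaError("curve needs at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise SchemaError("curve times must be strictly increasing")
        if self.times[0] != 0 or self.survival[0] != 1.0:
            raise SchemaError("curve must start at (0, 1.0)")
        if np.any(self.survival < 0) or np.any(self.survival > 1):
            raise SchemaError("survival must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise SchemaError("survival must be non-increasing")


@dataclass
class RiskTable:
    """Number-at-risk table for one (trial, arm) cell."""

    trial_id: str
    arm: str
    endpoint: str
    subgroup: str
    times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=int)
        if self.times.shape != self.n_at_risk.shape:
            raise SchemaError("times and n_at_risk must have equal length")

    def validate(self) -> None:
        if len(self.times) == 0 or self.times[0] != 0:
            raise SchemaError("risk table must start at time 0")
        if np.any(np.diff(self.times) <= 0):
            raise SchemaError("risk-table times must be strictly increasing")
        if np.any(np.diff(self.n_at_risk) > 0):
            raise SchemaError("n_at_risk must be non-increasing")
        if np.any(self.n_at_risk < 0):
            raise SchemaError("n_at_risk must be non-negative")


@dataclass(frozen=True)
class AggregateEffect:
    """Published per-trial hazard ratio with 95% CI, for two-stage pooling."""

    trial_id: str
    endpoint: str
    hr: float
    ci_low: float
    ci_high: float
    weight_n: int | None = None

    def __post_init__(self) -> None:
        if not (self.hr > 0 and self.ci_low > 0 and self.ci_high > 0):
            raise SchemaError(f"{self.trial_id}: HR and CI must be positive")
        if not self.ci_low <= self.hr <= self.ci_high:
            raise SchemaError(
                f"{self.trial_id}: require ci_low <= hr <= ci_high, got "
                f"({self.ci_low}, {self.hr}, {self.ci_high})"
            )


# ---------------------------------------------------------------------------
# registry I/O

_REGISTRY_COLUMNS = [
    "trial_id", "cancer_type", "regimen", "drug_class", "control_type",
    "assay_clone", "scoring_method", "n_low_pdl1", "n_total",
    "pct_printed", "ipd_available",
]


def bundled_registry_path() -> Path:
    """Path of the packaged trial-registry fixture (49 phase-3 RCTs)."""
    return Path(str(resources.files("icimeta").joinpath("data/table1.csv")))


def load_registry(path: str | Path | None = None) -> list[TrialRecord]:
    """Load a trial registry CSV into validated :class:`TrialRecord` rows.

    With no ``path``, loads the bundled registry of the 49 first-line
    checkpoint-inhibitor phase-3 trials.  Rows violating the schema raise
    :class:`SchemaError` naming the offending row index.
    """
    path = bundled_registry_path() if path is None else Path(path)
    df = pd.read_csv(path)
    missing = set(_REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"registry missing columns: {sorted(missing)}")
    records: list[TrialRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        try:
            n_low = int(row["n_low_pdl1"])
            n_tot = int(row["n_total"])
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"registry row {idx}: non-numeric count") from exc
        try:
            rec = TrialRecord(
                trial_id=str(row["trial_id"]),
                cancer_type=str(row["cancer_type"]),
                regimen=str(row["regimen"]),
                drug_class=str(row["drug_class"]),
                control_type=str(row["control_type"]),
                assay_clone=str(row["assay_clone"]),
                scoring_method=str(row["scoring_method"]),
                n_low_pdl1=n_low,
                n_total=n_tot,
                pct_printed=float(row["pct_printed"])
                if pd.notna(row["pct_printed"]) else None,
                ipd_available=bool(int(row["ipd_available"])),
            )
        except SchemaError as exc:
            raise SchemaError(f"registry row {idx}: {exc}") from exc
        if rec.trial_id in seen:
            raise SchemaError(f"registry row {idx}: duplicate trial_id {rec.trial_id!r}")
        seen.add(rec.trial_id)
        records.append(rec)
    return records


def registry_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Registry rows as a DataFrame indexed by trial_id (covariate lookup)."""
    df = pd.DataFrame([vars(r) for r in records])
    return df.set_index("trial_id", drop=False)


# ---------------------------------------------------------------------------
# IPD I/O

def validate_ipd(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an IPD frame against the ipd.csv schema; returns the frame.

    Raises :class:`SchemaError` naming the first offending row.
    """
    missing = set(IPD_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"IPD missing columns: {sorted(missing)}")
    t = pd.to_numeric(df["time_months"], errors="coerce")
    bad = df.index[t.isna() | ~np.isfinite(t) | (t < 0)]
    if len(bad):
        raise SchemaError(f"IPD row {bad[0]}: time_months must be finite and >= 0")
    ev = df["event"]
    bad = df.index[~ev.isin([0, 1])]
    if len(bad):
        raise SchemaError(f"IPD row {bad[0]}: event flag must be 0 or 1")
    for col, allowed in (("arm", ARMS), ("endpoint", ENDPOINTS), ("subgroup", SUBGROUPS)):
        bad = df.index[~df[col].isin(allowed)]
        if len(bad):
            raise SchemaError(f"IPD row {bad[0]}: {col} not in {allowed}")
    return df


def read_ipd(path: str | Path) -> pd.DataFrame:
    """Read and validate an ipd.csv file."""
    df = pd.read_csv(path)
    if df.empty and set(IPD_COLUMNS) <= set(df.columns):
        return df[IPD_COLUMNS]
    return validate_ipd(df)[IPD_COLUMNS]


def write_ipd(df: pd.DataFrame, path: str | Path) -> None:
    """Validate and write an IPD frame; write∘read is the identity."""
    if not df.empty:
        validate_ipd(df)
    out = df[IPD_COLUMNS] if set(IPD_COLUMNS) <= set(df.columns) else df
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# curve / risk-table / effects I/O

def write_curves(curves: Sequence[DigitizedCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, s in zip(c.times, c.survival):
            rows.append((c.trial_id, c.arm, c.endpoint, c.subgroup, t, s))
    pd.DataFrame(
        rows, columns=["trial_id", "arm", "endpoint", "subgroup", "time_months", "survival"]
    ).to_csv(path, index=False)


def read_curves(path: str | Path) -> list[DigitizedCurve]:
    df = pd.read_csv(path)
    out = []
    for key, g in df.groupby(["trial_id", "arm", "endpoint", "subgroup"], sort=False):
        g = g.sort_values("time_months")
        out.append(DigitizedCurve(*key, g["time_months"].to_numpy(),
                                  g["survival"].to_numpy()))
    return out


def write_risk_tables(tables: Sequence[RiskTable], path: str | Path) -> None:
    rows = []
    for r in tables:
        for t, n in zip(r.times, r.n_at_risk):
            rows.append((r.trial_id, r.arm, r.endpoint, r.subgroup, t, n))
    pd.DataFrame(
        rows, columns=["trial_id", "arm", "endpoint", "subgroup", "time_months", "n_at_risk"]
    ).to_csv(path, index=False)


def read_risk_tables(path: str | Path) -> list[RiskTable]:
    df = pd.read_csv(path)
    out = []
    for key, g in df.groupby(["trial_id", "arm", "endpoint", "subgroup"], sort=False):
        g = g.sort_values("time_months")
        out.append(RiskTable(*key, g["time_months"].to_numpy(),
                             g["n_at_risk"].to_numpy()))
    return out


def read_effects(path: str | Path) -> list[AggregateEffect]:
    df = pd.read_csv(path)
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(AggregateEffect(
                trial_id=str(row["trial_id"]),
                endpoint=str(row["endpoint"]),
                hr=float(row["hr"]),
                ci_low=float(row["ci_low"]),
                ci_high=float(row["ci_high"]),
                weight_n=int(row["weight_n"]) if "weight_n" in row and pd.notna(row.get("weight_n")) else None,
            ))
        except SchemaError as exc:
            raise SchemaError(f"effects row {idx}: {exc}") from exc
    return out


def write_effects(effects: Sequence[AggregateEffect], path: str | Path) -> None:
    pd.DataFrame([vars(e) for e in effects]).to_csv(path, index=False)


def months_to_years(months):
    return np.asarray(months, dtype=float) / 12.0


def years_to_months(years):
    return np.asarray(years, dtype=float) * 12.0
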