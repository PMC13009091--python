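"""Model parameter set, life tables, cohort files: schema, I/O, validation.

The parameter set collects every input of the two-phase Markov cohort model:
90-day modified Rankin Scale (mRS) outcome distributions per strategy arm,
utility weights per mRS state, recurrent-stroke and mortality parameters,
acute and long-term costs for the healthcare and societal perspectives, and
a probabilistic-sensitivity-analysis distribution spec per parameter.

Files are flat and diff-able: JSON (nested) or CSV (dotted ``key,value``
rows), a life table as ``age,qx`` CSV, and a patient-level cohort CSV.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ARMS",
    "MRS_STATES",
    "N_STATES",
    "DistributionSpec",
    "ParameterSet",
    "LifeTable",
    "CohortRecord",
    "FlowchartSummary",
    "Finding",
    "adjust_for_inflation",
    "validate_parameter_set",
    "load_parameter_set",
    "save_parameter_set",
    "load_cohort",
    "save_cohort",
    "summarize_cohort",
    "arm_of_record",
]

#: Strategy arms compared by the model.  ``etici2c3`` is the pooled
#: near-complete/complete reperfusion arm; the two ``etici2b`` arms are the
#: incomplete-reperfusion patterns, split by whether the residual occlusion
#: is technically reachable by further thrombectomy passes.
ARMS = (
    "etici2c3",
    "etici2b_accessible",
    "etici2b_non_accessible",
    "etici2c3_single_pass",
    "etici2c3_multi_pass",
)

#: Health states of the long-run Markov model: mRS 0-5 plus absorbing death.
MRS_STATES = ("mrs0", "mrs1", "mrs2", "mrs3", "mrs4", "mrs5", "dead")
N_STATES = len(MRS_STATES)
DEAD = N_STATES - 1

_ETICI_GRADES = ("0", "1", "2a", "2b", "2c", "3")
_PATTERNS = ("accessible", "non_accessible", "not_assessable", "not_applicable")

_VECTOR6 = (
    "utility",
    "mortality_hr",
    "cost_annual_care",
    "informal_care_cost",
    "return_to_work",
    "recurrent_mrs_dist",
)
_SCALAR_COSTS = ("cost_evt", "cost_ivt", "cost_acute_other", "annual_wage")


@dataclass(frozen=True)
class DistributionSpec:
    """Second-order (PSA) distribution attached to one parameter.

    Families follow the usual cost-effectiveness conventions: ``beta`` for
    quantities bounded in [0, 1], ``gamma``/``lognormal`` for non-negative
    quantities, ``dirichlet`` for probability vectors, ``fixed`` for
    parameters excluded from the PSA.  Specs are *relative*: sampling is
    moment-matched around the current point estimate, so ``params`` carries
    either ``rel_se`` (standard error as a fraction of the mean) or, for
    dirichlet, ``ess`` (effective sample size).
    """

    family: str
    params: Mapping[str, float] = field(default_factory=dict)

    _FAMILIES = ("beta", "gamma", "lognormal", "dirichlet", "fixed")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ValueError(
                f"unknown distribution family {self.family!r}; "
                f"expected one of {self._FAMILIES}"
            )
        for name, value in self.params.items():
            if value <= 0:
                raise ValueError(
                    f"distribution parameter {name}={value} must be positive"
                )


@dataclass
class ParameterSet:
    """All inputs of the cohort model, point estimates plus PSA specs.

    Vector parameters indexed by mRS state run over mRS 0..5 (death is
    handled by the model, not priced or utility-weighted).  ``mrs90_dist``
    vectors have 7 entries: mRS 0..5 and mRS 6 = dead at 90 days.
    """

    mrs90_dist: dict[str, np.ndarray]
    utility: np.ndarray
    p_recurrent_annual: float
    recurrent_mrs_dist: np.ndarray
    mortality_hr: np.ndarray
    case_fatality_recurrent: float
    cost_evt: float
    cost_ivt: float
    cost_acute_other: float
    p_ivt: dict[str, float]
    cost_annual_care: np.ndarray
    informal_care_cost: np.ndarray
    employment_rate: dict[int, float]
    return_to_work: np.ndarray
    annual_wage: float
    retirement_age: float
    start_age: float
    inflation_factor: float = 1.0
    currency_year: int = 2021
    psa_spec: dict[str, DistributionSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mrs90_dist = {
            k: np.asarray(v, dtype=float) for k, v in self.mrs90_dist.items()
        }
        for name in _VECTOR6:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.employment_rate = {int(k): float(v) for k, v in self.employment_rate.items()}

    def copy(self) -> "ParameterSet":
        new = replace(self)
        new.mrs90_dist = {k: v.copy() for k, v in self.mrs90_dist.items()}
        new.p_ivt = dict(self.p_ivt)
        new.employment_rate = dict(self.employment_rate)
        new.psa_spec = dict(self.psa_spec)
        for name in _VECTOR6:
            setattr(new, name, getattr(self, name).copy())
        return new

    def employment_rate_at(self, age: float) -> float:
        """Employment rate for ``age``, from 5-year bands; 0 at/after retirement."""
        if age >= self.retirement_age:
            return 0.0
        band = 5 * int(age // 5)
        if band in self.employment_rate:
            return self.employment_rate[band]
        lower = [b for b in self.employment_rate if b <= band]
        if not lower:
            return 0.0
        return self.employment_rate[max(lower)]

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "mrs90_dist": {k: list(map(float, v)) for k, v in self.mrs90_dist.items()},
            "p_ivt": {k: float(v) for k, v in self.p_ivt.items()},
            "employment_rate": {str(k): float(v) for k, v in self.employment_rate.items()},
            "p_recurrent_annual": float(self.p_recurrent_annual),
            "case_fatality_recurrent": float(self.case_fatality_recurrent),
            "retirement_age": float(self.retirement_age),
            "start_age": float(self.start_age),
            "inflation_factor": float(self.inflation_factor),
            "currency_year": int(self.currency_year),
            "psa_spec": {
                k: {"family": s.family, "params": dict(s.params)}
                for k, s in self.psa_spec.items()
            },
        }
        for name in _VECTOR6:
            d[name] = list(map(float, getattr(self, name)))
        for name in _SCALAR_COSTS:
            d[name] = float(getattr(self, name))
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        d = dict(d)
        required = (
            {"mrs90_dist", "p_ivt", "employment_rate", "p_recurrent_annual",
             "case_fatality_recurrent", "retirement_age", "start_age"}
            | set(_VECTOR6) | set(_SCALAR_COSTS)
        )
        missing = sorted(required - set(d))
        if missing:
            raise KeyError(f"parameter file is missing required names: {missing}")
        known = required | {"inflation_factor", "currency_year", "psa_spec"}
        unknown = sorted(set(d) - known)
        if unknown:
            raise KeyError(f"parameter file contains unknown names: {unknown}")
        psa = {
            k: DistributionSpec(v["family"], v.get("params", {}))
            for k, v in d.pop("psa_spec", {}).items()
        }
        return cls(psa_spec=psa, **d)


# -- findings ----------------------------------------------------------

@dataclass(frozen=True)
class Finding:
    """One validation finding; ``level`` is ``"error"`` or ``"warning"``."""

    level: str
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.level.upper()} [{self.field}]: {self.message}"


def _check_probability_vector(name: str, v: np.ndarray, findings: list[Finding]) -> None:
    if np.any(v < 0) or np.any(v > 1):
        findings.append(Finding("error", name, "entries outside [0, 1]"))
    elif abs(float(v.sum()) - 1.0) > 1e-9:
        findings.append(
            Finding("error", name, f"must sum to 1 (got {float(v.sum()):.12f})")
        )


def validate_parameter_set(ps: ParameterSet) -> list[Finding]:
    """Check every schema invariant; returns findings, never mutates input.

    Errors mark sets that cannot be run (range or normalization violations);
    warnings mark implausible but runnable inputs (non-monotone utilities,
    mortality hazard ratios below 1).
    """
    findings: list[Finding] = []
    for arm in ARMS:
        if arm not in ps.mrs90_dist:
            findings.append(Finding("error", f"mrs90_dist.{arm}", "missing arm"))
    for arm, v in ps.mrs90_dist.items():
        if len(v) != 7:
            findings.append(Finding("error", f"mrs90_dist.{arm}", "needs 7 entries (mRS 0-6)"))
            continue
        _check_probability_vector(f"mrs90_dist.{arm}", v, findings)
    for name in _VECTOR6:
        if len(getattr(ps, name)) != 6:
            findings.append(Finding("error", name, "needs 6 entries (mRS 0-5)"))
    _check_probability_vector("recurrent_mrs_dist", ps.recurrent_mrs_dist, findings)
    if np.any(ps.utility < 0) or np.any(ps.utility > 1):
        findings.append(Finding("error", "utility", "utilities must lie in [0, 1]"))
    elif np.any(np.diff(ps.utility) > 0):
        findings.append(
            Finding("warning", "utility", "utilities not non-increasing in mRS")
        )
    for name, value in (
        ("p_recurrent_annual", ps.p_recurrent_annual),
        ("case_fatality_recurrent", ps.case_fatality_recurrent),
    ):
        if not 0 <= value <= 1:
            findings.append(Finding("error", name, f"probability {value} outside [0, 1]"))
    for arm, p in ps.p_ivt.items():
        if not 0 <= p <= 1:
            findings.append(Finding("error", f"p_ivt.{arm}", f"probability {p} outside [0, 1]"))
    if np.any(ps.mortality_hr < 1):
        findings.append(
            Finding("warning", "mortality_hr", "hazard ratio below 1 for some state")
        )
    if np.any(ps.mortality_hr < 0):
        findings.append(Finding("error", "mortality_hr", "negative hazard ratio"))
    for name in ("cost_annual_care", "informal_care_cost", "return_to_work"):
        v = getattr(ps, name)
        bad = np.flatnonzero(v < 0)
        for i in bad:
            findings.append(Finding("error", f"{name}[{i}]", f"negative value {v[i]}"))
    if np.any(ps.return_to_work > 1):
        findings.append(Finding("error", "return_to_work", "probability above 1"))
    for name in _SCALAR_COSTS:
        if getattr(ps, name) < 0:
            findings.append(Finding("error", name, "cost must be non-negative"))
    for band, rate in ps.employment_rate.items():
        if not 0 <= rate <= 1:
            findings.append(
                Finding("error", f"employment_rate[{band}]", f"rate {rate} outside [0, 1]")
            )
    if ps.inflation_factor <= 0:
        findings.append(Finding("error", "inflation_factor", "must be positive"))
    if not ps.start_age < ps.retirement_age + 60:
        findings.append(Finding("error", "start_age", "implausible start age"))
    return findings


def adjust_for_inflation(cost: float, factor: float) -> float:
    """Index a cost to the target currency year: ``cost * factor``.

    ``factor`` is the ratio of the medical-care consumer-price index between
    the target year and the source year of the estimate.
    """
    if cost < 0:
        raise ValueError(f"cost must be non-negative, got {cost}")
    if factor <= 0:
        raise ValueError(f"inflation factor must be positive, got {factor}")
    return cost * factor


def _apply_inflation(ps: ParameterSet) -> ParameterSet:
    """Index all monetary fields at load time; resets the factor to 1."""
    f = ps.inflation_factor
    if f == 1.0:
        return ps
    for name in _SCALAR_COSTS:
        setattr(ps, name, adjust_for_inflation(getattr(ps, name), f))
    ps.cost_annual_care = ps.cost_annual_care * f
    ps.informal_care_cost = ps.informal_care_cost * f
    ps.inflation_factor = 1.0
    return ps


# -- parameter file I/O ------------------------------------------------

def _flatten(d: dict, prefix: str = "") -> Iterable[tuple[str, object]]:
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            yield from _flatten(v, key + ".")
        elif isinstance(v, list):
            for i, x in enumerate(v):
                yield f"{key}.{i}", x
        else:
            yield key, v


def _unflatten(rows: Iterable[tuple[str, object]]) -> dict:
    root: dict = {}
    for key, value in rows:
        parts = key.split(".")
        node = root
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value
    return _lists(root)


def _lists(node):
    """Turn dicts with contiguous integer keys back into lists."""
    if not isinstance(node, dict):
        return node
    node = {k: _lists(v) for k, v in node.items()}
    if node and all(k.isdigit() for k in node):
        idx = sorted(node, key=int)
        if [int(k) for k in idx] == list(range(len(idx))):
            return [node[k] for k in idx]
    return node


def save_parameter_set(ps: ParameterSet, path: str | Path, file_format: str | None = None) -> None:
    path = Path(path)
    fmt = file_format or ("csv" if path.suffix == ".csv" else "json")
    d = ps.to_dict()
    if fmt == "json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    elif fmt == "csv":
        psa = d.pop("psa_spec")
        rows = []
        for key, value in sorted(_flatten(d)):
            base = key.split(".")[0]
            parent = key.rsplit(".", 1)[0]
            spec = (psa.get(key) or psa.get(parent) or psa.get(base)
                    or {"family": "", "params": {}})
            rows.append(
                {"key": key, "value": value, "distribution": spec["family"],
                 "dist_params": json.dumps(spec["params"]) if spec["family"] else ""}
            )
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown parameter file format {fmt!r}")


def load_parameter_set(path: str | Path, file_format: str | None = None) -> ParameterSet:
    """Load, validate, and inflation-index a parameter file (JSON or CSV).

    Raises ``ValueError`` listing every validation *error* in the file;
    warnings are left to :func:`validate_parameter_set` callers.
    """
    path = Path(path)
    fmt = file_format or ("csv" if path.suffix == ".csv" else "json")
    if fmt == "json":
        d = json.loads(path.read_text())
    elif fmt == "csv":
        table = pd.read_csv(path, dtype={"key": str}, keep_default_na=False)
        d = _unflatten(
            (r.key, float(r.value) if _is_number(r.value) else r.value)
            for r in table.itertuples()
        )
        psa: dict[str, dict] = {}
        for r in table.itertuples():
            if r.distribution:
                base = r.key.split(".")[0]
                name = r.key.rsplit(".", 1)[0] if base == "mrs90_dist" else base
                psa.setdefault(name, {"family": r.distribution,
                                      "params": json.loads(r.dist_params or "{}")})
        d["psa_spec"] = psa
        d["currency_year"] = int(d.get("currency_year", 2021))
    else:
        raise ValueError(f"unknown parameter file format {fmt!r}")
    ps = ParameterSet.from_dict(d)
    errors = [f for f in validate_parameter_set(ps) if f.level == "error"]
    if errors:
        raise ValueError(
            "invalid parameter file:\n" + "\n".join(str(f) for f in errors)
        )
    return _apply_inflation(ps)


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


# -- life table --------------------------------------------------------

class LifeTable:
    """Annual death probabilities ``qx`` by integer age.

    Ages must be contiguous; the terminal age must have ``qx = 1`` so the
    lifetime horizon is guaranteed to extinguish the cohort.
    """

    def __init__(self, ages: Sequence[int], qx: Sequence[float]):
        self.ages = np.asarray(ages, dtype=int)
        self.qx_values = np.asarray(qx, dtype=float)
        if len(self.ages) != len(self.qx_values):
            raise ValueError("ages and qx must have equal length")
        if np.any(np.diff(self.ages) != 1):
            raise ValueError("life-table ages must be contiguous")
        if np.any((self.qx_values < 0) | (self.qx_values > 1)):
            raise ValueError("life-table qx outside [0, 1]")
        if self.qx_values[-1] != 1.0:
            raise ValueError("life table must be terminal-absorbing (qx = 1 at max age)")

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def qx(self, age: float) -> float:
        """Annual death probability at ``age`` (1 beyond the table's end)."""
        age = int(age)
        if age < self.min_age:
            raise ValueError(f"age {age} below life-table minimum {self.min_age}")
        if age > self.max_age:
            return 1.0
        return float(self.qx_values[age - self.min_age])

    def qx_array(self, ages: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages, dtype=int)
        if np.any(ages < self.min_age):
            raise ValueError("age below life-table minimum")
        idx = np.minimum(ages, self.max_age) - self.min_age
        return self.qx_values[idx]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages, "qx": self.qx_values}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        t = pd.read_csv(path)
        if not {"age", "qx"} <= set(t.columns):
            raise ValueError("life-table CSV needs columns: age, qx")
        return cls(t["age"].to_numpy(), t["qx"].to_numpy())


# -- cohort records ----------------------------------------------------

@dataclass(frozen=True)
class CohortRecord:
    """One trial patient: demographics, reperfusion grade, 90-day outcome."""

    patient_id: str
    age: float
    sex: str
    etici_grade: str
    pattern_class: str
    n_passes: int
    mrs90: int
    received_ivt: bool

    def validate(self) -> None:
        if self.etici_grade not in _ETICI_GRADES:
            raise ValueError(f"{self.patient_id}: unknown eTICI grade {self.etici_grade!r}")
        if self.pattern_class not in _PATTERNS:
            raise ValueError(f"{self.patient_id}: unknown pattern {self.pattern_class!r}")
        # pattern classification applies exactly to final eTICI 2b angiograms
        if (self.pattern_class != "not_applicable") != (self.etici_grade == "2b"):
            raise ValueError(
                f"{self.patient_id}: pattern_class {self.pattern_class!r} inconsistent "
                f"with eTICI grade {self.etici_grade!r}"
            )
        if not 0 <= self.mrs90 <= 6:
            raise ValueError(f"{self.patient_id}: mrs90 {self.mrs90} outside 0-6")
        if self.n_passes < 1:
            raise ValueError(f"{self.patient_id}: n_passes must be >= 1")


def arm_of_record(rec: CohortRecord) -> str | None:
    """Strategy arm a record contributes outcome data to (None = neither)."""
    if rec.etici_grade in ("2c", "3"):
        return "etici2c3_single_pass" if rec.n_passes == 1 else "etici2c3_multi_pass"
    if rec.etici_grade == "2b" and rec.pattern_class == "accessible":
        return "etici2b_accessible"
    if rec.etici_grade == "2b" and rec.pattern_class == "non_accessible":
        return "etici2b_non_accessible"
    return None


_COHORT_COLUMNS = [
    "patient_id", "age", "sex", "etici_grade", "pattern_class",
    "n_passes", "mrs90", "received_ivt",
]


def save_cohort(records: Sequence[CohortRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records], columns=_COHORT_COLUMNS).to_csv(
        path, index=False
    )


def load_cohort(path: str | Path) -> list[CohortRecord]:
    t = pd.read_csv(path, dtype={"etici_grade": str})
    missing = set(_COHORT_COLUMNS) - set(t.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    records = [
        CohortRecord(
            patient_id=str(r.patient_id), age=float(r.age), sex=str(r.sex),
            etici_grade=str(r.etici_grade), pattern_class=str(r.pattern_class),
            n_passes=int(r.n_passes), mrs90=int(r.mrs90),
            received_ivt=bool(r.received_ivt),
        )
        for r in t.itertuples()
    ]
    for rec in records:
        rec.validate()
    return records


@dataclass(frozen=True)
class FlowchartSummary:
    """Cohort accounting in trial-flowchart order.

    Enrolled patients are first stratified by final reperfusion grade; the
    incomplete (eTICI 2b) stratum is split into angiographically assessable
    and non-assessable, and the assessable ones into thrombectomy-accessible
    and non-accessible residual-occlusion patterns.
    """

    n_enrolled: int
    n_etici2c3: int
    n_etici2b: int
    n_assessable: int
    n_accessible: int
    n_non_accessible: int

    @property
    def p_etici2b(self) -> float:
        return self.n_etici2b / self.n_enrolled

    @property
    def p_assessable(self) -> float:
        return self.n_assessable / self.n_etici2b if self.n_etici2b else 0.0

    @property
    def p_accessible(self) -> float:
        return self.n_accessible / self.n_assessable if self.n_assessable else 0.0

    @property
    def p_non_accessible(self) -> float:
        return self.n_non_accessible / self.n_assessable if self.n_assessable else 0.0


def summarize_cohort(
    records: Sequence[CohortRecord],
) -> tuple[FlowchartSummary, dict[str, np.ndarray]]:
    """Flowchart counts plus per-arm empirical 90-day mRS distributions."""
    if not records:
        raise ValueError("cohort is empty")
    for rec in records:
        rec.validate()
    n2b = sum(r.etici_grade == "2b" for r in records)
    assessable = [
        r for r in records
        if r.etici_grade == "2b" and r.pattern_class != "not_assessable"
    ]
    summary = FlowchartSummary(
        n_enrolled=len(records),
        n_etici2c3=sum(r.etici_grade in ("2c", "3") for r in records),
        n_etici2b=n2b,
        n_assessable=len(assessable),
        n_accessible=sum(r.pattern_class == "accessible" for r in assessable),
        n_non_accessible=sum(r.pattern_class == "non_accessible" for r in assessable),
    )
    mrs: dict[str, np.ndarray] = {}
    for rec in records:
        arm = arm_of_record(rec)
        if arm is not None:
            mrs.setdefault(arm, np.zeros(7))[rec.mrs90] += 1
    # pooled near-complete arm combines single- and multi-pass outcomes
    pooled = sum(
        (mrs[a] for a in ("etici2c3_single_pass", "etici2c3_multi_pass") if a in mrs),
        np.zeros(7),
    )
    if pooled.sum():
        mrs["etici2c3"] = pooled
    empirical = {arm: counts / counts.sum() for arm, counts in mrs.items() if counts.sum()}
    return summary, empirical
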