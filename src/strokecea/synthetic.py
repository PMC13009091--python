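"""Synthetic trial cohorts, life tables, and parameter tables.

The generators emulate the statistical structure of the inputs the cohort
model consumes, so the whole pipeline is testable without external data:

* a patient-level cohort whose arm mix mirrors a thrombectomy trial
  flowchart (enrolled -> final eTICI 2b -> angiographically assessable ->
  accessible / non-accessible residual occlusion), with 90-day mRS outcomes
  drawn from arm-specific multinomials;
* a national-life-table stand-in built from a Gompertz mortality hazard;
* a complete model parameter table with conventional point estimates and a
  PSA distribution spec per parameter.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .parameters import (
    ARMS,
    CohortRecord,
    LifeTable,
    ParameterSet,
    validate_parameter_set,
)

__all__ = [
    "SyntheticConfig",
    "DEFAULT_PARAMETERS",
    "generate_cohort",
    "generate_life_table",
    "generate_parameter_table",
    "exact_flowchart_cohort",
]

# Arm mix of the default cohort: 45.8% pooled near-complete reperfusion
# (split 60/40 between first-pass and multi-pass), 40.7% incomplete
# (eTICI 2b) split 147:296 between accessible and non-accessible patterns,
# remainder below eTICI 2b.
_DEFAULT_ARM_PROPORTIONS = {
    "etici2c3_single_pass": 0.27477,
    "etici2c3_multi_pass": 0.18318,
    "etici2b_accessible": 450 / 1105 * 147 / 443,
    "etici2b_non_accessible": 450 / 1105 * 296 / 443,
    "other": 1.0
    - 0.27477
    - 0.18318
    - 450 / 1105 * 147 / 443
    - 450 / 1105 * 296 / 443,
}

# 90-day mRS profiles (mRS 0..5, dead). Ordered so that near-complete
# reperfusion stochastically dominates the incomplete patterns, and the
# accessible pattern (larger residual occlusions, more territorial
# infarcts) fares worst — the ordering reported for these strata.
_DEFAULT_MRS90 = {
    "etici2c3_single_pass": [0.21, 0.20, 0.15, 0.12, 0.12, 0.08, 0.12],
    "etici2c3_multi_pass": [0.19, 0.21, 0.15, 0.12, 0.12, 0.08, 0.13],
    "etici2b_accessible": [0.10, 0.14, 0.13, 0.15, 0.16, 0.12, 0.20],
    "etici2b_non_accessible": [0.15, 0.17, 0.15, 0.14, 0.14, 0.10, 0.15],
    "other": [0.05, 0.08, 0.10, 0.15, 0.20, 0.17, 0.25],
}

#: Complete default parameter table (2021 USD).  Utilities follow the
#: utility-weighted mRS convention; care and informal-care costs rise with
#: disability; acute procedure costs are the published US estimates
#: (EVT 15,510 USD; intravenous alteplase 7,421 USD).  PSA specs follow the
#: usual conventions: beta for probabilities/utilities and gamma for costs,
#: moment-matched at 20% relative standard error; Dirichlet for outcome
#: vectors with effective sample size equal to the trial stratum size.
DEFAULT_PARAMETERS: dict = {
    "mrs90_dist": {
        "etici2c3": [0.202, 0.204, 0.15, 0.12, 0.12, 0.08, 0.124],
        "etici2c3_single_pass": _DEFAULT_MRS90["etici2c3_single_pass"],
        "etici2c3_multi_pass": _DEFAULT_MRS90["etici2c3_multi_pass"],
        "etici2b_accessible": _DEFAULT_MRS90["etici2b_accessible"],
        "etici2b_non_accessible": _DEFAULT_MRS90["etici2b_non_accessible"],
    },
    "utility": [1.0, 0.91, 0.76, 0.65, 0.33, 0.0],
    "p_recurrent_annual": 0.04,
    "recurrent_mrs_dist": [0.10, 0.15, 0.17, 0.20, 0.21, 0.17],
    "mortality_hr": [1.0, 1.2, 1.5, 2.0, 2.8, 4.0],
    "case_fatality_recurrent": 0.16,
    "cost_evt": 15510.0,
    "cost_ivt": 7421.0,
    "cost_acute_other": 20000.0,
    "p_ivt": {
        "etici2c3": 0.621,
        "etici2c3_single_pass": 0.621,
        "etici2c3_multi_pass": 0.621,
        "etici2b_accessible": 0.558,
        "etici2b_non_accessible": 0.585,
    },
    "cost_annual_care": [2000.0, 4000.0, 8000.0, 15000.0, 28000.0, 45000.0],
    "informal_care_cost": [0.0, 2000.0, 5000.0, 10000.0, 18000.0, 26000.0],
    "employment_rate": {40: 0.80, 45: 0.80, 50: 0.78, 55: 0.72, 60: 0.57},
    "return_to_work": [0.85, 0.70, 0.50, 0.20, 0.05, 0.0],
    "annual_wage": 58260.0,
    "retirement_age": 65.0,
    "start_age": 70.0,
    "inflation_factor": 1.0,
    "currency_year": 2021,
    "psa_spec": {
        "mrs90_dist.etici2c3": {"family": "dirichlet", "params": {"ess": 506}},
        "mrs90_dist.etici2c3_single_pass": {"family": "dirichlet", "params": {"ess": 304}},
        "mrs90_dist.etici2c3_multi_pass": {"family": "dirichlet", "params": {"ess": 202}},
        "mrs90_dist.etici2b_accessible": {"family": "dirichlet", "params": {"ess": 147}},
        "mrs90_dist.etici2b_non_accessible": {"family": "dirichlet", "params": {"ess": 296}},
        "recurrent_mrs_dist": {"family": "dirichlet", "params": {"ess": 450}},
        "utility": {"family": "beta", "params": {"rel_se": 0.2}},
        "p_recurrent_annual": {"family": "beta", "params": {"rel_se": 0.2}},
        "case_fatality_recurrent": {"family": "beta", "params": {"rel_se": 0.2}},
        "p_ivt": {"family": "beta", "params": {"rel_se": 0.2}},
        "mortality_hr": {"family": "lognormal", "params": {"rel_se": 0.2}},
        "cost_evt": {"family": "gamma", "params": {"rel_se": 0.2}},
        "cost_ivt": {"family": "gamma", "params": {"rel_se": 0.2}},
        "cost_acute_other": {"family": "gamma", "params": {"rel_se": 0.2}},
        "cost_annual_care": {"family": "gamma", "params": {"rel_se": 0.2}},
        "informal_care_cost": {"family": "gamma", "params": {"rel_se": 0.2}},
        "annual_wage": {"family": "gamma", "params": {"rel_se": 0.2}},
        "employment_rate": {"family": "beta", "params": {"rel_se": 0.2}},
        "return_to_work": {"family": "beta", "params": {"rel_se": 0.2}},
        "retirement_age": {"family": "fixed"},
        "start_age": {"family": "fixed"},
        "inflation_factor": {"family": "fixed"},
    },
}


@dataclass
class SyntheticConfig:
    """Configuration of the cohort generator.

    ``arm_proportions`` gives the marginal probability of each strategy arm
    (the two eTICI 2b entries are *total* 2b shares); within a 2b patient
    the angiogram is assessable with probability ``assessable_fraction`` —
    non-assessable patients keep the 2b grade but lose the pattern label.
    """

    n_patients: int = 1105
    arm_proportions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ARM_PROPORTIONS)
    )
    mrs90_profiles: dict[str, Sequence[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_MRS90.items()}
    )
    age_mean_sd: tuple[float, float] = (70.7, 13.6)
    female_fraction: float = 0.488
    assessable_fraction: float = 443 / 450
    p_ivt: dict[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        _check_pvec("arm_proportions", list(self.arm_proportions.values()))
        for arm, prof in self.mrs90_profiles.items():
            if len(prof) != 7:
                raise ValueError(f"mrs90_profiles[{arm}] needs 7 entries")
            _check_pvec(f"mrs90_profiles[{arm}]", prof)
        for name, p in (
            ("female_fraction", self.female_fraction),
            ("assessable_fraction", self.assessable_fraction),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"{name}={p} outside [0, 1]")
        missing = set(self.arm_proportions) - set(self.mrs90_profiles)
        if missing:
            raise ValueError(f"mrs90_profiles missing arms: {sorted(missing)}")


def _check_pvec(name: str, v: Sequence[float]) -> None:
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError(f"{name} has negative entries")
    if abs(float(v.sum()) - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {float(v.sum()):.12f})")


def generate_cohort(config: SyntheticConfig) -> list[CohortRecord]:
    """Draw a trial-like cohort; identical config and seed -> identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    arms = list(config.arm_proportions)
    probs = np.array([config.arm_proportions[a] for a in arms], dtype=float)
    p_ivt = config.p_ivt or dict(DEFAULT_PARAMETERS["p_ivt"])
    mean_age, sd_age = config.age_mean_sd

    records: list[CohortRecord] = []
    for i in range(config.n_patients):
        arm = arms[rng.choice(len(arms), p=probs)]
        age = float(np.clip(rng.normal(mean_age, sd_age), 18.0, 95.0))
        sex = "F" if rng.random() < config.female_fraction else "M"
        mrs90 = int(rng.choice(7, p=np.asarray(config.mrs90_profiles[arm], float)))
        if arm == "etici2c3_single_pass":
            grade = "2c" if rng.random() < 0.5 else "3"
            pattern, passes = "not_applicable", 1
        elif arm == "etici2c3_multi_pass":
            grade = "2c" if rng.random() < 0.5 else "3"
            pattern = "not_applicable"
            passes = 2 + int(rng.choice(3, p=[0.6, 0.3, 0.1]))
        elif arm in ("etici2b_accessible", "etici2b_non_accessible"):
            grade = "2b"
            pattern = arm.removeprefix("etici2b_")
            if rng.random() > config.assessable_fraction:
                pattern = "not_assessable"
            passes = 1 + int(rng.choice(3, p=[0.5, 0.3, 0.2]))
        else:
            grade = str(rng.choice(["0", "1", "2a"], p=[0.2, 0.3, 0.5]))
            pattern = "not_applicable"
            passes = 1 + int(rng.choice(3, p=[0.5, 0.3, 0.2]))
        ivt = bool(rng.random() < p_ivt.get(arm, 0.585))
        records.append(
            CohortRecord(
                patient_id=f"P{i:05d}", age=age, sex=sex, etici_grade=grade,
                pattern_class=pattern, n_passes=passes, mrs90=mrs90,
                received_ivt=ivt,
            )
        )
    return records


def exact_flowchart_cohort() -> list[CohortRecord]:
    """Deterministic 1105-patient cohort with the reference stratum counts.

    506 near-complete (304 first-pass, 202 multi-pass), 450 eTICI 2b of
    which 7 non-assessable, 147 accessible, 296 non-accessible, and 149
    below eTICI 2b.  Ages, outcomes, and IVT flags are fixed placeholders;
    the cohort exists to exercise flowchart accounting exactly.
    """
    spec = [
        ("2c", "not_applicable", 1, 304),
        ("3", "not_applicable", 3, 202),
        ("2b", "accessible", 2, 147),
        ("2b", "non_accessible", 1, 296),
        ("2b", "not_assessable", 1, 7),
        ("2a", "not_applicable", 1, 149),
    ]
    records = []
    i = 0
    for grade, pattern, passes, count in spec:
        for _ in range(count):
            records.append(
                CohortRecord(
                    patient_id=f"P{i:05d}", age=70.0, sex="F" if i % 2 else "M",
                    etici_grade=grade, pattern_class=pattern, n_passes=passes,
                    mrs90=i % 7, received_ivt=bool(i % 3 == 0),
                )
            )
            i += 1
    return records


def generate_life_table(
    gompertz_a: float = 2.5e-5,
    gompertz_b: float = 0.095,
    min_age: int = 18,
    max_age: int = 100,
) -> LifeTable:
    """Gompertz-hazard life table: ``qx = 1 - exp(-a * exp(b * age))``.

    A smooth, age-increasing two-parameter stand-in for a national life
    table; the defaults put the annual death probability near 2% at age 70
    and 21% at age 95.  The terminal age is forced absorbing (``qx = 1``).
    """
    if gompertz_a <= 0 or gompertz_b <= 0:
        raise ValueError("Gompertz parameters must be positive")
    if not min_age < max_age:
        raise ValueError("min_age must be below max_age")
    ages = np.arange(min_age, max_age + 1)
    qx = 1.0 - np.exp(-gompertz_a * np.exp(gompertz_b * ages))
    qx = np.clip(qx, 0.0, 1.0)
    qx[-1] = 1.0
    return LifeTable(ages, qx)


def generate_parameter_table(
    seed: int = 0,
    schema_defaults: Mapping | None = None,
    jitter: float = 0.0,
) -> ParameterSet:
    """Build a complete, valid parameter set from the default schema.

    ``schema_defaults`` must cover every required parameter name (missing
    names raise, listing them).  With ``jitter`` > 0, probabilities and
    costs are perturbed multiplicatively by ``U(1-jitter, 1+jitter)`` draws
    (seeded) and probability vectors renormalized — handy for randomized
    property tests; the default ``jitter=0`` returns the point estimates.
    """
    ps = ParameterSet.from_dict(schema_defaults or DEFAULT_PARAMETERS)
    if jitter > 0:
        rng = np.random.default_rng(seed)

        def bump(x: np.ndarray) -> np.ndarray:
            return x * rng.uniform(1 - jitter, 1 + jitter, size=np.shape(x))

        for arm in list(ps.mrs90_dist):
            v = bump(ps.mrs90_dist[arm])
            ps.mrs90_dist[arm] = v / v.sum()
        v = bump(ps.recurrent_mrs_dist)
        ps.recurrent_mrs_dist = v / v.sum()
        ps.utility = np.clip(np.sort(bump(ps.utility))[::-1], 0.0, 1.0)
        ps.mortality_hr = np.maximum(bump(ps.mortality_hr), 1.0)
        ps.cost_annual_care = bump(ps.cost_annual_care)
        ps.informal_care_cost = bump(ps.informal_care_cost)
        ps.p_recurrent_annual = float(np.clip(bump(np.array(ps.p_recurrent_annual)), 0, 1))
        ps.case_fatality_recurrent = float(
            np.clip(bump(np.array(ps.case_fatality_recurrent)), 0, 1)
        )
        ps.cost_evt = float(bump(np.array(ps.cost_evt)))
        ps.cost_ivt = float(bump(np.array(ps.cost_ivt)))
        ps.cost_acute_other = float(bump(np.array(ps.cost_acute_other)))
    errors = [f for f in validate_parameter_set(ps) if f.level == "error"]
    if errors:  # pragma: no cover - guards schema edits
        raise ValueError("generated parameter set invalid: " + "; ".join(map(str, errors)))
    return ps
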