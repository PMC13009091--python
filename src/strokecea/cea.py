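"""Incremental cost-effectiveness analysis, PSA, and population scaling.

Implements the comparison layer on top of the cohort engine: incremental
costs and QALYs with dominance classification and ICERs, net monetary
benefit, second-order Monte-Carlo probabilistic sensitivity analysis (every
parameter redrawn from its distribution spec on each draw, both arms run on
the same joint sample), cost-effectiveness acceptability, and the scaling
of per-patient incremental outcomes to annual national figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .markov import LifetimeOutcome, run_lifetime
from .parameters import DistributionSpec, LifeTable, ParameterSet

__all__ = [
    "CEAComparison",
    "PSASample",
    "AcceptabilityResult",
    "PopulationImpactInputs",
    "PopulationImpact",
    "compare_arms",
    "net_monetary_benefit",
    "sample_parameter_set",
    "run_psa",
    "acceptability",
    "export_scatter",
    "population_impact",
]


# -- incremental comparison -------------------------------------------

@dataclass(frozen=True)
class CEAComparison:
    """Incremental result for intervention vs comparator, one perspective.

    ``dominance`` is one of ``intervention_dominant`` (more QALYs, no more
    cost — strictly better on at least one axis), ``comparator_dominant``
    (the mirror image), ``equivalent`` (identical on both axes), or
    ``icer_defined`` (a genuine trade-off; ``icer`` = delta cost per delta
    QALY).  Dominant comparisons carry no ICER, matching the reporting
    convention for cost-effectiveness tables.
    """

    intervention: str
    comparator: str
    perspective: str
    delta_qalys: float
    delta_cost: float
    dominance: str
    icer: float | None

    @property
    def icer_display(self) -> str:
        if self.dominance == "intervention_dominant":
            return f"{self.comparator} -> {self.intervention} dominant"
        if self.dominance == "comparator_dominant":
            return f"{self.comparator} dominant"
        if self.dominance == "equivalent":
            return "equivalent"
        return f"{self.icer:,.2f}"


def _classify(dq: float, dc: float) -> tuple[str, float | None]:
    if dq == 0 and dc == 0:
        return "equivalent", None
    if dq >= 0 and dc <= 0:
        return "intervention_dominant", None
    if dq <= 0 and dc >= 0:
        return "comparator_dominant", None
    # remaining: strict trade-off quadrants (dq and dc share a sign)
    return "icer_defined", dc / dq


def compare_arms(
    a: LifetimeOutcome, b: LifetimeOutcome, perspective: str = "healthcare"
) -> CEAComparison:
    """Incremental analysis of intervention ``a`` against comparator ``b``.

    Both outcomes must come from runs under the same configuration; the
    caller is responsible for that pairing (the model object enforces it).
    """
    if perspective not in ("healthcare", "societal"):
        raise ValueError(f"unknown perspective {perspective!r}")
    cost = "cost_healthcare" if perspective == "healthcare" else "cost_societal"
    dq = a.qalys - b.qalys
    dc = getattr(a, cost) - getattr(b, cost)
    dominance, icer = _classify(dq, dc)
    return CEAComparison(
        intervention=a.arm,
        comparator=b.arm,
        perspective=perspective,
        delta_qalys=dq,
        delta_cost=dc,
        dominance=dominance,
        icer=icer,
    )


def net_monetary_benefit(qalys: float, cost: float, wtp: float) -> float:
    """NMB = wtp * QALYs - cost (USD); positive increments are cost-effective."""
    if wtp < 0:
        raise ValueError("willingness-to-pay threshold must be >= 0")
    return wtp * qalys - cost


# -- PSA ---------------------------------------------------------------

@dataclass(frozen=True)
class PSASample:
    """One second-order Monte-Carlo draw: both arms on one joint sample."""

    draw: int
    outcome_a: LifetimeOutcome
    outcome_b: LifetimeOutcome

    def incremental(self, perspective: str) -> tuple[float, float]:
        cost = "cost_healthcare" if perspective == "healthcare" else "cost_societal"
        return (
            self.outcome_a.qalys - self.outcome_b.qalys,
            getattr(self.outcome_a, cost) - getattr(self.outcome_b, cost),
        )


def _beta_from_mean(m: float, rel_se: float, rng: np.random.Generator) -> float:
    s = rel_se * m
    if m <= 0.0 or m >= 1.0 or s == 0.0:
        return m
    s = min(s, 0.99 * np.sqrt(m * (1 - m)))
    nu = m * (1 - m) / s**2 - 1.0
    return float(rng.beta(m * nu, (1 - m) * nu))


def _gamma_from_mean(m: float, rel_se: float, rng: np.random.Generator) -> float:
    if m <= 0.0:
        return m
    shape = 1.0 / rel_se**2
    return float(rng.gamma(shape, m / shape))


def _lognormal_from_mean(m: float, rel_se: float, rng: np.random.Generator) -> float:
    if m <= 0.0:
        return m
    sigma2 = np.log1p(rel_se**2)
    mu = np.log(m) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


_SCALAR_SAMPLERS = {
    "beta": _beta_from_mean,
    "gamma": _gamma_from_mean,
    "lognormal": _lognormal_from_mean,
}


def _sample_value(value, spec: DistributionSpec, rng: np.random.Generator):
    if spec.family == "fixed":
        return value
    if spec.family == "dirichlet":
        v = np.asarray(value, dtype=float)
        ess = spec.params.get("ess", 100.0)
        alpha = np.maximum(v * ess, 1e-9)
        draw = rng.dirichlet(alpha)
        return draw / draw.sum()
    sampler = _SCALAR_SAMPLERS[spec.family]
    rel_se = spec.params.get("rel_se", 0.2)
    if np.ndim(value) == 0:
        return sampler(float(value), rel_se, rng)
    return np.array([sampler(float(x), rel_se, rng) for x in np.asarray(value)])


def sample_parameter_set(ps: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One joint PSA draw: every parameter redrawn per its spec.

    Parameters without a spec must be explicitly marked ``fixed``; a
    missing spec raises, naming the parameter, so no input silently sits
    out the sensitivity analysis.
    """
    out = ps.copy()
    spec_of = ps.psa_spec

    def get_spec(name: str) -> DistributionSpec:
        if name in spec_of:
            return spec_of[name]
        base = name.split(".")[0]
        if base in spec_of:
            return spec_of[base]
        raise KeyError(
            f"parameter {name!r} has no PSA distribution and is not marked fixed"
        )

    for arm in out.mrs90_dist:
        out.mrs90_dist[arm] = _sample_value(
            out.mrs90_dist[arm], get_spec(f"mrs90_dist.{arm}"), rng
        )
    out.recurrent_mrs_dist = _sample_value(
        out.recurrent_mrs_dist, get_spec("recurrent_mrs_dist"), rng
    )
    for name in (
        "utility", "mortality_hr", "cost_annual_care", "informal_care_cost",
        "return_to_work",
    ):
        setattr(out, name, _sample_value(getattr(out, name), get_spec(name), rng))
    out.utility = np.clip(out.utility, 0.0, 1.0)
    for name in (
        "p_recurrent_annual", "case_fatality_recurrent", "cost_evt", "cost_ivt",
        "cost_acute_other", "annual_wage",
    ):
        setattr(out, name, float(_sample_value(getattr(out, name), get_spec(name), rng)))
    spec = get_spec("p_ivt")
    out.p_ivt = {k: float(_sample_value(v, spec, rng)) for k, v in out.p_ivt.items()}
    spec = get_spec("employment_rate")
    out.employment_rate = {
        k: float(_sample_value(v, spec, rng)) for k, v in out.employment_rate.items()
    }
    return out


def run_psa(
    ps: ParameterSet,
    life_table: LifeTable,
    arms: tuple[str, str],
    n_draws: int = 10_000,
    master_seed: int = 12345,
    config: RunConfig = RunConfig(),
) -> list[PSASample]:
    """Second-order Monte Carlo: ``n_draws`` joint samples, both arms each.

    All parameters fluctuate simultaneously per their distribution specs;
    both arms are evaluated on the *same* sampled set so incremental
    results carry the parameter correlation.  Fully reproducible for a
    fixed ``master_seed``.
    """
    rng = np.random.default_rng(master_seed)
    a, b = arms
    samples: list[PSASample] = []
    for i in range(n_draws):
        drawn = sample_parameter_set(ps, rng)
        out_a = run_lifetime(a, drawn, life_table, config, keep_trace=False)
        out_b = run_lifetime(b, drawn, life_table, config, keep_trace=False)
        samples.append(PSASample(draw=i, outcome_a=out_a, outcome_b=out_b))
    return samples


@dataclass(frozen=True)
class AcceptabilityResult:
    """Fraction of PSA draws cost-effective at one WTP threshold."""

    wtp: float
    perspective: str
    fraction_acceptable: float
    n_draws: int


def acceptability(
    samples: list[PSASample], wtp: float, perspective: str = "healthcare"
) -> AcceptabilityResult:
    """Fraction of draws with positive incremental net monetary benefit."""
    if not samples:
        raise ValueError("no PSA samples")
    count = 0
    for s in samples:
        dq, dc = s.incremental(perspective)
        if net_monetary_benefit(dq, dc, wtp) > 0:
            count += 1
    return AcceptabilityResult(
        wtp=wtp,
        perspective=perspective,
        fraction_acceptable=count / len(samples),
        n_draws=len(samples),
    )


def export_scatter(samples: list[PSASample], perspective: str = "healthcare") -> pd.DataFrame:
    """One row per draw: (incremental QALYs, incremental cost) for plotting."""
    if not samples:
        raise ValueError("no PSA samples")
    rows = [s.incremental(perspective) for s in samples]
    return pd.DataFrame(rows, columns=["delta_qalys", "delta_cost"]).assign(
        draw=[s.draw for s in samples]
    )[["draw", "delta_qalys", "delta_cost"]]


# -- population scaling ------------------------------------------------

@dataclass(frozen=True)
class PopulationImpactInputs:
    """Annual national scaling inputs.

    ``n_procedures`` thrombectomies per year; ``p_incomplete`` the fraction
    with incomplete (eTICI 2b) reperfusion; of those, ``p_accessible`` /
    ``p_non_accessible`` the accessible/non-accessible split.  Per-patient
    deltas are the incremental QALYs and cost *savings* (positive = saving)
    of converting that pattern to complete reperfusion.
    """

    n_procedures: float
    p_incomplete: float
    p_accessible: float
    p_non_accessible: float
    dqaly_accessible: float
    dqaly_non_accessible: float
    dcost_accessible: dict[str, float] = field(default_factory=dict)
    dcost_non_accessible: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("p_incomplete", "p_accessible", "p_non_accessible"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.p_accessible + self.p_non_accessible - 1.0) > 1e-9:
            raise ValueError("p_accessible + p_non_accessible must equal 1")
        if self.n_procedures < 0:
            raise ValueError("n_procedures must be >= 0")


@dataclass(frozen=True)
class PopulationImpact:
    """Annual national totals; savings in millions of USD per perspective."""

    n_incomplete: float
    qalys_accessible: float
    qalys_non_accessible: float
    qalys_total: float
    savings_accessible: dict[str, float]
    savings_non_accessible: dict[str, float]
    savings_total: dict[str, float]
    rounding_mode: str


def population_impact(
    inputs: PopulationImpactInputs, rounding_mode: str = "paper"
) -> PopulationImpact:
    """Scale per-patient increments to annual national QALYs and savings.

    ``rounding_mode="paper"`` reproduces printed-report arithmetic: QALY
    components rounded to the nearest integer and savings components to the
    nearest million USD *before* summing.  ``"exact"`` reports unrounded
    values (savings still expressed in millions).
    """
    inputs.validate()
    if rounding_mode not in ("paper", "exact"):
        raise ValueError(f"unknown rounding_mode {rounding_mode!r}")
    n_inc = inputs.n_procedures * inputs.p_incomplete
    n_acc = n_inc * inputs.p_accessible
    n_non = n_inc * inputs.p_non_accessible

    q_acc = n_acc * inputs.dqaly_accessible
    q_non = n_non * inputs.dqaly_non_accessible
    perspectives = sorted(set(inputs.dcost_accessible) | set(inputs.dcost_non_accessible))
    s_acc = {p: n_acc * inputs.dcost_accessible.get(p, 0.0) / 1e6 for p in perspectives}
    s_non = {p: n_non * inputs.dcost_non_accessible.get(p, 0.0) / 1e6 for p in perspectives}

    if rounding_mode == "paper":
        q_acc, q_non = round(q_acc), round(q_non)
        s_acc = {p: float(round(v)) for p, v in s_acc.items()}
        s_non = {p: float(round(v)) for p, v in s_non.items()}
    return PopulationImpact(
        n_incomplete=n_inc,
        qalys_accessible=q_acc,
        qalys_non_accessible=q_non,
        qalys_total=q_acc + q_non,
        savings_accessible=s_acc,
        savings_non_accessible=s_non,
        savings_total={p: s_acc[p] + s_non[p] for p in perspectives},
        rounding_mode=rounding_mode,
    )
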