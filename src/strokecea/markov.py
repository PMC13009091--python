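"""Two-phase Markov cohort engine.

Phase one is a single 3-month short-run cycle that lands the cohort on its
arm-specific 90-day mRS distribution and books the acute-phase QALYs and
costs.  Phase two is an annual-cycle Markov state-transition model over the
seven health states (mRS 0-5 and absorbing death): each year a survivor can
stay put, suffer a recurrent stroke and deteriorate to an equal-or-worse
state, or die of the recurrence or of age-related background mortality.
Background mortality comes from a life table, multiplied by an mRS-specific
hazard ratio; the two death causes combine multiplicatively within a cycle
(independence approximation).

A matrix-based cohort run is the production path; ``microsim_oracle``
re-estimates the same quantities by sampling individual patient
trajectories and serves as an independent brute-force cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .economics import CostComponents, acute_phase_cost, premature_death_loss
from .parameters import DEAD, MRS_STATES, N_STATES, LifeTable, ParameterSet

__all__ = [
    "CycleTrace",
    "LifetimeOutcome",
    "MicrosimEstimate",
    "run_short_run",
    "build_transition_matrix",
    "build_transition_matrices",
    "run_long_run",
    "run_lifetime",
    "run_lifetime_age_mixture",
    "microsim_oracle",
]

_TOL = 1e-9


def _check_distribution(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (N_STATES,):
        raise ValueError(f"state distribution needs {N_STATES} entries")
    if np.any(v < -_TOL) or abs(v.sum() - 1.0) > 1e-9:
        raise ValueError("state distribution must be non-negative and sum to 1")
    return v


@dataclass
class CycleTrace:
    """Per-cycle record of the long-run phase (numpy-backed).

    ``occupancy[t]`` is the state distribution at the *end* of cycle ``t``
    (row 0 is the 90-day starting distribution).  Accrual columns are per
    cycle; cumulative sums are exposed via :meth:`to_frame`.
    """

    ages: np.ndarray
    occupancy: np.ndarray
    qalys: np.ndarray
    qalys_discounted: np.ndarray
    cost_healthcare: np.ndarray
    cost_healthcare_discounted: np.ndarray
    cost_societal: np.ndarray
    cost_societal_discounted: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        n = len(self.qalys)
        df = pd.DataFrame(
            {
                "cycle": np.arange(1, n + 1),
                "age": self.ages,
                **{
                    f"occ_{name}": self.occupancy[1:, i]
                    for i, name in enumerate(MRS_STATES)
                },
                "qalys": self.qalys,
                "qalys_discounted": self.qalys_discounted,
                "cost_healthcare": self.cost_healthcare,
                "cost_healthcare_discounted": self.cost_healthcare_discounted,
                "cost_societal": self.cost_societal,
                "cost_societal_discounted": self.cost_societal_discounted,
            }
        )
        for col in (
            "qalys_discounted",
            "cost_healthcare_discounted",
            "cost_societal_discounted",
        ):
            df[f"cum_{col}"] = df[col].cumsum()
        return df


@dataclass
class LifetimeOutcome:
    """Discounted lifetime totals for one strategy arm (acute + long run)."""

    arm: str
    qalys: float
    cost_healthcare: float
    cost_societal: float
    life_years: float
    acute_qalys: float
    acute_costs: CostComponents
    trace: CycleTrace | None = None


def run_short_run(
    arm: str, ps: ParameterSet
) -> tuple[np.ndarray, float, CostComponents]:
    """Acute 3-month phase: 90-day state distribution, QALYs, and costs.

    The arm's 90-day mRS distribution maps directly onto the health states
    (mRS 6 -> dead).  QALYs accrue for a quarter year against the surviving
    states' utilities; costs come from :func:`~strokecea.economics.acute_phase_cost`.
    """
    if arm not in ps.mrs90_dist:
        raise KeyError(f"arm {arm!r} not found in parameter set mrs90_dist")
    dist = _check_distribution(ps.mrs90_dist[arm])
    qalys = 0.25 * float(np.dot(dist[:DEAD], ps.utility))
    return dist.copy(), qalys, acute_phase_cost(arm, ps)


def build_transition_matrices(
    ps: ParameterSet, ages: np.ndarray, life_table: LifeTable
) -> np.ndarray:
    """Row-stochastic annual transition matrices for each age (vectorized).

    For a living state ``s`` at age ``a`` with background death probability
    ``qx(a)``::

        P(death)      = 1 - (1 - min(qx*hr_s, 1)) * (1 - p_rec * cf)
        P(s -> s'>s)  = p_rec * (1 - cf) * W(s -> s')
        P(stay)       = remainder

    where ``W`` is the post-recurrence mRS distribution truncated to states
    >= ``s`` and renormalized (its mass at ``s`` folds into "stay").  Death
    is absorbing.  Raises if any remainder goes negative (infeasible
    parameter combination).
    """
    ages = np.atleast_1d(np.asarray(ages))
    qx = life_table.qx_array(ages)  # (A,)
    hr = np.asarray(ps.mortality_hr, dtype=float)  # (6,)
    p_rec = float(ps.p_recurrent_annual)
    cf = float(ps.case_fatality_recurrent)

    p_bg = np.minimum(qx[:, None] * hr[None, :], 1.0)  # (A, 6)
    p_death = 1.0 - (1.0 - p_bg) * (1.0 - p_rec * cf)

    # worsening kernel: rows = current state, cols = new state (> current)
    w = np.asarray(ps.recurrent_mrs_dist, dtype=float)
    worse = np.zeros((6, 6))
    for s in range(6):
        tail = w[s:].sum()
        if tail > 0:
            worse[s, s + 1 :] = w[s + 1 :] / tail
    move = p_rec * (1.0 - cf) * worse  # (6, 6), survival-conditional moves

    mats = np.zeros((len(ages), N_STATES, N_STATES))
    mats[:, :6, :6] = move[None, :, :] * (1.0 - p_bg)[:, :, None]
    mats[:, :6, DEAD] = p_death
    stay = 1.0 - p_death - mats[:, :6, :6].sum(axis=2)
    if np.any(stay < -_TOL):
        a_idx, s_idx = np.argwhere(stay < -_TOL)[0]
        raise ValueError(
            f"infeasible transition: negative stay probability at age "
            f"{ages[a_idx]}, state {MRS_STATES[s_idx]}"
        )
    stay = np.clip(stay, 0.0, 1.0)
    idx = np.arange(6)
    mats[:, idx, idx] += stay
    mats[:, DEAD, DEAD] = 1.0
    return mats


def build_transition_matrix(
    ps: ParameterSet, age: float, life_table: LifeTable
) -> np.ndarray:
    """Single-age convenience wrapper around :func:`build_transition_matrices`."""
    return build_transition_matrices(ps, np.array([int(age)]), life_table)[0]


def _accrual_ages(start_age: float, n_cycles: int) -> np.ndarray:
    # integer age during each annual cycle t = 1..n
    return np.asarray([int(start_age) + t for t in range(n_cycles)])


def run_long_run(
    start: np.ndarray,
    start_age: float,
    ps: ParameterSet,
    life_table: LifeTable,
    discount_rate: float = 0.03,
    horizon: int | None = None,
    cycle_correction: str = "half_cycle",
) -> CycleTrace:
    """Annual Markov phase from the 90-day distribution to extinction.

    Cycle ``t`` (1-based) covers ages ``start_age + t - 1`` to
    ``start_age + t`` and is discounted by ``(1 + r)^-t``.  QALY and cost
    accruals use end-of-cycle occupancy (``cycle_correction="none"``) or
    the start/end average (``"half_cycle"``); premature-death productivity
    losses are booked as a lump sum against the deaths of each cycle.
    """
    occ = _check_distribution(start)
    if cycle_correction not in ("half_cycle", "none"):
        raise ValueError(f"unknown cycle_correction {cycle_correction!r}")
    n_cycles = horizon if horizon is not None else life_table.max_age - int(start_age) + 1
    if n_cycles < 0:
        raise ValueError("start_age beyond life-table maximum")
    ages = _accrual_ages(start_age, n_cycles)
    mats = build_transition_matrices(ps, ages, life_table)

    u = np.asarray(ps.utility)
    care = np.asarray(ps.cost_annual_care)
    informal = np.asarray(ps.informal_care_cost)
    prod = np.array(
        [
            ps.employment_rate_at(a) * ps.annual_wage
            for a in ages
        ]
    )  # (T,) per-age full-employment wage base; state factor applied below
    not_rtw = 1.0 - np.asarray(ps.return_to_work)

    occupancy = np.zeros((n_cycles + 1, N_STATES))
    occupancy[0] = occ
    qalys = np.zeros(n_cycles)
    hc = np.zeros(n_cycles)
    soc = np.zeros(n_cycles)
    disc = (1.0 + discount_rate) ** -np.arange(1, n_cycles + 1)

    for t in range(n_cycles):
        new = occ @ mats[t]
        acc = 0.5 * (occ + new) if cycle_correction == "half_cycle" else new
        living = acc[:DEAD]
        qalys[t] = float(living @ u)
        hc[t] = float(living @ care)
        new_dead = max(new[DEAD] - occ[DEAD], 0.0)
        death_loss = new_dead * premature_death_loss(
            ages[t] + 1, ps, discount_rate
        )
        soc[t] = hc[t] + float(living @ informal) + prod[t] * float(living @ not_rtw) + death_loss
        occupancy[t + 1] = new
        occ = new

    return CycleTrace(
        ages=ages,
        occupancy=occupancy,
        qalys=qalys,
        qalys_discounted=qalys * disc,
        cost_healthcare=hc,
        cost_healthcare_discounted=hc * disc,
        cost_societal=soc,
        cost_societal_discounted=soc * disc,
    )


def run_lifetime(
    arm: str,
    ps: ParameterSet,
    life_table: LifeTable,
    config: RunConfig = RunConfig(),
    keep_trace: bool = True,
) -> LifetimeOutcome:
    """Full two-phase run for one arm: acute phase then annual cycles."""
    start, acute_qalys, acute_costs = run_short_run(arm, ps)
    horizon = None
    if config.max_age is not None:
        horizon = int(config.max_age) - int(ps.start_age) + 1
    trace = run_long_run(
        start,
        ps.start_age,
        ps,
        life_table,
        discount_rate=config.discount_rate,
        horizon=horizon,
        cycle_correction=config.cycle_correction,
    )
    survival = 1.0 - trace.occupancy[:, DEAD]
    if config.cycle_correction == "half_cycle":
        life_years = float(0.5 * (survival[:-1] + survival[1:]).sum())
    else:
        life_years = float(survival[1:].sum())
    life_years += 0.25 * float(survival[0])
    return LifetimeOutcome(
        arm=arm,
        qalys=acute_qalys + float(trace.qalys_discounted.sum()),
        cost_healthcare=acute_costs.healthcare_total
        + float(trace.cost_healthcare_discounted.sum()),
        cost_societal=acute_costs.societal_total
        + float(trace.cost_societal_discounted.sum()),
        life_years=life_years,
        acute_qalys=acute_qalys,
        acute_costs=acute_costs,
        trace=trace if keep_trace else None,
    )


def run_lifetime_age_mixture(
    arm: str,
    ps: ParameterSet,
    life_table: LifeTable,
    ages: np.ndarray,
    weights: np.ndarray | None = None,
    config: RunConfig = RunConfig(),
) -> LifetimeOutcome:
    """Age-mixture sensitivity run: outcomes averaged over starting ages.

    The cohort model normally uses one representative starting age; here
    the lifetime run is repeated at each age in ``ages`` (e.g. a cohort
    file's observed ages) and the totals averaged with ``weights``
    (uniform by default).  The returned outcome carries no trace.
    """
    ages = np.asarray(ages)
    if weights is None:
        weights = np.full(len(ages), 1.0 / len(ages))
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(ages):
        raise ValueError("ages and weights must have equal length")
    if abs(weights.sum() - 1.0) > 1e-9 or np.any(weights < 0):
        raise ValueError("weights must be a probability vector")
    totals = np.zeros(4)
    acute = np.zeros(2)
    for age, w in zip(ages, weights):
        ps_age = ps.copy()
        ps_age.start_age = float(age)
        out = run_lifetime(arm, ps_age, life_table, config, keep_trace=False)
        totals += w * np.array(
            [out.qalys, out.cost_healthcare, out.cost_societal, out.life_years])
        acute += w * np.array([out.acute_qalys, out.acute_costs.direct_healthcare])
    return LifetimeOutcome(
        arm=arm,
        qalys=float(totals[0]),
        cost_healthcare=float(totals[1]),
        cost_societal=float(totals[2]),
        life_years=float(totals[3]),
        acute_qalys=float(acute[0]),
        acute_costs=CostComponents(direct_healthcare=float(acute[1])),
        trace=None,
    )


@dataclass(frozen=True)
class MicrosimEstimate:
    """Monte-Carlo estimate of lifetime outcomes with standard errors."""

    arm: str
    n_patients: int
    qalys: float
    qalys_se: float
    cost_healthcare: float
    cost_healthcare_se: float
    cost_societal: float
    cost_societal_se: float


def microsim_oracle(
    arm: str,
    ps: ParameterSet,
    life_table: LifeTable,
    config: RunConfig = RunConfig(),
    n_patients: int = 10_000,
    seed: int = 0,
) -> MicrosimEstimate:
    """Estimate lifetime outcomes by simulating individual trajectories.

    Each patient draws a 90-day state from the arm's mRS distribution, then
    walks the annual transition matrices by inverse-CDF sampling, accruing
    the same per-state utilities and costs the cohort run integrates.
    Brute-force cross-check for :func:`run_lifetime`; the two must agree
    within Monte-Carlo error.
    """
    rng = np.random.default_rng(seed)
    start, acute_qalys, acute_costs = run_short_run(arm, ps)
    n_cycles = (
        int(config.max_age) - int(ps.start_age) + 1
        if config.max_age is not None
        else life_table.max_age - int(ps.start_age) + 1
    )
    ages = _accrual_ages(ps.start_age, n_cycles)
    cum = build_transition_matrices(ps, ages, life_table).cumsum(axis=2)

    u = np.append(ps.utility, 0.0)
    care = np.append(ps.cost_annual_care, 0.0)
    informal = np.append(ps.informal_care_cost, 0.0)
    not_rtw = np.append(1.0 - np.asarray(ps.return_to_work), 0.0)
    half = config.cycle_correction == "half_cycle"
    disc = (1.0 + config.discount_rate) ** -np.arange(1, n_cycles + 1)

    states = rng.choice(N_STATES, size=n_patients, p=start)
    qalys = np.zeros(n_patients)
    hc = np.zeros(n_patients)
    soc = np.zeros(n_patients)
    # per-patient acute societal components depend on the sampled 90-day state
    qalys += 0.25 * u[states]
    hc += ps.cost_evt + ps.p_ivt.get(arm, 0.0) * ps.cost_ivt + ps.cost_acute_other
    hc += 0.25 * care[states]
    acute_prod = np.array(
        [
            ps.employment_rate_at(ps.start_age) * ps.annual_wage * 0.25 * nr
            for nr in not_rtw
        ]
    )
    soc += 0.25 * informal[states] + acute_prod[states]
    soc += np.where(states == DEAD, premature_death_loss(ps.start_age, ps), 0.0)

    prod = np.array([ps.employment_rate_at(a) * ps.annual_wage for a in ages])
    for t in range(n_cycles):
        draws = rng.random(n_patients)
        new_states = (cum[t][states] > draws[:, None]).argmax(axis=1)
        if half:
            w_old, w_new = 0.5, 0.5
        else:
            w_old, w_new = 0.0, 1.0
        q_acc = w_old * u[states] + w_new * u[new_states]
        h_acc = w_old * care[states] + w_new * care[new_states]
        extra = (
            w_old * informal[states]
            + w_new * informal[new_states]
            + prod[t] * (w_old * not_rtw[states] + w_new * not_rtw[new_states])
        )
        died = (new_states == DEAD) & (states != DEAD)
        extra = extra + died * premature_death_loss(
            ages[t] + 1, ps, config.discount_rate
        )
        qalys += disc[t] * q_acc
        hc += disc[t] * h_acc
        soc += disc[t] * extra
        states = new_states

    soc = soc + hc  # societal totals include all healthcare accruals
    return MicrosimEstimate(
        arm=arm,
        n_patients=n_patients,
        qalys=float(qalys.mean()),
        qalys_se=float(qalys.std(ddof=1) / np.sqrt(n_patients)),
        cost_healthcare=float(hc.mean()),
        cost_healthcare_se=float(hc.std(ddof=1) / np.sqrt(n_patients)),
        cost_societal=float(soc.mean()),
        cost_societal_se=float(soc.std(ddof=1) / np.sqrt(n_patients)),
    )
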