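"""Per-cycle and acute-phase costing under two analytic perspectives.

The healthcare perspective counts only direct medical costs (acute
procedures and state-dependent annual care).  The societal perspective adds
three human-capital components: informal care provided by family and
friends, productivity lost by survivors who do not return to work, and the
future earnings forgone through premature death.  All components are priced
per modified Rankin Scale (mRS) state per year and pro-rated linearly with
cycle length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import DEAD, ParameterSet

__all__ = [
    "CostComponents",
    "cycle_healthcare_cost",
    "informal_care_cost",
    "productivity_loss",
    "premature_death_loss",
    "acute_phase_cost",
]


@dataclass(frozen=True)
class CostComponents:
    """Cost breakdown for one accrual; all components in USD, >= 0."""

    direct_healthcare: float = 0.0
    informal_care: float = 0.0
    productivity_loss: float = 0.0
    premature_death_loss: float = 0.0

    @property
    def healthcare_total(self) -> float:
        return self.direct_healthcare

    @property
    def societal_total(self) -> float:
        return (
            self.direct_healthcare
            + self.informal_care
            + self.productivity_loss
            + self.premature_death_loss
        )


def cycle_healthcare_cost(state: int, ps: ParameterSet, cycle_length: float = 1.0) -> float:
    """Direct care cost of occupying ``state`` for ``cycle_length`` years."""
    if state == DEAD:
        return 0.0
    return float(ps.cost_annual_care[state]) * cycle_length


def informal_care_cost(state: int, ps: ParameterSet, cycle_length: float = 1.0) -> float:
    """Uncompensated family/friend care, priced per state per year."""
    if state == DEAD:
        return 0.0
    return float(ps.informal_care_cost[state]) * cycle_length


def productivity_loss(
    state: int, age: float, ps: ParameterSet, cycle_length: float = 1.0
) -> float:
    """Earnings lost by a survivor in ``state`` over one cycle.

    Human-capital valuation: the age-band employment rate times the
    probability of *not* returning to work in that disability state times
    the annual wage.  Zero at or beyond retirement age, and for the dead
    (whose loss is booked once via :func:`premature_death_loss`).
    """
    if state == DEAD or age >= ps.retirement_age:
        return 0.0
    rate = ps.employment_rate_at(age)
    return rate * (1.0 - float(ps.return_to_work[state])) * ps.annual_wage * cycle_length


def premature_death_loss(
    age_at_death: float, ps: ParameterSet, discount_rate: float = 0.0
) -> float:
    """Discounted future earnings forgone by dying at ``age_at_death``.

    Sums employment-rate-weighted wages over the whole years from the age
    at death up to retirement age, discounted back to the year of death.
    Booked as a lump sum in the cycle the death occurs.
    """
    loss = 0.0
    age = float(age_at_death)
    t = 0
    while age < ps.retirement_age:
        loss += ps.employment_rate_at(age) * ps.annual_wage / (1.0 + discount_rate) ** t
        age += 1.0
        t += 1
    return loss


def acute_phase_cost(
    arm: str,
    ps: ParameterSet,
    extra_passes: float = 0.0,
    cost_per_pass: float = 0.0,
) -> CostComponents:
    """Procedure-phase costs for one strategy arm.

    Direct healthcare: thrombectomy plus thrombolysis (weighted by the
    arm's IVT rate) plus other acute hospital costs.  Societal components
    accrue over the 3-month short-run phase against the 90-day mRS
    distribution; deaths within 90 days book the premature-death loss at
    the starting age.

    By default the thrombectomy is priced as one procedure regardless of
    the number of passes (cost differences between single- and multi-pass
    strategies then flow from outcomes, not device use); for sensitivity
    analyses a per-additional-pass increment can be added via
    ``extra_passes`` (mean additional passes) and ``cost_per_pass``.
    """
    if arm not in ps.mrs90_dist:
        raise KeyError(f"arm {arm!r} not found in parameter set")
    p_ivt = ps.p_ivt.get(arm, 0.0)
    direct = (ps.cost_evt + extra_passes * cost_per_pass
              + p_ivt * ps.cost_ivt + ps.cost_acute_other)
    dist = ps.mrs90_dist[arm]
    informal = sum(
        dist[s] * informal_care_cost(s, ps, 0.25) for s in range(DEAD)
    )
    productivity = sum(
        dist[s] * productivity_loss(s, ps.start_age, ps, 0.25) for s in range(DEAD)
    )
    death_loss = float(dist[DEAD]) * premature_death_loss(ps.start_age, ps)
    # short-run state care costs are part of direct healthcare
    direct += sum(dist[s] * cycle_healthcare_cost(s, ps, 0.25) for s in range(DEAD))
    return CostComponents(
        direct_healthcare=float(direct),
        informal_care=float(informal),
        productivity_loss=float(productivity),
        premature_death_loss=float(death_loss),
    )
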