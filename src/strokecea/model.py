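"""Model/results facade over the cohort engine.

``MarkovCohortModel`` is built from a parameter set, a life table, and an
ordered (intervention, comparator) arm pair; ``fit()`` runs the base case
deterministically on the point estimates and returns ``CEAResults``, which
carries the per-arm lifetime outcomes, the incremental comparisons per
perspective, a ``summary()`` table, and the entry point to the PSA.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import (
    AcceptabilityResult,
    CEAComparison,
    PSASample,
    acceptability,
    compare_arms,
    export_scatter,
    run_psa,
)
from .config import RunConfig
from .markov import LifetimeOutcome, run_lifetime
from .parameters import LifeTable, ParameterSet, load_parameter_set, validate_parameter_set

__all__ = ["MarkovCohortModel", "CEAResults", "PSAResults"]


class MarkovCohortModel:
    """Two-arm, two-phase Markov cohort cost-effectiveness model.

    Parameters
    ----------
    params : ParameterSet
        Complete model inputs (point estimates plus PSA specs).
    life_table : LifeTable
        Background annual death probabilities by age.
    intervention, comparator : str
        Ordered strategy arms; increments are intervention minus comparator.
    config : RunConfig
        Discounting, cycle-correction, horizon, WTP, and PSA settings.

    Examples
    --------
    >>> from strokecea import MarkovCohortModel
    >>> model = MarkovCohortModel.from_defaults(
    ...     intervention="etici2c3", comparator="etici2b_accessible")
    >>> res = model.fit()
    >>> print(res.summary())                       # doctest: +SKIP
    """

    def __init__(
        self,
        params: ParameterSet,
        life_table: LifeTable,
        intervention: str,
        comparator: str,
        config: RunConfig = RunConfig(),
    ):
        if intervention == comparator:
            raise ValueError("intervention and comparator arms must be distinct")
        errors = [f for f in validate_parameter_set(params) if f.level == "error"]
        if errors:
            raise ValueError(
                "parameter set invalid:\n" + "\n".join(str(f) for f in errors)
            )
        for arm in (intervention, comparator):
            if arm not in params.mrs90_dist:
                raise KeyError(f"arm {arm!r} not present in parameter set")
        self.params = params
        self.life_table = life_table
        self.intervention = intervention
        self.comparator = comparator
        self.config = config

    @classmethod
    def from_files(
        cls,
        parameter_path: str,
        life_table_path: str,
        intervention: str,
        comparator: str,
        config: RunConfig = RunConfig(),
    ) -> "MarkovCohortModel":
        return cls(
            load_parameter_set(parameter_path),
            LifeTable.from_csv(life_table_path),
            intervention,
            comparator,
            config,
        )

    @classmethod
    def from_defaults(
        cls,
        intervention: str = "etici2c3",
        comparator: str = "etici2b_accessible",
        config: RunConfig = RunConfig(),
    ) -> "MarkovCohortModel":
        """Model on the synthetic default parameter table and life table."""
        from .synthetic import generate_life_table, generate_parameter_table

        return cls(
            generate_parameter_table(),
            generate_life_table(),
            intervention,
            comparator,
            config,
        )

    def run_arm(self, arm: str, keep_trace: bool = True) -> LifetimeOutcome:
        return run_lifetime(arm, self.params, self.life_table, self.config, keep_trace)

    def fit(self) -> "CEAResults":
        """Deterministic base case on point estimates for both arms."""
        outcomes = {
            arm: self.run_arm(arm) for arm in (self.intervention, self.comparator)
        }
        comparisons = {
            p: compare_arms(outcomes[self.intervention], outcomes[self.comparator], p)
            for p in self.config.perspectives
        }
        return CEAResults(model=self, outcomes=outcomes, comparisons=comparisons)


@dataclass
class CEAResults:
    """Base-case results: per-arm outcomes plus incremental comparisons."""

    model: MarkovCohortModel
    outcomes: dict[str, LifetimeOutcome]
    comparisons: dict[str, CEAComparison]

    def to_frame(self) -> pd.DataFrame:
        """Cost-effectiveness table: one block per perspective."""
        a, b = self.model.intervention, self.model.comparator
        rows = []
        oa, ob = self.outcomes[a], self.outcomes[b]
        rows.append(("qalys", oa.qalys, ob.qalys, oa.qalys - ob.qalys, ""))
        for p in self.model.config.perspectives:
            cmp = self.comparisons[p]
            attr = "cost_healthcare" if p == "healthcare" else "cost_societal"
            rows.append(
                (
                    f"cost_{p}",
                    getattr(oa, attr),
                    getattr(ob, attr),
                    cmp.delta_cost,
                    "",
                )
            )
            rows.append((f"icer_{p}", np.nan, np.nan, np.nan, cmp.icer_display))
        return pd.DataFrame(
            rows, columns=["quantity", a, b, "difference", "note"]
        )

    def summary(self) -> str:
        """Human-readable base-case table (currency year in the header)."""
        cfg = self.model.config
        buf = io.StringIO()
        buf.write("Markov cohort cost-effectiveness: base case\n")
        buf.write(
            f"  intervention={self.model.intervention}  "
            f"comparator={self.model.comparator}\n"
        )
        buf.write(
            f"  discount={cfg.discount_rate:.1%}/yr  "
            f"cycle_correction={cfg.cycle_correction}  "
            f"currency: {self.model.params.currency_year} USD\n\n"
        )
        with pd.option_context("display.float_format", "{:,.3f}".format):
            buf.write(self.to_frame().to_string(index=False))
        return buf.getvalue()

    def run_psa(
        self, n_draws: int | None = None, master_seed: int | None = None
    ) -> "PSAResults":
        """Second-order Monte Carlo around this base case."""
        cfg = self.model.config
        samples = run_psa(
            self.model.params,
            self.model.life_table,
            (self.model.intervention, self.model.comparator),
            n_draws=n_draws if n_draws is not None else cfg.n_psa_draws,
            master_seed=master_seed if master_seed is not None else cfg.master_seed,
            config=cfg,
        )
        return PSAResults(model=self.model, samples=samples)


@dataclass
class PSAResults:
    """Probabilistic sensitivity analysis results for one arm pair."""

    model: MarkovCohortModel
    samples: list[PSASample] = field(repr=False)

    def scatter(self, perspective: str = "healthcare") -> pd.DataFrame:
        return export_scatter(self.samples, perspective)

    def acceptability(self, wtp: float, perspective: str = "healthcare") -> AcceptabilityResult:
        return acceptability(self.samples, wtp, perspective)

    def acceptability_table(self) -> pd.DataFrame:
        """Acceptability at every configured WTP threshold and perspective."""
        rows = []
        for p in self.model.config.perspectives:
            for wtp in self.model.config.wtp_thresholds:
                r = self.acceptability(wtp, p)
                rows.append(
                    {
                        "perspective": p,
                        "wtp": wtp,
                        "fraction_acceptable": r.fraction_acceptable,
                        "n_draws": r.n_draws,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write(
            f"PSA: {len(self.samples)} draws, "
            f"{self.model.intervention} vs {self.model.comparator}\n"
        )
        for p in self.model.config.perspectives:
            sc = self.scatter(p)
            buf.write(
                f"  [{p}] mean dQALY={sc.delta_qalys.mean():.3f}  "
                f"mean dCost={sc.delta_cost.mean():,.0f} USD\n"
            )
        with pd.option_context("display.float_format", "{:,.4f}".format):
            buf.write(self.acceptability_table().to_string(index=False))
        return buf.getvalue()

    def plot_scatter(self, perspective: str = "healthcare", ax=None):
        """Incremental cost-effectiveness plane (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sc = self.scatter(perspective)
        ax.scatter(sc.delta_qalys, sc.delta_cost, s=4, alpha=0.4)
        for wtp, style in zip(self.model.config.wtp_thresholds, ("--", ":")):
            q = np.linspace(sc.delta_qalys.min(), sc.delta_qalys.max(), 50)
            ax.plot(q, wtp * q, style, color="grey", label=f"{wtp:,.0f}/QALY")
        ax.axhline(0, color="k", lw=0.5)
        ax.axvline(0, color="k", lw=0.5)
        ax.set_xlabel("incremental QALYs")
        ax.set_ylabel("incremental cost (USD)")
        ax.set_title(f"{self.model.intervention} vs {self.model.comparator} ({perspective})")
        ax.legend()
        return ax
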