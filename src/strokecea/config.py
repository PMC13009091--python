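"""Run-level configuration shared by the model, PSA, and CLI."""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class RunConfig:
    """Constants of one model run.

    Parameters
    ----------
    discount_rate : float
        Annual discount rate applied to both QALYs and costs (3%/year by
        convention; set 0 for undiscounted results).
    cycle_correction : str
        ``"half_cycle"`` accrues each annual cycle against the average of
        the start- and end-of-cycle occupancy (trapezoid); ``"none"``
        accrues against end-of-cycle occupancy.
    max_age : float or None
        Horizon: run until the cohort reaches this age (None = life-table
        terminal age, where the death probability is 1, so the cohort is
        guaranteed extinct — a lifetime horizon).
    wtp_thresholds : tuple of float
        Willingness-to-pay thresholds (USD/QALY) for net-monetary-benefit
        and acceptability reporting.
    """

    discount_rate: float = 0.03
    cycle_correction: str = "half_cycle"
    max_age: float | None = None
    wtp_thresholds: tuple[float, ...] = (50_000.0, 100_000.0)
    n_psa_draws: int = 10_000
    master_seed: int = 12345
    rounding_mode: str = "paper"
    perspectives: tuple[str, ...] = ("healthcare", "societal")

    def __post_init__(self) -> None:
        if self.cycle_correction not in ("half_cycle", "none"):
            raise ValueError(f"unknown cycle_correction {self.cycle_correction!r}")
        if any(w <= 0 for w in self.wtp_thresholds):
            raise ValueError("WTP thresholds must be positive")
        if self.n_psa_draws < 1:
            raise ValueError("n_psa_draws must be >= 1")
        if self.rounding_mode not in ("paper", "exact"):
            raise ValueError(f"unknown rounding_mode {self.rounding_mode!r}")

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)
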