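"""Three-state Markov cohort engine.

The cohort starts fully in the stable state and is advanced each cycle by
the row-stochastic matrix over (stable, progressive, dead)::

    [[1 - p_sp - p_sd,  p_sp,      p_sd],
     [0,                1 - p_pd,  p_pd],
     [0,                0,         1   ]]

Rewards (person-time, quality-adjusted person-time, costs) are accrued per
cycle from the state-occupancy fractions, discounted at the per-cycle rate,
and summed over the horizon.  Where within a cycle membership is counted
(begin / end / half-cycle) is a :class:`~mrcc_cea.parameters.ModelSettings`
switch, as is how the adverse-event disutility is charged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ModelSettings, ParameterError, StrategyParameters, TransitionProbabilities

__all__ = ["CohortTrace", "StrategyOutcome", "run_cohort", "accrue_outcomes", "discount_factors"]

STATES = ("stable", "progressive", "dead")


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy fractions per cycle, rows ``0..horizon``."""

    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = self.occupancy
        if occ.ndim != 2 or occ.shape[1] != 3:
            raise ParameterError(f"occupancy must be (n_cycles+1, 3), got {occ.shape}")
        if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-12):
            raise ParameterError("occupancy rows must sum to 1")
        if occ.min() < -1e-15 or occ.max() > 1.0 + 1e-12:
            raise ParameterError("occupancy fractions must lie in [0, 1]")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def stable(self) -> np.ndarray:
        return self.occupancy[:, 0]

    @property
    def progressive(self) -> np.ndarray:
        return self.occupancy[:, 1]

    @property
    def dead(self) -> np.ndarray:
        return self.occupancy[:, 2]

    def to_dataframe(self, settings: ModelSettings | None = None) -> pd.DataFrame:
        """Trace as a DataFrame; with settings, adds the per-cycle discount factor."""
        frame = pd.DataFrame(self.occupancy, columns=list(STATES))
        frame.insert(0, "cycle", np.arange(len(frame)))
        if settings is not None:
            rate = settings.cycle_discount
            frame["discount_factor"] = (1.0 + rate) ** (-frame["cycle"].to_numpy(dtype=float))
        return frame


def run_cohort(transitions: TransitionProbabilities, settings: ModelSettings) -> CohortTrace:
    """Advance the cohort over the horizon; row 0 is the all-stable start."""
    matrix = transitions.as_matrix()
    horizon = settings.horizon_cycles
    occupancy = np.empty((horizon + 1, 3))
    occupancy[0] = (1.0, 0.0, 0.0)
    for t in range(1, horizon + 1):
        occupancy[t] = occupancy[t - 1] @ matrix
    return CohortTrace(occupancy)


def discount_factors(settings: ModelSettings) -> np.ndarray:
    """Discount factors for cycles 1..horizon: ``(1 + r_cycle)**(-t)``."""
    rate = settings.cycle_discount
    t = np.arange(1, settings.horizon_cycles + 1, dtype=float)
    return (1.0 + rate) ** (-t)


def _counted_occupancy(trace: CohortTrace, settings: ModelSettings) -> np.ndarray:
    """Occupancy credited to cycles 1..horizon under the counting convention."""
    occ = trace.occupancy
    if settings.state_counting == "begin":
        return occ[:-1]
    if settings.state_counting == "end":
        return occ[1:]
    return 0.5 * (occ[:-1] + occ[1:])


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted aggregates for one strategy, plus the underlying trace."""

    strategy: str
    life_years: float
    qalys: float
    total_cost: float
    trace: CohortTrace
    settings: ModelSettings

    def __post_init__(self) -> None:
        if self.qalys > self.life_years + 1e-9:
            raise ParameterError("qalys cannot exceed life_years (all utilities <= 1)")


def accrue_outcomes(strategy: StrategyParameters, settings: ModelSettings) -> StrategyOutcome:
    """Run the cohort for one strategy and accrue discounted LY, QALY and cost.

    Costs: drug, tests, outpatient and adverse-event management accrue while
    stable (first-line treatment stops at progression unless
    ``treatment_cost_in_progressive`` is set); the progressive-state cost
    covers subsequent care; societal costs accrue in every alive state when
    ``societal_cost_in_progressive`` is set, otherwise only while stable.
    """
    trace = run_cohort(strategy.transitions, settings)
    occ = _counted_occupancy(trace, settings)
    d = discount_factors(settings)
    ypc = settings.years_per_cycle
    stable, progressive = occ[:, 0], occ[:, 1]

    life_years = float(((stable + progressive) * ypc * d).sum())

    u = strategy.utilities
    ae_decrement = strategy.ae_rate * u.ae_disutility
    u_stable_eff = u.stable
    if settings.ae_disutility_mode == "per_cycle":
        u_stable_eff = max(u.stable - ae_decrement, 0.0)
    qalys = float(((stable * u_stable_eff + progressive * u.progressive) * ypc * d).sum())
    if settings.ae_disutility_mode == "one_time":
        qalys -= ae_decrement
    elif settings.ae_disutility_mode == "duration_limited":
        k = min(settings.ae_duration_cycles, settings.horizon_cycles)
        qalys -= float(ae_decrement * ypc * d[:k].sum())

    c = strategy.costs
    stable_cost = c.drug + c.tests + c.outpatient + c.adverse_events + c.societal
    progressive_cost = c.progressive_state
    if settings.societal_cost_in_progressive:
        progressive_cost += c.societal
    if settings.treatment_cost_in_progressive:
        progressive_cost += c.drug + c.tests + c.outpatient
    total_cost = float(((stable * stable_cost + progressive * progressive_cost) * d).sum())

    return StrategyOutcome(
        strategy=strategy.name,
        life_years=life_years,
        qalys=qalys,
        total_cost=total_cost,
        trace=trace,
        settings=settings,
    )
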