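"""Incremental cost-effectiveness comparison of two strategies.

Deltas are always reference minus comparator.  The ICER is ``delta_cost /
delta_effect`` and is undefined (None) when the effect difference is zero.
Dominance uses the strict quadrant convention: the reference strategy
dominates only when it is both strictly cheaper and strictly more effective
(in QALYs).  A negative ICER in the dominant quadrant is reported
numerically but is never compared against the willingness-to-pay
threshold; in the trade-off quadrants cost-effectiveness is ``ICER <= WTP``
when QALYs are gained and ``ICER >= WTP`` when QALYs are given up for
savings.  The net monetary benefit ``NMB = WTP * delta_qaly - delta_cost``
is positive exactly when the reference is cost-effective at that WTP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

from .markov import StrategyOutcome, accrue_outcomes

if TYPE_CHECKING:  # pragma: no cover
    from .config import CEAConfig

__all__ = [
    "CEAOutcome",
    "BaseCaseReport",
    "MismatchedSettingsError",
    "compare",
    "full_base_case",
    "DOMINANCE_LABELS",
]

DOMINANCE_LABELS = (
    "reference_dominant",
    "comparator_dominant",
    "tradeoff_cost_effective",
    "tradeoff_not_cost_effective",
    "equivalent",
)


class MismatchedSettingsError(ValueError):
    """The two outcomes were produced under different model settings."""


@dataclass(frozen=True)
class CEAOutcome:
    """Incremental comparison of a reference strategy against a comparator."""

    reference_name: str
    comparator_name: str
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_ly: float | None
    icer_per_qaly: float | None
    nmb_at_wtp: float
    wtp: float
    dominance: str

    def to_dict(self) -> dict:
        return {
            "reference": self.reference_name,
            "comparator": self.comparator_name,
            "delta_cost_usd": self.delta_cost,
            "delta_ly": self.delta_ly,
            "delta_qaly": self.delta_qaly,
            "icer_per_ly_usd": self.icer_per_ly,
            "icer_per_qaly_usd": self.icer_per_qaly,
            "nmb_at_wtp_usd": self.nmb_at_wtp,
            "wtp_usd_per_qaly": self.wtp,
            "dominance": self.dominance,
        }


def _classify(delta_cost: float, delta_qaly: float, wtp: float) -> str:
    if delta_cost == 0.0 and delta_qaly == 0.0:
        return "equivalent"
    if delta_cost < 0.0 and delta_qaly > 0.0:
        return "reference_dominant"
    if delta_cost > 0.0 and delta_qaly < 0.0:
        return "comparator_dominant"
    if delta_qaly > 0.0:  # delta_cost >= 0: paying for health gained
        return (
            "tradeoff_cost_effective"
            if delta_cost / delta_qaly <= wtp
            else "tradeoff_not_cost_effective"
        )
    if delta_qaly < 0.0:  # delta_cost <= 0: savings for health forgone
        return (
            "tradeoff_cost_effective"
            if delta_cost / delta_qaly >= wtp
            else "tradeoff_not_cost_effective"
        )
    # delta_qaly == 0, delta_cost != 0: classify by sign of the NMB
    return "tradeoff_cost_effective" if delta_cost < 0.0 else "tradeoff_not_cost_effective"


def compare(
    reference: StrategyOutcome, comparator: StrategyOutcome, wtp: float | None = None
) -> CEAOutcome:
    """Incremental comparison of two strategy outcomes at a WTP threshold.

    ``wtp`` defaults to the threshold stored in the outcomes' shared model
    settings.  Raises :class:`MismatchedSettingsError` if the two outcomes
    were produced under different settings.
    """
    if reference.settings != comparator.settings:
        raise MismatchedSettingsError(
            "reference and comparator were run under different model settings"
        )
    if wtp is None:
        wtp = reference.settings.wtp
    delta_cost = reference.total_cost - comparator.total_cost
    delta_ly = reference.life_years - comparator.life_years
    delta_qaly = reference.qalys - comparator.qalys
    return CEAOutcome(
        reference_name=reference.strategy,
        comparator_name=comparator.strategy,
        delta_cost=delta_cost,
        delta_ly=delta_ly,
        delta_qaly=delta_qaly,
        icer_per_ly=None if delta_ly == 0.0 else delta_cost / delta_ly,
        icer_per_qaly=None if delta_qaly == 0.0 else delta_cost / delta_qaly,
        nmb_at_wtp=wtp * delta_qaly - delta_cost,
        wtp=wtp,
        dominance=_classify(delta_cost, delta_qaly, wtp),
    )


@dataclass(frozen=True)
class BaseCaseReport:
    """Per-strategy aggregates plus the incremental comparison."""

    reference: StrategyOutcome
    comparator: StrategyOutcome
    comparison: CEAOutcome

    def summary_frame(self):
        """Per-strategy discounted LY / QALY / cost table."""
        import pandas as pd

        return pd.DataFrame(
            {
                "strategy": [self.reference.strategy, self.comparator.strategy],
                "life_years": [self.reference.life_years, self.comparator.life_years],
                "qalys": [self.reference.qalys, self.comparator.qalys],
                "total_cost_usd": [self.reference.total_cost, self.comparator.total_cost],
            }
        )

    def to_dict(self) -> dict:
        return {
            "strategies": {
                outcome.strategy: {
                    "life_years": outcome.life_years,
                    "qalys": outcome.qalys,
                    "total_cost_usd": outcome.total_cost,
                    "dead_fraction_at_horizon": float(outcome.trace.dead[-1]),
                }
                for outcome in (self.reference, self.comparator)
            },
            "comparison": self.comparison.to_dict(),
        }


def full_base_case(config: "CEAConfig") -> BaseCaseReport:
    """Run both strategies of a configuration and compare them."""
    reference = accrue_outcomes(config.strategy(config.reference), config.settings)
    comparator = accrue_outcomes(config.strategy(config.comparator), config.settings)
    return BaseCaseReport(
        reference=reference,
        comparator=comparator,
        comparison=compare(reference, comparator, config.settings.wtp),
    )
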