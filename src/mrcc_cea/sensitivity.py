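"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) analysis reruns the full comparison with a single
parameter pushed to its low and high bound, everything else at base.  Each
row carries the ICER and the net monetary benefit at both bounds; rows are
ranked by the spread of the chosen metric.  NMB is the default ranking
metric because the base case is dominance: the ICER's denominator (the
QALY difference) can pass through zero inside a parameter's range, which
makes ICER intervals explode and their widths meaningless, while the NMB
is linear in both deltas.

Probabilistic sensitivity analysis samples every varied parameter
independently from its fitted beta/gamma distribution, reruns both
strategies per draw, and records the incremental cost and QALY pair.  The
cost-effectiveness acceptability curve is the fraction of draws with
positive net monetary benefit across a willingness-to-pay grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cea import full_base_case
from .config import CEAConfig

__all__ = [
    "OWSARow",
    "PSAResult",
    "CEACCurve",
    "one_way_sensitivity",
    "owsa_frame",
    "run_psa",
    "ceac",
    "plot_tornado",
    "plot_ceac",
    "plot_psa_scatter",
]

logger = logging.getLogger(__name__)

DISCOUNT_PARAMETER = "settings.annual_discount"
#: the discount rate is varied over 0-8% annually, not +/-20%
DISCOUNT_BOUNDS = (0.0, 0.08)


@dataclass(frozen=True)
class OWSARow:
    """Outcome interval from varying one parameter over its range."""

    parameter: str
    low_value: float
    high_value: float
    icer_at_low: float | None
    icer_at_high: float | None
    nmb_at_low: float
    nmb_at_high: float
    metric: str

    @property
    def spread(self) -> float:
        """Absolute width of the outcome interval on the ranking metric."""
        if self.metric == "nmb":
            return abs(self.nmb_at_high - self.nmb_at_low)
        low = math.inf if self.icer_at_low is None else self.icer_at_low
        high = math.inf if self.icer_at_high is None else self.icer_at_high
        return abs(high - low)


def _clamp_bound(config: CEAConfig, key: str, low: float, high: float) -> tuple[float, float]:
    """Clamp bounds that would break a structural invariant with all other
    parameters held at base (utility ordering, stable-state exit mass)."""
    clamped_low, clamped_high = low, high
    if key == "utility.stable":
        clamped_low = max(low, config.value("utility.progressive"))
    elif key == "utility.progressive":
        clamped_high = min(high, config.value("utility.stable"))
    elif key.endswith(".p_stable_to_progressive"):
        arm = key.rsplit(".", 1)[0]
        clamped_high = min(high, 1.0 - config.value(f"{arm}.p_stable_to_dead"))
    elif key.endswith(".p_stable_to_dead"):
        arm = key.rsplit(".", 1)[0]
        clamped_high = min(high, 1.0 - config.value(f"{arm}.p_stable_to_progressive"))
    if (clamped_low, clamped_high) != (low, high):
        logger.warning(
            "%s: range (%.6g, %.6g) clamped to (%.6g, %.6g) to keep the model feasible",
            key, low, high, clamped_low, clamped_high,
        )
    return clamped_low, clamped_high


def _outcome_at(config: CEAConfig, key: str, bound: float):
    if key == DISCOUNT_PARAMETER:
        perturbed = config.with_values(annual_discount=bound)
    else:
        perturbed = config.with_values({key: bound})
    comparison = full_base_case(perturbed).comparison
    return comparison.icer_per_qaly, comparison.nmb_at_wtp


def one_way_sensitivity(
    config: CEAConfig,
    parameters: Sequence[str] | None = None,
    metric: str = "nmb",
    include_discount: bool = True,
    discount_bounds: tuple[float, float] = DISCOUNT_BOUNDS,
) -> list[OWSARow]:
    """Tornado rows, sorted by descending spread of ``metric`` (nmb or icer).

    ``parameters`` defaults to every varied parameter of the configuration.
    Bounds that would violate a hard invariant (a probability or utility
    above 1) are clamped with a warning.
    """
    if metric not in ("nmb", "icer"):
        raise ValueError(f"metric must be 'nmb' or 'icer', got {metric!r}")
    if parameters is None:
        keys = list(config.varied_parameters())
        if include_discount:
            keys.append(DISCOUNT_PARAMETER)
    else:
        keys = list(parameters)

    rows = []
    for key in keys:
        if key == DISCOUNT_PARAMETER:
            low, high = discount_bounds
        else:
            param = config.parameters[key]
            low, high = param.low, param.high
            if param.family == "beta" and high > 1.0:
                logger.warning("%s: upper bound %.4g clamped to 1", key, high)
                high = 1.0
            low, high = _clamp_bound(config, key, low, high)
        icer_low, nmb_low = _outcome_at(config, key, low)
        icer_high, nmb_high = _outcome_at(config, key, high)
        rows.append(
            OWSARow(
                parameter=key,
                low_value=low,
                high_value=high,
                icer_at_low=icer_low,
                icer_at_high=icer_high,
                nmb_at_low=nmb_low,
                nmb_at_high=nmb_high,
                metric=metric,
            )
        )
    rows.sort(key=lambda row: -row.spread)
    return rows


def owsa_frame(rows: Sequence[OWSARow]) -> pd.DataFrame:
    """Tornado rows as a DataFrame (one row per parameter, widest first)."""
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in rows],
            "low_value": [r.low_value for r in rows],
            "high_value": [r.high_value for r in rows],
            "icer_at_low": [r.icer_at_low for r in rows],
            "icer_at_high": [r.icer_at_high for r in rows],
            "nmb_at_low": [r.nmb_at_low for r in rows],
            "nmb_at_high": [r.nmb_at_high for r in rows],
            "spread": [r.spread for r in rows],
        }
    )


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo draws of the incremental (cost, QALY) pair."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: int
    n: int
    n_resampled: int
    wtp: float
    reference_name: str
    comparator_name: str

    @property
    def draws(self) -> np.ndarray:
        """(n, 2) array of (delta_cost, delta_qaly) pairs."""
        return np.column_stack([self.delta_cost, self.delta_qaly])

    def nmb(self, wtp: float | None = None) -> np.ndarray:
        if wtp is None:
            wtp = self.wtp
        return wtp * self.delta_qaly - self.delta_cost

    def probability_cost_effective(self, wtp: float | None = None) -> float:
        """Fraction of draws with positive net monetary benefit at ``wtp``."""
        return float((self.nmb(wtp) > 0).mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"draw": np.arange(self.n), "delta_cost": self.delta_cost,
             "delta_qaly": self.delta_qaly}
        )


def run_psa(config: CEAConfig, n: int = 1000, seed: int = 0) -> PSAResult:
    """Probabilistic sensitivity analysis with ``n`` seeded Monte Carlo draws.

    Every varied parameter is drawn independently from its fitted
    distribution.  Draws violating a structural invariant — the two exit
    probabilities from the stable state summing past 1, or the progressive
    utility exceeding the stable utility — are rejected and resampled,
    which preserves the stated marginal families; the count of rejections
    is logged and returned.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    distributions = config.distributions()
    keys = list(distributions)
    index = {key: i for i, key in enumerate(keys)}
    matrix = (
        np.column_stack([distributions[key].sample(rng, size=n) for key in keys])
        if keys
        else np.empty((n, 0))
    )

    def _column(key: str) -> np.ndarray:
        if key in index:
            return matrix[:, index[key]]
        return np.full(n, config.value(key))

    def _infeasible_rows() -> np.ndarray:
        bad = np.zeros(n, dtype=bool)
        for arm in config.strategy_names:
            bad |= (
                _column(f"{arm}.p_stable_to_progressive")
                + _column(f"{arm}.p_stable_to_dead")
                > 1.0
            )
        bad |= _column("utility.progressive") > _column("utility.stable")
        return np.flatnonzero(bad)

    n_resampled = 0
    bad = _infeasible_rows()
    while bad.size:
        n_resampled += int(bad.size)
        for key in keys:
            matrix[bad, index[key]] = distributions[key].sample(rng, size=bad.size)
        bad = _infeasible_rows()

    delta_cost = np.empty(n)
    delta_qaly = np.empty(n)
    for i in range(n):
        sample = {key: float(matrix[i, index[key]]) for key in keys}
        comparison = full_base_case(config.with_values(sample)).comparison
        delta_cost[i] = comparison.delta_cost
        delta_qaly[i] = comparison.delta_qaly
    if n_resampled:
        logger.info("PSA rejected and resampled %d infeasible draws", n_resampled)
    return PSAResult(
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        seed=seed,
        n=n,
        n_resampled=n_resampled,
        wtp=config.settings.wtp,
        reference_name=config.reference,
        comparator_name=config.comparator,
    )


@dataclass(frozen=True)
class CEACCurve:
    """Probability the reference strategy is cost-effective vs the WTP grid."""

    wtp_grid: np.ndarray
    prob_cost_effective: np.ndarray

    def __post_init__(self) -> None:
        if len(self.wtp_grid) != len(self.prob_cost_effective):
            raise ValueError("grid and probabilities must have equal length")
        if len(self.wtp_grid) == 0:
            raise ValueError("empty WTP grid")
        if np.any(np.diff(self.wtp_grid) <= 0):
            raise ValueError("WTP grid must be strictly ascending")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wtp": self.wtp_grid, "prob_cost_effective": self.prob_cost_effective}
        )


def ceac(psa: PSAResult, wtp_grid: np.ndarray | None = None) -> CEACCurve:
    """Cost-effectiveness acceptability curve from PSA draws.

    The default grid spans 0 to three times the configured WTP threshold in
    100 steps.  At each grid point the probability is the fraction of draws
    with ``wtp * delta_qaly - delta_cost > 0``.
    """
    if psa.n == 0:
        raise ValueError("PSA result has no draws")
    if wtp_grid is None:
        wtp_grid = np.linspace(0.0, 3.0 * psa.wtp, 101)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    nmb = wtp_grid[:, None] * psa.delta_qaly[None, :] - psa.delta_cost[None, :]
    return CEACCurve(wtp_grid=wtp_grid, prob_cost_effective=(nmb > 0).mean(axis=1))


# ---------------------------------------------------------------------------
# plotting conveniences (files only; the data tables are the primary output)
# ---------------------------------------------------------------------------

def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_tornado(rows: Sequence[OWSARow], path, top: int = 12) -> None:
    """Horizontal tornado bar chart of the widest ``top`` parameters."""
    plt = _pyplot()
    rows = list(rows)[:top][::-1]
    if rows and rows[0].metric == "nmb":
        lows = [r.nmb_at_low for r in rows]
        highs = [r.nmb_at_high for r in rows]
        xlabel = "net monetary benefit (USD)"
    else:
        lows = [r.icer_at_low if r.icer_at_low is not None else np.nan for r in rows]
        highs = [r.icer_at_high if r.icer_at_high is not None else np.nan for r in rows]
        xlabel = "ICER (USD/QALY)"
    labels = [r.parameter for r in rows]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(rows) + 1.5))
    for i, (lo, hi) in enumerate(zip(lows, highs)):
        ax.barh(i, hi - lo, left=lo, color="#4878b0", height=0.6)
    ax.set_yticks(range(len(labels)), labels, fontsize=8)
    ax.set_xlabel(xlabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: CEACCurve, path) -> None:
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.wtp_grid, curve.prob_cost_effective)
    ax.set_xlabel("willingness to pay (USD/QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_psa_scatter(psa: PSAResult, path, wtp: float | None = None) -> None:
    plt = _pyplot()
    if wtp is None:
        wtp = psa.wtp
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa.delta_qaly, psa.delta_cost, s=6, alpha=0.4)
    q = np.linspace(*ax.get_xlim(), 10)
    ax.plot(q, wtp * q, "k--", lw=1, label=f"WTP = {wtp:,.0f} USD/QALY")
    ax.axhline(0, color="grey", lw=0.6)
    ax.axvline(0, color="grey", lw=0.6)
    ax.set_xlabel(f"incremental QALYs ({psa.reference_name} - {psa.comparator_name})")
    ax.set_ylabel("incremental cost (USD)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
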