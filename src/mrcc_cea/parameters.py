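"""Model inputs and their derivations.

Everything the decision model consumes lives here as a small validated
type: trial summary statistics (median PFS/OS, grade>=3 adverse-event
incidence), per-cycle transition probabilities, health-state utilities,
per-cycle cost components, global model settings, and the probability
distributions used by probabilistic sensitivity analysis.

The central derivation is the constant-hazard conversion from a median
time-to-event ``m`` to a per-cycle transition probability::

    p = 1 - 0.5**(cycle_length / m)

which is the discrete-time restatement of ``p = 1 - exp(-R * c)`` with
hazard ``R = ln(2) / m``.  Probabilities for death after progression use
the post-progression interval ``median_os - median_pfs``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ParameterError",
    "TrialSummary",
    "TransitionProbabilities",
    "UtilitySet",
    "CostSet",
    "ModelSettings",
    "StrategyParameters",
    "ParameterDistribution",
    "median_to_cycle_prob",
    "cycle_prob_to_median",
    "derive_transitions",
    "annual_to_cycle_discount",
    "fit_distribution",
]

#: ratio of a 95% normal interval width to the standard deviation
_RANGE_TO_SD = 2.0 * 1.959963984540054


class ParameterError(ValueError):
    """A model input violates one of its invariants."""


def _check(condition: bool, message: str) -> None:
    if not condition:
        raise ParameterError(message)


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------

def median_to_cycle_prob(median_time: float, cycle_length: float = 1.0) -> float:
    """Per-cycle event probability implied by a median time-to-event.

    Parameters
    ----------
    median_time : float
        Median time to the event, in months. Must be positive.
    cycle_length : float
        Model cycle length in months (default one month).

    Returns
    -------
    float
        ``1 - 0.5**(cycle_length / median_time)``, the probability that a
        subject with constant hazard ``ln(2)/median_time`` experiences the
        event within one cycle.
    """
    _check(median_time > 0, f"median_time must be > 0, got {median_time}")
    _check(cycle_length > 0, f"cycle_length must be > 0, got {cycle_length}")
    return 1.0 - 0.5 ** (cycle_length / median_time)


def cycle_prob_to_median(prob: float, cycle_length: float = 1.0) -> float:
    """Invert :func:`median_to_cycle_prob`: median implied by a per-cycle probability."""
    _check(0.0 < prob < 1.0, f"prob must be in (0, 1), got {prob}")
    _check(cycle_length > 0, f"cycle_length must be > 0, got {cycle_length}")
    return cycle_length * math.log(0.5) / math.log(1.0 - prob)


def annual_to_cycle_discount(
    annual_rate: float, cycle_length_months: float = 1.0, compounding: str = "compound"
) -> float:
    """Convert an annual discount rate to the per-cycle rate.

    ``compound`` (default) uses the compound-equivalent rate
    ``(1 + r)**(c/12) - 1`` which preserves the annual rate exactly over a
    year of cycles; ``simple`` divides the rate proportionally (``r * c/12``).
    """
    _check(annual_rate >= -1.0, f"annual discount rate must be >= -1, got {annual_rate}")
    _check(cycle_length_months > 0, "cycle_length_months must be > 0")
    fraction = cycle_length_months / 12.0
    if compounding == "compound":
        return (1.0 + annual_rate) ** fraction - 1.0
    if compounding == "simple":
        return annual_rate * fraction
    raise ParameterError(f"unknown compounding convention {compounding!r}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialSummary:
    """Arm-level summary statistics of a two-arm trial.

    ``median_os`` and ``median_pfs`` are in months; ``ae_grade3_rate`` is the
    incidence of grade>=3 adverse events as a proportion.
    """

    arm_name: str
    median_os: float
    median_pfs: float
    ae_grade3_rate: float

    def __post_init__(self) -> None:
        _check(self.median_os > 0, f"{self.arm_name}: median_os must be > 0")
        _check(self.median_pfs > 0, f"{self.arm_name}: median_pfs must be > 0")
        _check(
            self.median_pfs <= self.median_os,
            f"{self.arm_name}: median_pfs ({self.median_pfs}) cannot exceed "
            f"median_os ({self.median_os})",
        )
        _check(
            0.0 <= self.ae_grade3_rate <= 1.0,
            f"{self.arm_name}: ae_grade3_rate must be in [0, 1]",
        )


@dataclass(frozen=True)
class TransitionProbabilities:
    """Per-cycle transition probabilities of the three-state model."""

    stable_to_progressive: float
    stable_to_dead: float
    progressive_to_dead: float

    def __post_init__(self) -> None:
        for name in ("stable_to_progressive", "stable_to_dead", "progressive_to_dead"):
            value = getattr(self, name)
            _check(0.0 <= value <= 1.0, f"{name} must be in [0, 1], got {value}")
        _check(
            self.stable_to_progressive + self.stable_to_dead <= 1.0,
            "stable_to_progressive + stable_to_dead exceeds 1: "
            f"{self.stable_to_progressive} + {self.stable_to_dead}",
        )

    def as_matrix(self) -> np.ndarray:
        """Row-stochastic 3x3 matrix over states (stable, progressive, dead)."""
        p_sp, p_sd, p_pd = (
            self.stable_to_progressive,
            self.stable_to_dead,
            self.progressive_to_dead,
        )
        return np.array(
            [
                [1.0 - p_sp - p_sd, p_sp, p_sd],
                [0.0, 1.0 - p_pd, p_pd],
                [0.0, 0.0, 1.0],
            ]
        )


def derive_transitions(summary: TrialSummary, cycle_length: float = 1.0) -> TransitionProbabilities:
    """Derive per-cycle transition probabilities from trial medians.

    Progression (stable -> progressive) comes from the PFS median, death from
    the stable state from the OS median, and death after progression from the
    post-progression interval ``median_os - median_pfs``.
    """
    pd_interval = summary.median_os - summary.median_pfs
    _check(
        pd_interval > 0,
        f"{summary.arm_name}: post-progression interval (median_os - median_pfs) "
        f"must be positive, got {pd_interval}",
    )
    return TransitionProbabilities(
        stable_to_progressive=median_to_cycle_prob(summary.median_pfs, cycle_length),
        stable_to_dead=median_to_cycle_prob(summary.median_os, cycle_length),
        progressive_to_dead=median_to_cycle_prob(pd_interval, cycle_length),
    )


@dataclass(frozen=True)
class UtilitySet:
    """Annual quality-of-life weights. Death is fixed at 0 and is not a field."""

    stable: float
    progressive: float
    ae_disutility: float

    def __post_init__(self) -> None:
        _check(0.0 <= self.stable <= 1.0, f"stable utility must be in [0, 1], got {self.stable}")
        _check(
            0.0 <= self.progressive <= 1.0,
            f"progressive utility must be in [0, 1], got {self.progressive}",
        )
        _check(
            self.progressive <= self.stable,
            f"progressive utility ({self.progressive}) cannot exceed stable "
            f"utility ({self.stable})",
        )
        _check(self.ae_disutility >= 0, "ae_disutility must be >= 0")


@dataclass(frozen=True)
class CostSet:
    """Per-cycle cost components in USD."""

    drug: float
    tests: float
    outpatient: float
    societal: float
    adverse_events: float
    progressive_state: float

    def __post_init__(self) -> None:
        for name in (
            "drug",
            "tests",
            "outpatient",
            "societal",
            "adverse_events",
            "progressive_state",
        ):
            _check(getattr(self, name) >= 0, f"cost component {name} must be >= 0")


@dataclass(frozen=True)
class ModelSettings:
    """Global simulation settings and reward conventions.

    The convention switches (``state_counting``, ``ae_disutility_mode``,
    ``discount_compounding`` and the cost-attribution flags) exist because
    decision-analytic software differs on them; the defaults are the
    calibrated conventions described in docs/methods.md.

    Attributes
    ----------
    cycle_length_months : float
        Length of one Markov cycle, months.
    horizon_cycles : int
        Number of cycles simulated (120 monthly cycles = 10 years).
    annual_discount : float
        Annual discount rate applied to costs, LYs and QALYs.
    wtp : float
        Willingness-to-pay threshold in USD per QALY.
    state_counting : str
        Where within a cycle state membership is counted: ``begin``, ``end``
        or ``half`` (half-cycle correction).
    discount_compounding : str
        ``compound`` for ``(1+r)**(c/12)-1`` per cycle, ``simple`` for ``r*c/12``.
    ae_disutility_mode : str
        ``per_cycle``: stable-state utility reduced by ae_rate*disutility while
        on treatment; ``one_time``: a single undiscounted QALY lump
        ae_rate*disutility at model entry; ``duration_limited``: the decrement
        applied for ``ae_duration_cycles`` cycles only.
    ae_duration_cycles : int
        Duration for the ``duration_limited`` mode.
    societal_cost_in_progressive : bool
        Whether societal costs accrue in the progressive state as well.
    treatment_cost_in_progressive : bool
        Whether first-line treatment costs continue after progression
        (treatment normally stops at progression).
    """

    cycle_length_months: float = 1.0
    horizon_cycles: int = 120
    annual_discount: float = 0.05
    wtp: float = 34340.50
    state_counting: str = "begin"
    discount_compounding: str = "compound"
    ae_disutility_mode: str = "per_cycle"
    ae_duration_cycles: int = 1
    societal_cost_in_progressive: bool = True
    treatment_cost_in_progressive: bool = False

    def __post_init__(self) -> None:
        _check(self.cycle_length_months > 0, "cycle_length_months must be > 0")
        _check(self.horizon_cycles >= 1, "horizon_cycles must be >= 1")
        _check(self.annual_discount >= 0, "annual_discount must be >= 0")
        _check(self.wtp >= 0, "wtp must be >= 0")
        _check(
            self.state_counting in ("begin", "end", "half"),
            f"state_counting must be begin/end/half, got {self.state_counting!r}",
        )
        _check(
            self.discount_compounding in ("compound", "simple"),
            f"discount_compounding must be compound/simple, got {self.discount_compounding!r}",
        )
        _check(
            self.ae_disutility_mode in ("per_cycle", "one_time", "duration_limited"),
            "ae_disutility_mode must be per_cycle/one_time/duration_limited, "
            f"got {self.ae_disutility_mode!r}",
        )
        _check(self.ae_duration_cycles >= 0, "ae_duration_cycles must be >= 0")

    @property
    def cycle_discount(self) -> float:
        """Per-cycle discount rate under the configured compounding."""
        return annual_to_cycle_discount(
            self.annual_discount, self.cycle_length_months, self.discount_compounding
        )

    @property
    def years_per_cycle(self) -> float:
        return self.cycle_length_months / 12.0


@dataclass(frozen=True)
class StrategyParameters:
    """One treatment arm: transitions, utilities, costs and AE incidence."""

    name: str
    transitions: TransitionProbabilities
    utilities: UtilitySet
    costs: CostSet
    ae_rate: float

    def __post_init__(self) -> None:
        _check(0.0 <= self.ae_rate <= 1.0, f"{self.name}: ae_rate must be in [0, 1]")


# ---------------------------------------------------------------------------
# PSA distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterDistribution:
    """A sampling specification for probabilistic sensitivity analysis.

    ``family`` is ``beta`` (probabilities and utilities), ``gamma`` (costs) or
    ``degenerate`` (fixed at the mean).  ``shape_params`` holds (alpha, beta)
    for the beta family and (shape, scale) for the gamma family.
    """

    family: str
    mean: float
    low: float
    high: float
    shape_params: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        _check(
            self.family in ("beta", "gamma", "degenerate"),
            f"unknown distribution family {self.family!r}",
        )
        _check(
            self.low <= self.mean <= self.high,
            f"require low <= mean <= high, got {self.low}, {self.mean}, {self.high}",
        )

    def frozen(self):
        """The scipy frozen distribution, or None for the degenerate family."""
        if self.family == "beta":
            return stats.beta(*self.shape_params)
        if self.family == "gamma":
            shape, scale = self.shape_params
            return stats.gamma(shape, scale=scale)
        return None

    def sample(self, rng: np.random.Generator, size=None):
        """Draw from the distribution using ``rng``; degenerate returns the mean."""
        dist = self.frozen()
        if dist is None:
            if size is None:
                return self.mean
            return np.full(size, self.mean)
        return dist.rvs(size=size, random_state=rng)


def fit_distribution(
    family: str, mean: float, low: float, high: float
) -> ParameterDistribution:
    """Method-of-moments fit of a PSA distribution from a base value and range.

    The (low, high) range is interpreted as a 95% interval, so
    ``sd = (high - low) / 3.92``.  The fitted distribution's mean equals the
    base-case mean exactly (to floating-point precision) by construction.
    A zero-width range, or ``family="degenerate"``, yields the degenerate
    distribution that always returns the mean.
    """
    _check(low <= mean <= high, f"require low <= mean <= high, got {low}, {mean}, {high}")
    sd = (high - low) / _RANGE_TO_SD
    if family == "degenerate" or sd == 0.0:
        return ParameterDistribution("degenerate", mean, low, high)
    var = sd * sd
    if family == "beta":
        _check(0.0 <= low and high <= 1.0, "beta family requires the range within [0, 1]")
        _check(0.0 < mean < 1.0, f"beta family requires mean in (0, 1), got {mean}")
        nu = mean * (1.0 - mean) / var - 1.0
        _check(
            nu > 0.0,
            f"infeasible beta moments: variance {var:.6g} >= mean*(1-mean) "
            f"= {mean * (1 - mean):.6g}",
        )
        return ParameterDistribution("beta", mean, low, high, (mean * nu, (1.0 - mean) * nu))
    if family == "gamma":
        _check(mean > 0.0, "gamma family requires a positive mean")
        _check(low >= 0.0, "gamma family requires a non-negative range")
        return ParameterDistribution("gamma", mean, low, high, (mean * mean / var, var / mean))
    raise ParameterError(f"unknown distribution family {family!r}")
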