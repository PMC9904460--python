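"""Synthetic two-arm trial generator.

Generates patient-level data with exactly the statistical structure the
decision model assumes: progression-free survival times are exponential
with hazard ``ln(2)/median_pfs``; overall survival is PFS plus an
independent exponential post-progression time with hazard
``ln(2)/(median_os - median_pfs)``; grade>=3 adverse events are Bernoulli.
Because the constant-hazard assumption is shared, the generator and the
median-to-probability conversion are mutually consistent by construction,
so the full medians -> transition probabilities -> cohort model pipeline
can be exercised end-to-end without external data.

Default arm sizes (90 / 43) mirror the phase II trial the base-case
parameters come from.  An administrative-censoring hook exists (off by
default); with censoring, medians are estimated by Kaplan-Meier instead of
the sample median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import ParameterError, TrialSummary

__all__ = [
    "ArmSpec",
    "SyntheticTrial",
    "simulate_trial",
    "estimate_summary",
    "DEFAULT_ARMS",
]

_LN2 = math.log(2.0)

_COLUMNS = ["arm", "pfs_months", "os_months", "ae_grade3", "pfs_event", "os_event"]


@dataclass(frozen=True)
class ArmSpec:
    """Generating parameters of one arm: medians in months, AE rate, size."""

    name: str
    median_pfs: float
    median_os: float
    ae_rate: float
    n: int

    def __post_init__(self) -> None:
        if not 0 < self.median_pfs < self.median_os:
            raise ParameterError(
                f"{self.name}: require 0 < median_pfs < median_os, "
                f"got {self.median_pfs}, {self.median_os}"
            )
        if not 0.0 <= self.ae_rate <= 1.0:
            raise ParameterError(f"{self.name}: ae_rate must be in [0, 1]")
        if self.n < 1:
            raise ParameterError(f"{self.name}: arm size must be >= 1")


DEFAULT_ARMS = (
    ArmSpec("anlotinib", median_pfs=17.5, median_os=30.9, ae_rate=0.289, n=90),
    ArmSpec("sunitinib", median_pfs=16.6, median_os=30.5, ae_rate=0.558, n=43),
)


@dataclass(frozen=True)
class SyntheticTrial:
    """Patient-level data of a simulated two-arm trial."""

    data: pd.DataFrame
    seed: int | None
    arm_specs: Mapping[str, ArmSpec]

    @property
    def arm_names(self) -> tuple[str, ...]:
        return tuple(self.arm_specs) if self.arm_specs else tuple(self.data["arm"].unique())

    def arm(self, name: str) -> pd.DataFrame:
        subset = self.data[self.data["arm"] == name]
        if subset.empty:
            raise ParameterError(f"arm {name!r} is empty")
        return subset

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SyntheticTrial":
        data = pd.read_csv(path)
        missing = [c for c in ("arm", "pfs_months", "os_months", "ae_grade3") if c not in data]
        if missing:
            raise ParameterError(f"trial CSV missing columns: {missing}")
        for col in ("pfs_event", "os_event"):
            if col not in data:
                data[col] = 1
        return cls(data=data[_COLUMNS], seed=None, arm_specs={})


def simulate_trial(
    arm_specs: Sequence[ArmSpec] = DEFAULT_ARMS,
    seed: int = 0,
    censor_after_months: float | None = None,
) -> SyntheticTrial:
    """Simulate a trial; fully reproducible for a fixed seed.

    With ``censor_after_months`` set, follow-up is administratively cut at
    that time: times are truncated and the event indicators record which
    observations are events (1) versus censored (0).
    """
    rng = np.random.default_rng(seed)
    frames = []
    for spec in arm_specs:
        pfs = rng.exponential(spec.median_pfs / _LN2, spec.n)
        post_progression = rng.exponential((spec.median_os - spec.median_pfs) / _LN2, spec.n)
        os_time = pfs + post_progression
        ae = rng.random(spec.n) < spec.ae_rate
        pfs_event = np.ones(spec.n, dtype=int)
        os_event = np.ones(spec.n, dtype=int)
        if censor_after_months is not None:
            cutoff = float(censor_after_months)
            pfs_event = (pfs <= cutoff).astype(int)
            os_event = (os_time <= cutoff).astype(int)
            pfs = np.minimum(pfs, cutoff)
            os_time = np.minimum(os_time, cutoff)
        frames.append(
            pd.DataFrame(
                {
                    "arm": spec.name,
                    "pfs_months": pfs,
                    "os_months": os_time,
                    "ae_grade3": ae.astype(int),
                    "pfs_event": pfs_event,
                    "os_event": os_event,
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    return SyntheticTrial(data=data, seed=seed, arm_specs={s.name: s for s in arm_specs})


def _median(times: np.ndarray, events: np.ndarray) -> float:
    if events.all():
        return float(np.median(times))
    # censored observations present: Kaplan-Meier median
    from lifelines import KaplanMeierFitter

    fitter = KaplanMeierFitter()
    fitter.fit(times, event_observed=events)
    return float(fitter.median_survival_time_)


def estimate_summary(trial: SyntheticTrial) -> dict[str, TrialSummary]:
    """Per-arm median PFS/OS and AE proportion, ready for transition derivation.

    The PFS median is the sample (or Kaplan-Meier) median of the PFS times.
    The OS median is estimated component-wise as ``median(PFS) +
    median(OS - PFS)``: in the constant-hazard world the model lives in,
    the OS-median parameter is exactly the PFS median plus the
    post-progression median, whereas the raw sample median of the OS times
    estimates the median of the convolution of the two exponentials, which
    is systematically larger than the generating parameter.  The
    component-wise estimator is consistent for the quantity the
    median-to-probability derivation consumes.
    """
    summaries: dict[str, TrialSummary] = {}
    for name in trial.arm_names:
        subset = trial.arm(name)
        pfs = subset["pfs_months"].to_numpy()
        pfs_event = subset["pfs_event"].to_numpy(dtype=bool)
        post_progression = subset["os_months"].to_numpy() - pfs
        os_event = subset["os_event"].to_numpy(dtype=bool)
        median_pfs = _median(pfs, pfs_event)
        # censored-at-progression rows contribute no post-progression time
        observed = post_progression[pfs_event]
        median_pd = _median(observed, os_event[pfs_event])
        summaries[name] = TrialSummary(
            arm_name=name,
            median_os=median_pfs + median_pd,
            median_pfs=median_pfs,
            ae_grade3_rate=float(subset["ae_grade3"].mean()),
        )
    return summaries
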