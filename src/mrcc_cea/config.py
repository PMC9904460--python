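"""Configuration loading, validation and the flat parameter space.

A configuration couples two strategy blocks (transition probabilities or
survival medians, arm-specific costs, AE incidence) with shared utilities,
shared cost components and global model settings.  Internally every
scalar model input lives in a flat map of :class:`ModelParameter` objects
keyed like ``anlotinib.p_stable_to_progressive`` or ``cost.tests``; the
sensitivity analyses vary entries of that map, and typed
:class:`~mrcc_cea.parameters.StrategyParameters` objects are assembled
from it on demand.

Validation is collected, not fail-fast per field: a malformed file raises
:class:`ConfigError` listing every offending field.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .parameters import (
    CostSet,
    ModelSettings,
    ParameterDistribution,
    ParameterError,
    StrategyParameters,
    TransitionProbabilities,
    TrialSummary,
    UtilitySet,
    derive_transitions,
    fit_distribution,
)

__all__ = ["ConfigError", "ModelParameter", "CEAConfig", "load_config", "config_from_dict"]

logger = logging.getLogger(__name__)

#: default one-way / PSA range is +/-20% of the base value
_DEFAULT_RANGE_FRACTION = 0.20

_TRANSITION_KEYS = ("p_stable_to_progressive", "p_stable_to_dead", "p_progressive_to_dead")
_UTILITY_KEYS = ("utility.stable", "utility.progressive", "utility.ae_disutility")
_SHARED_COST_KEYS = ("cost.tests", "cost.outpatient", "cost.societal", "cost.progressive_state")


class ConfigError(ValueError):
    """One or more configuration fields are invalid; lists every failure."""

    def __init__(self, errors: Iterable[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.errors))


@dataclass(frozen=True)
class ModelParameter:
    """A scalar model input with its sensitivity range and PSA family."""

    key: str
    value: float
    low: float
    high: float
    family: str  # beta | gamma | degenerate
    vary: bool = True

    def distribution(self) -> ParameterDistribution:
        family = self.family if self.vary else "degenerate"
        return fit_distribution(family, self.value, self.low, self.high)


def _default_range(value: float, family: str) -> tuple[float, float]:
    low = value * (1.0 - _DEFAULT_RANGE_FRACTION)
    high = value * (1.0 + _DEFAULT_RANGE_FRACTION)
    if family == "beta" and high > 1.0:
        logger.warning("range upper bound clamped to 1 for a probability/utility parameter")
        high = 1.0
    return low, high


@dataclass(frozen=True)
class CEAConfig:
    """A validated two-strategy model configuration."""

    reference: str
    comparator: str
    settings: ModelSettings
    parameters: Mapping[str, ModelParameter]
    name: str = "cea-model"
    currency: str = "USD"
    ae_rates: Mapping[str, float] = field(default_factory=dict)

    @property
    def strategy_names(self) -> tuple[str, str]:
        return (self.reference, self.comparator)

    def value(self, key: str) -> float:
        return self.parameters[key].value

    def strategy(self, name: str) -> StrategyParameters:
        """Assemble the typed parameter bundle for one arm."""
        if name not in self.strategy_names:
            raise KeyError(f"unknown strategy {name!r}; have {self.strategy_names}")
        transitions = TransitionProbabilities(
            stable_to_progressive=self.value(f"{name}.p_stable_to_progressive"),
            stable_to_dead=self.value(f"{name}.p_stable_to_dead"),
            progressive_to_dead=self.value(f"{name}.p_progressive_to_dead"),
        )
        utilities = UtilitySet(
            stable=self.value("utility.stable"),
            progressive=self.value("utility.progressive"),
            ae_disutility=self.value("utility.ae_disutility"),
        )
        costs = CostSet(
            drug=self.value(f"{name}.drug_cost"),
            tests=self.value("cost.tests"),
            outpatient=self.value("cost.outpatient"),
            societal=self.value("cost.societal"),
            adverse_events=self.value(f"{name}.ae_cost"),
            progressive_state=self.value("cost.progressive_state"),
        )
        return StrategyParameters(
            name=name,
            transitions=transitions,
            utilities=utilities,
            costs=costs,
            ae_rate=self.ae_rates[name],
        )

    def varied_parameters(self) -> dict[str, ModelParameter]:
        return {k: p for k, p in self.parameters.items() if p.vary and p.low < p.high}

    def distributions(self) -> dict[str, ParameterDistribution]:
        """Fitted PSA distributions for every varied parameter."""
        return {k: p.distribution() for k, p in self.varied_parameters().items()}

    def with_values(
        self,
        overrides: Mapping[str, float] | None = None,
        annual_discount: float | None = None,
        settings: ModelSettings | None = None,
    ) -> "CEAConfig":
        """A copy with some parameter values (and/or settings) replaced."""
        params = dict(self.parameters)
        for key, value in (overrides or {}).items():
            if key not in params:
                raise KeyError(f"unknown parameter {key!r}")
            old = params[key]
            params[key] = ModelParameter(key, float(value), old.low, old.high, old.family, old.vary)
        new_settings = settings if settings is not None else self.settings
        if annual_discount is not None:
            new_settings = replace(new_settings, annual_discount=annual_discount)
        return replace(self, parameters=params, settings=new_settings)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "currency": self.currency,
            "reference": self.reference,
            "comparator": self.comparator,
            "settings": {
                "cycle_length_months": self.settings.cycle_length_months,
                "horizon_cycles": self.settings.horizon_cycles,
                "annual_discount": self.settings.annual_discount,
                "wtp": self.settings.wtp,
                "state_counting": self.settings.state_counting,
                "discount_compounding": self.settings.discount_compounding,
                "ae_disutility_mode": self.settings.ae_disutility_mode,
                "ae_duration_cycles": self.settings.ae_duration_cycles,
                "societal_cost_in_progressive": self.settings.societal_cost_in_progressive,
                "treatment_cost_in_progressive": self.settings.treatment_cost_in_progressive,
            },
            "ae_rates": dict(self.ae_rates),
            "parameters": {
                k: {"value": p.value, "low": p.low, "high": p.high,
                    "family": p.family, "vary": p.vary}
                for k, p in sorted(self.parameters.items())
            },
        }

    def digest(self) -> str:
        """SHA-256 of the canonical JSON form, for run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _parse_entry(raw, key: str, family: str, errors: list[str],
                 vary: bool = True) -> ModelParameter | None:
    """One scalar entry: either a bare number or {value, low, high, vary}."""
    try:
        if isinstance(raw, Mapping):
            value = float(raw["value"])
            vary = bool(raw.get("vary", vary))
            if "low" in raw or "high" in raw:
                low = float(raw["low"])
                high = float(raw["high"])
            else:
                low, high = _default_range(value, family)
        else:
            value = float(raw)
            low, high = _default_range(value, family)
    except (TypeError, KeyError, ValueError):
        errors.append(f"{key}: expected a number or a {{value, low, high}} mapping, got {raw!r}")
        return None
    if not low <= value <= high:
        errors.append(f"{key}: require low <= value <= high, got {low}, {value}, {high}")
        return None
    if family == "beta" and not (0.0 <= low and high <= 1.0):
        errors.append(
            f"{key}: probability/utility and its range must lie in [0, 1], "
            f"got value {value} with range ({low}, {high})"
        )
        return None
    if family == "gamma" and low < 0.0:
        errors.append(f"{key}: cost values must be >= 0, got range ({low}, {high})")
        return None
    return ModelParameter(key, value, low, high, family, vary)


def _strategy_transitions(name: str, block: Mapping, cycle_length: float,
                          params: dict, errors: list[str]) -> None:
    """Fill the three transition-probability parameters for one arm.

    Accepts either an explicit ``transitions`` block or survival ``medians``
    (``{pfs, os}``), which are converted with the constant-hazard formula.
    """
    if "transitions" in block:
        trans = block["transitions"]
        mapping = {
            "p_stable_to_progressive": "stable_to_progressive",
            "p_stable_to_dead": "stable_to_dead",
            "p_progressive_to_dead": "progressive_to_dead",
        }
        for param_key, yaml_key in mapping.items():
            if yaml_key not in trans:
                errors.append(f"{name}.transitions.{yaml_key}: missing")
                continue
            entry = _parse_entry(trans[yaml_key], f"{name}.{param_key}", "beta", errors)
            if entry is not None:
                params[entry.key] = entry
    elif "medians" in block:
        medians = block["medians"]
        try:
            summary = TrialSummary(
                arm_name=name,
                median_pfs=float(medians["pfs"]),
                median_os=float(medians["os"]),
                ae_grade3_rate=0.0,
            )
            derived = derive_transitions(summary, cycle_length)
        except (ParameterError, KeyError, TypeError, ValueError) as exc:
            errors.append(f"{name}.medians: {exc}")
            return
        logger.info(
            "%s: transition probabilities derived from medians PFS=%s OS=%s -> "
            "(%.6f, %.6f, %.6f)",
            name, medians["pfs"], medians["os"],
            derived.stable_to_progressive, derived.stable_to_dead, derived.progressive_to_dead,
        )
        for param_key, value in (
            ("p_stable_to_progressive", derived.stable_to_progressive),
            ("p_stable_to_dead", derived.stable_to_dead),
            ("p_progressive_to_dead", derived.progressive_to_dead),
        ):
            low, high = _default_range(value, "beta")
            params[f"{name}.{param_key}"] = ModelParameter(
                f"{name}.{param_key}", value, low, high, "beta"
            )
    else:
        errors.append(f"strategies.{name}: needs either 'transitions' or 'medians'")


def config_from_dict(data: Mapping) -> CEAConfig:
    """Build and validate a :class:`CEAConfig` from a parsed YAML/JSON mapping."""
    errors: list[str] = []

    settings_raw = dict(data.get("settings", {}))
    if settings_raw.pop("half_cycle_correction", False):
        settings_raw["state_counting"] = "half"
    try:
        settings = ModelSettings(**settings_raw)
    except (ParameterError, TypeError) as exc:
        errors.append(f"settings: {exc}")
        settings = ModelSettings()

    strategies = data.get("strategies", {})
    if len(strategies) < 2:
        errors.append("strategies: at least two strategy blocks are required")
    names = list(strategies)
    reference = data.get("reference", names[0] if names else "")
    comparator = data.get("comparator", names[1] if len(names) > 1 else "")
    for role, who in (("reference", reference), ("comparator", comparator)):
        if who not in strategies:
            errors.append(f"{role}: {who!r} is not a strategy block")

    params: dict[str, ModelParameter] = {}
    for key in _UTILITY_KEYS:
        raw = data.get("utilities", {}).get(key.split(".", 1)[1])
        if raw is None:
            errors.append(f"{key}: missing")
            continue
        entry = _parse_entry(raw, key, "beta", errors)
        if entry is not None:
            params[key] = entry
    for key in _SHARED_COST_KEYS:
        raw = data.get("shared_costs", {}).get(key.split(".", 1)[1])
        if raw is None:
            errors.append(f"{key}: missing")
            continue
        entry = _parse_entry(raw, key, "gamma", errors)
        if entry is not None:
            params[key] = entry

    ae_rates: dict[str, float] = {}
    for name, block in strategies.items():
        if not isinstance(block, Mapping):
            errors.append(f"strategies.{name}: expected a mapping")
            continue
        _strategy_transitions(name, block, settings.cycle_length_months, params, errors)
        for param_key, yaml_key, family in (
            ("drug_cost", "drug_cost", "gamma"),
            ("ae_cost", "ae_cost", "gamma"),
        ):
            if yaml_key not in block:
                errors.append(f"strategies.{name}.{yaml_key}: missing")
                continue
            entry = _parse_entry(block[yaml_key], f"{name}.{param_key}", family, errors)
            if entry is not None:
                params[entry.key] = entry
        try:
            rate = float(block["ae_rate"])
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"must be in [0, 1], got {rate}")
            ae_rates[name] = rate
        except (KeyError, TypeError, ValueError) as exc:
            errors.append(f"strategies.{name}.ae_rate: {exc}")

    config = CEAConfig(
        reference=reference,
        comparator=comparator,
        settings=settings,
        parameters=params,
        name=str(data.get("name", "cea-model")),
        currency=str(data.get("currency", "USD")),
        ae_rates=ae_rates,
    )

    # cross-field invariants: every strategy bundle must construct cleanly
    if not errors:
        for name in config.strategy_names:
            try:
                config.strategy(name)
            except (ParameterError, KeyError) as exc:
                errors.append(f"strategies.{name}: {exc}")
        for key, param in params.items():
            try:
                param.distribution()
            except ParameterError as exc:
                errors.append(f"{key}: {exc}")

    if errors:
        raise ConfigError(errors)
    return config


def load_config(path: str | Path | None = None) -> CEAConfig:
    """Load a YAML/JSON configuration; None loads the bundled base case."""
    if path is None:
        source = resources.files("mrcc_cea").joinpath("data/base_case.yaml")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ConfigError([f"top level of {path or 'bundled base case'} must be a mapping"])
    return config_from_dict(data)
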