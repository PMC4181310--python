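"""Neonatal age estimation from new-hoof growth.

Newborn ungulates grow hoof past the fetal growth-ring line at a roughly
constant rate, so the millimetres of "new" hoof at capture serve as an age
proxy.  Published calibrations are simple linear regressions of age (days)
on new-hoof growth (mm), fitted to captive animals of known age:

    age = intercept + slope * hoof_growth

Intercepts differ widely among calibrations (from -8.29 to +5.29 days),
which is the source of the staggered-entry survival biases this package
quantifies.  This module houses the registry of published calibrations for
white-tailed deer, mule deer and pronghorn, applies them with truncation of
negative estimates at zero (a newborn cannot have negative age), and scores
them against animals of known age.

Age-class convention: an estimated age ``a`` maps to integer day class
``floor(a)``; class 0 means 0-24 h old, class 1 means 24-48 h, and so on.
Known-age newborns (captured at <=24 h) are class 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "WHITE_TAILED_DEER",
    "MULE_DEER",
    "PRONGHORN",
    "HoofGrowthModel",
    "AgeEstimate",
    "AccuracyTable",
    "AgeSummary",
    "lookup_model",
    "register_model",
    "registered_models",
    "estimate_age",
    "estimate_ages",
    "accuracy_table",
    "summarize_estimates",
    "round_half_up",
]

WHITE_TAILED_DEER = "white-tailed deer"
MULE_DEER = "mule deer"
PRONGHORN = "pronghorn"


@dataclass(frozen=True)
class HoofGrowthModel:
    """A published linear age-from-hoof-growth calibration.

    Parameters
    ----------
    name : str
        Calibration name (e.g. ``"Brinkman"``).
    species : str
        Species the calibration applies to.
    intercept : float
        Predicted age in days at zero new-hoof growth.
    slope : float
        Days of age per mm of new-hoof growth; must be positive.
    label : str
        Short cohort code used in survival model specs (B, S, H, HS, R, TG).
    """

    name: str
    species: str
    intercept: float
    slope: float
    label: str

    def __post_init__(self) -> None:
        if not (self.slope > 0):
            raise ValueError(f"slope must be positive, got {self.slope!r}")

    def predict(self, hoof_growth: float) -> float:
        """Raw (untruncated) predicted age in days."""
        return self.intercept + self.slope * hoof_growth


@dataclass(frozen=True)
class AgeEstimate:
    """An age estimate for one animal under one calibration.

    ``raw_age`` may be negative; ``truncated_age = max(0, raw_age)`` and
    ``age_class = floor(truncated_age)``.
    """

    raw_age: float
    truncated_age: float
    age_class: int
    model_name: str


@dataclass(frozen=True)
class AccuracyTable:
    """Proportion of animals classified within each day tolerance.

    ``proportions[i]`` is the fraction of animals whose estimated integer day
    class falls within ``tolerances[i]`` days of the true class; tolerance 0
    is "assigned to the correct age".
    """

    model_name: str
    tolerances: tuple[int, ...]
    proportions: tuple[float, ...]
    n: int


@dataclass(frozen=True)
class AgeSummary:
    mean: float
    se: float
    min: float
    max: float
    n: int


def _load_registry() -> dict[tuple[str, str], HoofGrowthModel]:
    registry: dict[tuple[str, str], HoofGrowthModel] = {}
    text = resources.files("fawnfate").joinpath("data/age_models.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        species, name, label, intercept, slope = line.split("\t")
        registry[(species, name)] = HoofGrowthModel(
            name=name,
            species=species,
            intercept=float(intercept),
            slope=float(slope),
            label=label,
        )
    return registry


_REGISTRY = _load_registry()


def lookup_model(species: str, name: str) -> HoofGrowthModel:
    """Return the registered calibration for a (species, name) pair.

    Raises
    ------
    KeyError
        If the pair is not registered; the message lists valid options.
    """
    try:
        return _REGISTRY[(species, name)]
    except KeyError:
        valid = ", ".join(f"({s}, {n})" for s, n in sorted(_REGISTRY))
        raise KeyError(
            f"no registered age model ({species!r}, {name!r}); valid pairs: {valid}"
        ) from None


def register_model(model: HoofGrowthModel, overwrite: bool = False) -> None:
    """Register an additional calibration (e.g. from a user config)."""
    key = (model.species, model.name)
    if key in _REGISTRY and not overwrite:
        raise ValueError(f"model {key} already registered; pass overwrite=True")
    _REGISTRY[key] = model


def registered_models(species: str | None = None) -> list[HoofGrowthModel]:
    """All registered calibrations, optionally restricted to one species."""
    models = list(_REGISTRY.values())
    if species is not None:
        models = [m for m in models if m.species == species]
    return models


def estimate_age(model: HoofGrowthModel, hoof_growth: float) -> AgeEstimate:
    """Apply a calibration to one hoof-growth measurement.

    Negative raw estimates are truncated to zero before classing, because a
    captured neonate cannot be younger than a newborn.
    """
    if not np.isfinite(hoof_growth) or hoof_growth < 0:
        raise ValueError(f"hoof_growth must be finite and >= 0, got {hoof_growth!r}")
    raw = model.predict(hoof_growth)
    truncated = max(0.0, raw)
    return AgeEstimate(
        raw_age=raw,
        truncated_age=truncated,
        age_class=int(math.floor(truncated)),
        model_name=model.name,
    )


def estimate_ages(model: HoofGrowthModel, hoof_growths: Iterable[float]) -> list[AgeEstimate]:
    return [estimate_age(model, h) for h in hoof_growths]


def _age_class(x: "AgeEstimate | float | int") -> int:
    if isinstance(x, AgeEstimate):
        return x.age_class
    return int(math.floor(x))


def accuracy_table(
    true_ages: Sequence[float],
    estimates: Sequence["AgeEstimate | int"],
    tolerances: Sequence[int] = (0, 1, 2, 3),
    model_name: str = "",
) -> AccuracyTable:
    """Score estimated integer day classes against known day classes.

    The proportion at tolerance ``t`` is the fraction of animals with
    ``|estimated class - true class| <= t``; proportions are necessarily
    non-decreasing in the tolerance.
    """
    if len(true_ages) == 0:
        raise ValueError("cannot score an empty sample")
    if len(true_ages) != len(estimates):
        raise ValueError(
            f"length mismatch: {len(true_ages)} true ages vs {len(estimates)} estimates"
        )
    true_cls = np.array([_age_class(a) for a in true_ages])
    est_cls = np.array([_age_class(e) for e in estimates])
    err = np.abs(est_cls - true_cls)
    props = tuple(float(np.mean(err <= t)) for t in tolerances)
    if not model_name and estimates and isinstance(estimates[0], AgeEstimate):
        model_name = estimates[0].model_name
    return AccuracyTable(
        model_name=model_name,
        tolerances=tuple(int(t) for t in tolerances),
        proportions=props,
        n=len(true_ages),
    )


def summarize_estimates(
    estimates: Sequence[AgeEstimate], use_truncated: bool = False
) -> AgeSummary:
    """Mean, SE and range of a sample of age estimates.

    By default the *raw* (untruncated) ages are summarised — reported
    age-estimate summaries include negative means for calibrations with
    strongly negative intercepts, so raw ages are the replication mode.
    SE is the n-1 sample standard deviation over sqrt(n); a single estimate
    has SE 0 by convention.
    """
    if len(estimates) == 0:
        raise ValueError("cannot summarise an empty sample")
    ages = np.array(
        [e.truncated_age if use_truncated else e.raw_age for e in estimates]
    )
    n = len(ages)
    se = float(np.std(ages, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return AgeSummary(
        mean=float(np.mean(ages)),
        se=se,
        min=float(np.min(ages)),
        max=float(np.max(ages)),
        n=n,
    )


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention used for reported tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
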