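"""Rate arithmetic: population adjustment, treatment-effect mapping,
composite-rate disaggregation, and rate <-> probability conversion."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import BaselineRates, UncertainParam, ValidationError

__all__ = [
    "AdjustmentInputs",
    "EventSplit",
    "DEFAULT_EVENT_SPLIT",
    "ethnicity_adjust",
    "adjust_rate",
    "split_composite",
    "treated_rate",
    "rate_to_prob",
    "prob_to_rate",
]


@dataclass(frozen=True)
class AdjustmentInputs:
    """Inputs to the age/LDL-C population risk adjustment.

    ``delta_age`` is target minus source age (years); ``delta_ldl`` the
    LDL-C difference in mmol/L.
    """

    r0: float            # events per 100 person-years
    hr_ethnicity: float
    hr_age: float        # per year of age
    delta_age: float
    rr_ldl: float        # per 1 mmol/L
    delta_ldl: float

    def __post_init__(self) -> None:
        if self.r0 < 0:
            raise ValidationError("r0 must be >= 0")
        for name in ("hr_ethnicity", "hr_age", "rr_ldl"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


@dataclass(frozen=True)
class EventSplit:
    """Fractions of the composite event rate attributed to each endpoint."""

    frac_mi: float
    frac_is: float
    frac_cv_death: float

    def __post_init__(self) -> None:
        for name in ("frac_mi", "frac_is", "frac_cv_death"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        total = self.frac_mi + self.frac_is + self.frac_cv_death
        if total > 1 + 1e-12:
            raise ValidationError(f"event fractions sum to {total} > 1")


# Back-solved from the base-case event-specific rates (3.53, 1.72, 0.70
# per 100 py; they sum to 5.95).
DEFAULT_EVENT_SPLIT = EventSplit(3.53 / 5.95, 1.72 / 5.95, 0.70 / 5.95)


def ethnicity_adjust(r0: float, hr: float) -> float:
    """Scale an event rate by an ethnicity hazard ratio."""
    if r0 < 0:
        raise ValidationError("rate must be >= 0")
    if hr <= 0:
        raise ValidationError("hazard ratio must be > 0")
    return r0 * hr


def adjust_rate(inputs: AdjustmentInputs) -> float:
    """Adjust a source-population event rate for age and LDL-C differences.

    Returns ``r0 * hr_age**delta_age * rr_ldl**delta_ldl`` (the ethnicity
    HR is applied separately via :func:`ethnicity_adjust`).
    """
    out = (inputs.r0
           * inputs.hr_age ** inputs.delta_age
           * inputs.rr_ldl ** inputs.delta_ldl)
    if not math.isfinite(out):
        raise ValidationError("rate adjustment produced a non-finite value")
    return out


def split_composite(composite: float, split: EventSplit = DEFAULT_EVENT_SPLIT) -> BaselineRates:
    """Disaggregate a composite event rate into MI / IS / CV-death rates."""
    if composite < 0:
        raise ValidationError("composite rate must be >= 0")

    def fx(x: float) -> UncertainParam:
        return UncertainParam(x, x, x, "fixed")

    return BaselineRates(
        composite=fx(composite),
        mi=fx(composite * split.frac_mi),
        is_=fx(composite * split.frac_is),
        cv_death=fx(composite * split.frac_cv_death),
    )


def treated_rate(r0: float, rr: float, delta_ldl: float) -> float:
    """Event rate after an LDL-C reduction of ``delta_ldl`` mmol/L:
    ``r0 * rr**delta_ldl``."""
    if r0 < 0:
        raise ValidationError("rate must be >= 0")
    if rr <= 0:
        raise ValidationError("rate ratio must be > 0")
    if delta_ldl < 0:
        raise ValidationError("delta_ldl must be >= 0")
    return r0 * rr ** delta_ldl


def rate_to_prob(r: float, t: float = 1.0) -> float:
    """Convert an annual event rate (per person-year) to a probability over
    ``t`` years: ``1 - exp(-r t)``."""
    if r < 0:
        raise ValidationError("rate must be >= 0")
    if t <= 0:
        raise ValidationError("time must be > 0")
    return -math.expm1(-r * t)


def prob_to_rate(p: float, t: float = 1.0) -> float:
    """Inverse of :func:`rate_to_prob`: ``-ln(1 - p) / t``."""
    if not 0 <= p < 1:
        raise ValidationError("probability must be in [0, 1)")
    if t <= 0:
        raise ValidationError("time must be > 0")
    return -math.log1p(-p) / t
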