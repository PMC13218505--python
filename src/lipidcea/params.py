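"""Model input definitions, validation, and YAML persistence.

Every quantitative input to the cohort model lives here as an
:class:`UncertainParam` (a point estimate plus an uncertainty range and a
distribution family used by the sensitivity machinery) grouped into typed
sections.  :func:`default_parameters` returns the packaged base-case
parameterization; :func:`load_parameters` / :func:`save_parameters` move the
same structure through a YAML document.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ValidationError",
    "UncertainParam",
    "PopulationProfile",
    "BaselineRates",
    "EffectParameters",
    "CostSet",
    "UtilitySet",
    "RunSettings",
    "ModelParameters",
    "default_parameters",
    "load_parameters",
    "save_parameters",
    "annual_drug_cost",
]

DISTRIBUTION_FAMILIES = ("gamma", "lognormal", "normal", "beta", "fixed")


class ValidationError(ValueError):
    """Raised when a model input violates its declared constraints."""


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ValidationError(f"{field_name}: {message}")


@dataclass(frozen=True)
class UncertainParam:
    """A scalar input with an uncertainty range and sampling family.

    ``low``/``high`` are the one-way sensitivity bounds; when the family is
    not ``fixed`` they are additionally interpreted as a 95% interval for
    distribution fitting.
    """

    point: float
    low: float
    high: float
    family: str = "fixed"

    def __post_init__(self) -> None:
        _require(self.family in DISTRIBUTION_FAMILIES, "family",
                 f"unknown distribution family {self.family!r}")
        _require(self.low <= self.point <= self.high, "point",
                 f"range ({self.low}, {self.high}) must bracket point {self.point}")

    @property
    def is_fixed(self) -> bool:
        return self.family == "fixed"

    def with_point(self, value: float) -> "UncertainParam":
        """Return a copy at a new point, widening the range if needed."""
        return UncertainParam(value, min(self.low, value), max(self.high, value),
                              self.family)


def _fixed(point: float, low: float | None = None, high: float | None = None) -> UncertainParam:
    if low is None:
        low, high = point, point
    return UncertainParam(point, low, high, "fixed")


@dataclass(frozen=True)
class PopulationProfile:
    mean_age: float
    male_fraction: float
    mean_ldl: float          # mg/dL
    statin_fraction: float

    def __post_init__(self) -> None:
        _require(self.mean_age > 0, "population.mean_age", "must be positive")
        _require(0 <= self.male_fraction <= 1, "population.male_fraction", "must be in [0, 1]")
        _require(self.mean_ldl > 0, "population.mean_ldl", "must be positive")
        _require(0 <= self.statin_fraction <= 1, "population.statin_fraction", "must be in [0, 1]")


@dataclass(frozen=True)
class BaselineRates:
    """Annual event rates per 100 person-years for the untreated cohort."""

    composite: UncertainParam
    mi: UncertainParam
    is_: UncertainParam
    cv_death: UncertainParam

    def __post_init__(self) -> None:
        for name in ("composite", "mi", "is_", "cv_death"):
            _require(getattr(self, name).point >= 0, f"baseline.{name}", "must be >= 0")
        for name in ("mi", "is_", "cv_death"):
            _require(getattr(self, name).point <= self.composite.point,
                     f"baseline.{name}", "component rate exceeds composite rate")


@dataclass(frozen=True)
class EffectParameters:
    """Treatment-effect inputs: rate ratios per 1 mmol/L LDL-C reduction,
    achieved LDL-C reductions, and recurrence/post-event hazard ratios."""

    rr_mace: UncertainParam
    rr_mi: UncertainParam
    rr_is: UncertainParam
    rr_cv_death: UncertainParam
    rr_all_cause: UncertainParam
    ldl_reduction_pct: UncertainParam    # percent
    ldl_reduction_abs: UncertainParam    # mmol/L
    hr_recurrent_mi: UncertainParam
    hr_recurrent_is: UncertainParam
    hr_post_event_death: UncertainParam

    def __post_init__(self) -> None:
        for name in ("rr_mace", "rr_mi", "rr_is", "rr_cv_death", "rr_all_cause",
                     "hr_recurrent_mi", "hr_recurrent_is", "hr_post_event_death"):
            _require(getattr(self, name).point > 0, f"effects.{name}", "ratio must be > 0")


@dataclass(frozen=True)
class CostSet:
    """Annual costs in 2024 CNY (death costs are one-off on entry)."""

    inclisiran_year1: UncertainParam
    inclisiran_later: UncertainParam
    statin_annual: UncertainParam
    mi_year1: UncertainParam
    mi_later: UncertainParam
    is_year1: UncertainParam
    is_later: UncertainParam
    cv_death: UncertainParam
    non_cv_death: UncertainParam

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            _require(getattr(self, f.name).point >= 0, f"costs.{f.name}", "must be >= 0")


@dataclass(frozen=True)
class UtilitySet:
    baseline_ascvd: UncertainParam
    mi_year1: UncertainParam
    mi_later: UncertainParam
    is_year1: UncertainParam
    is_later: UncertainParam

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            p = getattr(self, f.name)
            _require(0 <= p.low and p.high <= 1, f"utilities.{f.name}",
                     "utility and its range must lie in [0, 1]")


@dataclass(frozen=True)
class RunSettings:
    horizon_years: int = 30
    discount_rate: float = 0.045
    wtp: float = 191_498.0
    half_cycle: bool = True
    psa_draws: int = 1000
    rng_seed: int = 20240
    # Whether the all-cause-mortality rate ratio modifies the background
    # (non-CV) death rate in the treated arm.
    mortality_benefit: bool = True

    def __post_init__(self) -> None:
        _require(self.horizon_years >= 1, "settings.horizon_years", "must be >= 1")
        _require(0 <= self.discount_rate <= 1, "settings.discount_rate", "must be in [0, 1]")
        _require(self.wtp > 0, "settings.wtp", "must be positive")
        _require(self.psa_draws >= 1, "settings.psa_draws", "must be >= 1")


@dataclass(frozen=True)
class ModelParameters:
    population: PopulationProfile
    baseline: BaselineRates
    effects: EffectParameters
    costs: CostSet
    utilities: UtilitySet
    settings: RunSettings = field(default_factory=RunSettings)


# --------------------------------------------------------------------------
# base case

INCLISIRAN_PRICE_PER_DOSE = 2790.0
INJECTION_FEE_PER_DOSE = 5.0


def annual_drug_cost(price_per_dose: float, fee_per_dose: float, doses: int) -> float:
    """Annual drug cost: ``doses * (price + fee)``."""
    if price_per_dose < 0 or fee_per_dose < 0 or doses < 0:
        raise ValidationError("annual_drug_cost: inputs must be >= 0")
    return doses * (price_per_dose + fee_per_dose)


def default_parameters() -> ModelParameters:
    """The packaged base-case input set."""
    u = UncertainParam
    return ModelParameters(
        population=PopulationProfile(
            mean_age=59.5, male_fraction=0.747, mean_ldl=109.0, statin_fraction=0.977),
        baseline=BaselineRates(
            composite=_fixed(6.66, 5.33, 7.99),
            mi=_fixed(3.53, 2.82, 4.24),
            is_=_fixed(1.72, 1.38, 2.06),
            cv_death=_fixed(0.70, 0.56, 0.84)),
        effects=EffectParameters(
            rr_mace=u(0.78, 0.76, 0.80, "lognormal"),
            rr_mi=u(0.73, 0.70, 0.76, "lognormal"),
            rr_is=u(0.79, 0.74, 0.85, "lognormal"),
            rr_cv_death=u(0.84, 0.80, 0.88, "lognormal"),
            rr_all_cause=u(0.90, 0.87, 0.93, "lognormal"),
            ldl_reduction_pct=u(57.2, 51.3, 63.1, "normal"),
            ldl_reduction_abs=u(1.56, 1.50, 1.63, "normal"),
            hr_recurrent_mi=u(1.13, 1.04, 1.22, "lognormal"),
            hr_recurrent_is=u(1.13, 0.99, 1.30, "lognormal"),
            hr_post_event_death=u(1.31, 1.15, 1.49, "lognormal")),
        costs=CostSet(
            inclisiran_year1=u(
                annual_drug_cost(INCLISIRAN_PRICE_PER_DOSE, INJECTION_FEE_PER_DOSE, 3),
                6708.0, 8385.0, "gamma"),
            inclisiran_later=u(
                annual_drug_cost(INCLISIRAN_PRICE_PER_DOSE, INJECTION_FEE_PER_DOSE, 2),
                4472.0, 5590.0, "gamma"),
            statin_annual=u(3645.0, 2916.0, 3645.0, "gamma"),
            mi_year1=u(23567.4, 18853.9, 28280.9, "gamma"),
            mi_later=u(3885.2, 3108.2, 4662.2, "gamma"),
            is_year1=u(10005.7, 8004.6, 12006.8, "gamma"),
            is_later=u(4398.0, 3518.4, 5277.6, "gamma"),
            cv_death=u(15212.0, 12169.6, 18254.4, "gamma"),
            non_cv_death=u(6044.1, 4835.3, 7252.9, "gamma")),
        utilities=UtilitySet(
            baseline_ascvd=u(0.824, 0.800, 0.848, "beta"),
            mi_year1=u(0.672, 0.625, 0.719, "beta"),
            mi_later=u(0.824, 0.800, 0.848, "beta"),
            is_year1=u(0.327, 0.264, 0.390, "beta"),
            is_later=u(0.524, 0.472, 0.576, "beta")),
        settings=RunSettings(),
    )


# --------------------------------------------------------------------------
# (de)serialization

_SECTIONS = ("population", "baseline", "effects", "costs", "utilities", "settings")


def _param_to_obj(p: UncertainParam) -> Any:
    if p.is_fixed and p.low == p.point == p.high:
        return p.point
    return {"point": p.point, "low": p.low, "high": p.high, "family": p.family}


def _obj_to_param(obj: Any, field_name: str) -> UncertainParam:
    if isinstance(obj, (int, float)):
        return _fixed(float(obj))
    if not isinstance(obj, dict):
        raise ValidationError(f"{field_name}: expected number or mapping, got {type(obj).__name__}")
    missing = {"point", "low", "high"} - obj.keys()
    if missing:
        raise ValidationError(f"{field_name}: missing keys {sorted(missing)}")
    try:
        return UncertainParam(float(obj["point"]), float(obj["low"]),
                              float(obj["high"]), str(obj.get("family", "fixed")))
    except ValidationError as exc:
        raise ValidationError(f"{field_name}: {exc}") from exc


def parameters_to_dict(params: ModelParameters) -> dict:
    out: dict[str, dict] = {}
    for section in _SECTIONS:
        sec_obj = getattr(params, section)
        sec: dict[str, Any] = {}
        for f in dataclasses.fields(sec_obj):
            v = getattr(sec_obj, f.name)
            sec[f.name] = _param_to_obj(v) if isinstance(v, UncertainParam) else v
        out[section] = sec
    return out


def parameters_from_dict(doc: dict) -> ModelParameters:
    if not isinstance(doc, dict):
        raise ValidationError("config root must be a mapping")
    defaults = default_parameters()
    built = {}
    for section in _SECTIONS:
        sec_doc = doc.get(section, {})
        if not isinstance(sec_doc, dict):
            raise ValidationError(f"{section}: expected a mapping")
        cls = type(getattr(defaults, section))
        kwargs = {}
        for f in dataclasses.fields(cls):
            default_val = getattr(getattr(defaults, section), f.name)
            if f.name not in sec_doc:
                kwargs[f.name] = default_val
            elif isinstance(default_val, UncertainParam):
                kwargs[f.name] = _obj_to_param(sec_doc[f.name], f"{section}.{f.name}")
            else:
                kwargs[f.name] = type(default_val)(sec_doc[f.name])
        unknown = set(sec_doc) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"{section}: unknown keys {sorted(unknown)}")
        try:
            built[section] = cls(**kwargs)
        except ValidationError:
            raise
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{section}: {exc}") from exc
    return ModelParameters(**built)


def load_parameters(path: str | Path) -> ModelParameters:
    """Load and validate a parameter configuration from a YAML file.

    Missing optional fields take the packaged base-case defaults.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parameters_from_dict(doc or {})


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(parameters_to_dict(params), fh, sort_keys=False)
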