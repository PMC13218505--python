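"""Annual-cycle cohort state-transition engine.

Six modeled health states (death split into CV / non-CV for cost
assignment): baseline disease, acute MI, acute ischemic stroke, post-MI,
post-IS, and the two absorbing death states.  Event probabilities come from
annual rates via the exponential conversion; background non-CV mortality
comes from an age-indexed life table; transitions are memoryless and at most
one event occurs per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import rate_to_prob
from .params import ModelParameters, ValidationError

__all__ = [
    "HealthState",
    "LifeTable",
    "ArmSpec",
    "CohortTrace",
    "make_arms",
    "mortality_split",
    "discount_factor",
    "transition_matrix",
    "run_cohort",
]


class HealthState(IntEnum):
    BASELINE_ASCVD = 0
    ACUTE_MI = 1
    ACUTE_IS = 2
    POST_MI = 3
    POST_IS = 4
    DEAD_CV = 5
    DEAD_NONCV = 6


N_STATES = len(HealthState)
ALIVE = [HealthState.BASELINE_ASCVD, HealthState.ACUTE_MI, HealthState.ACUTE_IS,
         HealthState.POST_MI, HealthState.POST_IS]
DEAD = [HealthState.DEAD_CV, HealthState.DEAD_NONCV]

LIFETABLE_COLUMNS = ["age", "all_cause_rate", "cv_rate"]


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed all-cause and CV mortality rates (per person-year)."""

    ages: np.ndarray
    all_cause_rate: np.ndarray
    cv_rate: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        ac = np.asarray(self.all_cause_rate, dtype=float)
        cv = np.asarray(self.cv_rate, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "all_cause_rate", ac)
        object.__setattr__(self, "cv_rate", cv)
        if not (len(ages) == len(ac) == len(cv)):
            raise ValidationError("life table columns must have equal length")
        if len(ages) == 0:
            raise ValidationError("life table is empty")
        if not np.all(np.diff(ages) > 0):
            raise ValidationError("life table ages must be strictly increasing")
        if np.any(cv < 0) or np.any(ac < 0):
            raise ValidationError("life table rates must be >= 0")
        if np.any(cv > ac + 1e-12):
            raise ValidationError("cv_rate exceeds all_cause_rate in life table")

    @property
    def age_min(self) -> float:
        return float(self.ages[0])

    @property
    def age_max(self) -> float:
        return float(self.ages[-1])

    def rates_at(self, age: float) -> tuple[float, float]:
        """(all-cause, CV) mortality rates for the row covering ``age``
        (integer-age rows; the floor of ``age`` is looked up, no
        interpolation)."""
        a = float(np.floor(age))
        idx = np.searchsorted(self.ages, a, side="right") - 1
        if idx < 0 or a > self.age_max:
            raise ValidationError(f"age {age} not covered by life table "
                                  f"[{self.age_min}, {self.age_max}]")
        return float(self.all_cause_rate[idx]), float(self.cv_rate[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages,
                             "all_cause_rate": self.all_cause_rate,
                             "cv_rate": self.cv_rate})

    def to_csv(self, path: str | Path) -> None:
        # %.17g guarantees bit-exact float round-trips through the CSV
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = set(LIFETABLE_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"life table CSV missing columns {sorted(missing)}")
        return cls(df["age"].to_numpy(float),
                   df["all_cause_rate"].to_numpy(float),
                   df["cv_rate"].to_numpy(float))


@dataclass(frozen=True)
class ArmSpec:
    name: str
    on_inclisiran: bool
    delta_ldl: float  # achieved LDL-C reduction, mmol/L (0 for comparator)

    def __post_init__(self) -> None:
        if self.delta_ldl < 0:
            raise ValidationError("delta_ldl must be >= 0")


def make_arms(params: ModelParameters) -> tuple[ArmSpec, ArmSpec]:
    """(comparator, intervention) arm specifications for a parameter set."""
    comparator = ArmSpec("statin", on_inclisiran=False, delta_ldl=0.0)
    intervention = ArmSpec("inclisiran+statin", on_inclisiran=True,
                           delta_ldl=params.effects.ldl_reduction_abs.point)
    return comparator, intervention


def mortality_split(life_table: LifeTable, age: float) -> tuple[float, float]:
    """Split life-table mortality at ``age`` into (cv_rate, non_cv_rate)."""
    all_cause, cv = life_table.rates_at(age)
    if cv > all_cause + 1e-12:
        raise ValidationError(f"cv rate {cv} exceeds all-cause rate {all_cause} at age {age}")
    return cv, all_cause - cv


def discount_factor(rate: float, cycle: int, half_cycle: bool) -> float:
    """Per-cycle discount factor; mid-cycle exponent when ``half_cycle``."""
    if rate < 0:
        raise ValidationError("discount rate must be >= 0")
    if cycle < 1:
        raise ValidationError("cycle index starts at 1")
    exponent = cycle - 0.5 if half_cycle else cycle
    return (1.0 + rate) ** -exponent


def _event_rates(params: ModelParameters, arm: ArmSpec) -> tuple[float, float, float]:
    """Per-person-year MI / IS / CV-death rates for an arm (treated rates
    apply the per-mmol/L rate ratios raised to the achieved reduction)."""
    e = params.effects
    mi = params.baseline.mi.point / 100.0
    is_ = params.baseline.is_.point / 100.0
    cvd = params.baseline.cv_death.point / 100.0
    if arm.delta_ldl > 0:
        mi *= e.rr_mi.point ** arm.delta_ldl
        is_ *= e.rr_is.point ** arm.delta_ldl
        cvd *= e.rr_cv_death.point ** arm.delta_ldl
    return mi, is_, cvd


def transition_matrix(params: ModelParameters, arm: ArmSpec,
                      life_table: LifeTable, age: float) -> np.ndarray:
    """One-cycle transition-probability matrix at attained age ``age``.

    Event probabilities convert each annual rate independently; recurrent
    events from post states carry their recurrence hazard ratios; CV death
    in the cycle after an event carries the post-event hazard ratio; acute
    survivors move deterministically to their post state.
    """
    mi, is_, cvd = _event_rates(params, arm)
    _, non_cv = mortality_split(life_table, age)
    e = params.effects
    if arm.delta_ldl > 0 and params.settings.mortality_benefit:
        non_cv *= e.rr_all_cause.point ** arm.delta_ldl

    p_ncv = rate_to_prob(non_cv)
    S = HealthState
    m = np.zeros((N_STATES, N_STATES))

    def fill(row: HealthState, moves: dict[HealthState, float], stay: HealthState) -> None:
        total = 0.0
        for dest, p in moves.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(
                    f"transition {row.name}->{dest.name} probability {p} outside [0, 1]")
            m[row, dest] = p
            total += p
        if total > 1.0 + 1e-12:
            raise ValidationError(
                f"transition probabilities out of state {row.name} sum to {total} > 1")
        m[row, stay] += 1.0 - total

    fill(S.BASELINE_ASCVD,
         {S.ACUTE_MI: rate_to_prob(mi), S.ACUTE_IS: rate_to_prob(is_),
          S.DEAD_CV: rate_to_prob(cvd), S.DEAD_NONCV: p_ncv},
         stay=S.BASELINE_ASCVD)

    # The cycle following an acute event: elevated CV death, survivors to
    # the post state (no second event in the acute year).
    p_cvd_acute = rate_to_prob(cvd * e.hr_post_event_death.point)
    fill(S.ACUTE_MI, {S.DEAD_CV: p_cvd_acute, S.DEAD_NONCV: p_ncv}, stay=S.POST_MI)
    fill(S.ACUTE_IS, {S.DEAD_CV: p_cvd_acute, S.DEAD_NONCV: p_ncv}, stay=S.POST_IS)

    fill(S.POST_MI,
         {S.ACUTE_MI: rate_to_prob(mi * e.hr_recurrent_mi.point),
          S.ACUTE_IS: rate_to_prob(is_),
          S.DEAD_CV: rate_to_prob(cvd), S.DEAD_NONCV: p_ncv},
         stay=S.POST_MI)
    fill(S.POST_IS,
         {S.ACUTE_MI: rate_to_prob(mi),
          S.ACUTE_IS: rate_to_prob(is_ * e.hr_recurrent_is.point),
          S.DEAD_CV: rate_to_prob(cvd), S.DEAD_NONCV: p_ncv},
         stay=S.POST_IS)

    m[S.DEAD_CV, S.DEAD_CV] = 1.0
    m[S.DEAD_NONCV, S.DEAD_NONCV] = 1.0
    return m


@dataclass
class CohortTrace:
    """Per-cycle occupancy and discounted cost/QALY streams for one arm.

    ``occupancy`` has ``horizon + 1`` rows: row 0 is the start of cycle 1
    and row k the state distribution after k cycles.
    """

    arm: ArmSpec
    ages: np.ndarray          # attained age at the start of each cycle
    occupancy: np.ndarray     # (horizon+1, n_states)
    cycle_costs: np.ndarray   # discounted CNY, per cycle
    cycle_qalys: np.ndarray   # discounted QALYs, per cycle

    @property
    def total_cost(self) -> float:
        return float(self.cycle_costs.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.cycle_qalys.sum())

    def validate(self, tol: float = 1e-9) -> None:
        sums = self.occupancy.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=tol):
            raise ValidationError("occupancy rows do not sum to 1")
        if self.occupancy.min() < -tol or self.occupancy.max() > 1 + tol:
            raise ValidationError("occupancy outside [0, 1]")
        dead = self.occupancy[:, DEAD].sum(axis=1)
        if np.any(np.diff(dead) < -tol):
            raise ValidationError("dead occupancy decreased")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy[1:],
                          columns=[s.name.lower() for s in HealthState])
        df.insert(0, "cycle", np.arange(1, len(df) + 1))
        df.insert(1, "age", self.ages)
        df["cost_discounted"] = self.cycle_costs
        df["qaly_discounted"] = self.cycle_qalys
        df["arm"] = self.arm.name
        return df


def _state_costs(params: ModelParameters, arm: ArmSpec, cycle: int) -> np.ndarray:
    """Per-cycle cost attached to occupancy of each alive state (CNY)."""
    c = params.costs
    v = np.zeros(N_STATES)
    v[HealthState.ACUTE_MI] = c.mi_year1.point
    v[HealthState.ACUTE_IS] = c.is_year1.point
    v[HealthState.POST_MI] = c.mi_later.point
    v[HealthState.POST_IS] = c.is_later.point
    drug = c.statin_annual.point
    if arm.on_inclisiran:
        drug += c.inclisiran_year1.point if cycle == 1 else c.inclisiran_later.point
    for s in ALIVE:
        v[s] += drug
    return v


def _state_utilities(params: ModelParameters) -> np.ndarray:
    u = params.utilities
    v = np.zeros(N_STATES)
    v[HealthState.BASELINE_ASCVD] = u.baseline_ascvd.point
    v[HealthState.ACUTE_MI] = u.mi_year1.point
    v[HealthState.ACUTE_IS] = u.is_year1.point
    v[HealthState.POST_MI] = u.mi_later.point
    v[HealthState.POST_IS] = u.is_later.point
    return v


def run_cohort(params: ModelParameters, arm: ArmSpec, life_table: LifeTable) -> CohortTrace:
    """Evolve the cohort over the configured horizon and accumulate
    discounted, half-cycle-corrected costs and QALYs.

    Costs and utilities accrue on start-of-cycle occupancy; one-off death
    costs are charged to the incident dying fraction in the cycle of death.
    """
    settings = params.settings
    horizon = settings.horizon_years
    start_age = params.population.mean_age
    last_age = start_age + horizon - 1
    if np.floor(last_age) > life_table.age_max:
        raise ValidationError(
            f"horizon {horizon} needs life-table coverage to age {np.floor(last_age)}, "
            f"table ends at {life_table.age_max}")

    util = _state_utilities(params)
    occ = np.zeros((horizon + 1, N_STATES))
    occ[0, HealthState.BASELINE_ASCVD] = 1.0
    costs = np.zeros(horizon)
    qalys = np.zeros(horizon)
    ages = start_age + np.arange(horizon)

    for k in range(1, horizon + 1):
        age = ages[k - 1]
        m = transition_matrix(params, arm, life_table, age)
        occ[k] = occ[k - 1] @ m
        df = discount_factor(settings.discount_rate, k, settings.half_cycle)

        state_cost = _state_costs(params, arm, k)
        cost_k = float(occ[k - 1] @ state_cost)
        cost_k += (occ[k, HealthState.DEAD_CV] - occ[k - 1, HealthState.DEAD_CV]) \
            * params.costs.cv_death.point
        cost_k += (occ[k, HealthState.DEAD_NONCV] - occ[k - 1, HealthState.DEAD_NONCV]) \
            * params.costs.non_cv_death.point
        costs[k - 1] = cost_k * df
        qalys[k - 1] = float(occ[k - 1] @ util) * df

    trace = CohortTrace(arm=arm, ages=ages, occupancy=occ,
                        cycle_costs=costs, cycle_qalys=qalys)
    trace.validate()
    return trace
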