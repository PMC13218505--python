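"""Incremental cost-effectiveness outputs and the WTP decision rule."""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .markov import CohortTrace, LifeTable, make_arms, run_cohort
from .params import ModelParameters

__all__ = ["CEResult", "compute_icer", "is_cost_effective", "run_comparison",
           "results_table"]

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class CEResult:
    """Paired-arm totals and incremental outputs (arm b vs arm a)."""

    cost_a: float
    cost_b: float
    qaly_a: float
    qaly_b: float
    inc_cost: float
    inc_qaly: float
    icer: float | None     # None when flagged
    flag: str | None       # DOMINANT / DOMINATED / UNDEFINED / None
    nmb: float
    wtp: float


def compute_icer(comparator: CohortTrace, intervention: CohortTrace,
                 wtp: float) -> CEResult:
    """Incremental cost, QALYs, ICER (with dominance flags) and NMB.

    The ICER is formed from unrounded totals; rounding is a display
    concern only.
    """
    return icer_from_totals(comparator.total_cost, comparator.total_qalys,
                            intervention.total_cost, intervention.total_qalys, wtp)


def icer_from_totals(cost_a: float, qaly_a: float, cost_b: float, qaly_b: float,
                     wtp: float) -> CEResult:
    inc_cost = cost_b - cost_a
    inc_qaly = qaly_b - qaly_a
    nmb = wtp * inc_qaly - inc_cost

    icer: float | None
    flag: str | None
    if inc_qaly == 0:
        icer, flag = None, UNDEFINED
    elif inc_qaly > 0 and inc_cost < 0:
        icer, flag = None, DOMINANT
    elif inc_qaly < 0 and inc_cost > 0:
        icer, flag = None, DOMINATED
    else:
        icer, flag = inc_cost / inc_qaly, None
        if not math.isfinite(icer):
            icer, flag = None, UNDEFINED

    return CEResult(cost_a=cost_a, cost_b=cost_b, qaly_a=qaly_a, qaly_b=qaly_b,
                    inc_cost=inc_cost, inc_qaly=inc_qaly, icer=icer, flag=flag,
                    nmb=nmb, wtp=wtp)


def is_cost_effective(result: CEResult, wtp: float | None = None) -> bool:
    """True iff the intervention is dominant, or its ICER is defined and
    below the threshold with a positive QALY gain."""
    wtp = result.wtp if wtp is None else wtp
    if result.flag == DOMINANT:
        return True
    if result.flag in (DOMINATED, UNDEFINED):
        return False
    return result.inc_qaly > 0 and result.icer is not None and result.icer < wtp


def run_comparison(params: ModelParameters, life_table: LifeTable
                   ) -> tuple[CEResult, CohortTrace, CohortTrace]:
    """Run both arms under one parameter set and compare them."""
    comparator, intervention = make_arms(params)
    trace_a = run_cohort(params, comparator, life_table)
    trace_b = run_cohort(params, intervention, life_table)
    result = compute_icer(trace_a, trace_b, params.settings.wtp)
    return result, trace_a, trace_b


def results_table(result: CEResult, trace_a: CohortTrace, trace_b: CohortTrace
                  ) -> pd.DataFrame:
    """Two-strategy results table (rounded display columns alongside full
    precision)."""
    icer_display = result.icer if result.icer is not None else result.flag
    rows = [
        {"strategy": trace_a.arm.name, "total_cost": round(result.cost_a, 2),
         "total_qalys": round(result.qaly_a, 2), "inc_cost": None,
         "inc_qalys": None, "icer": None,
         "total_cost_full": result.cost_a, "total_qalys_full": result.qaly_a},
        {"strategy": trace_b.arm.name, "total_cost": round(result.cost_b, 2),
         "total_qalys": round(result.qaly_b, 2),
         "inc_cost": round(result.inc_cost, 2),
         "inc_qalys": round(result.inc_qaly, 2),
         "icer": round(icer_display, 2) if isinstance(icer_display, float) else icer_display,
         "total_cost_full": result.cost_b, "total_qalys_full": result.qaly_b},
    ]
    return pd.DataFrame(rows)
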