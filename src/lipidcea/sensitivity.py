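"""Deterministic and probabilistic sensitivity machinery.

One-way analysis swings each parameter across its range and records both
ICERs (tornado ordering by spread); probabilistic analysis samples every
non-fixed parameter from a distribution fitted to its point and 95%
interval, reruns both arms per draw, and feeds the acceptability curve.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .economics import CEResult, run_comparison
from .markov import LifeTable
from .params import ModelParameters, UncertainParam, ValidationError

__all__ = [
    "DistributionSpec",
    "OwsaRow",
    "PsaDraws",
    "fit_distribution",
    "run_owsa",
    "run_psa",
    "ceac",
    "horizon_sweep",
    "owsa_table",
    "DEFAULT_OWSA_PARAMS",
]

_Z95 = 2 * 1.959963984540054  # width of a 95% normal interval in sd units


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one uncertain parameter."""

    family: str
    params: dict

    def frozen(self):
        p = self.params
        if self.family == "lognormal":
            return stats.lognorm(s=p["sigma"], scale=np.exp(p["mu"]))
        if self.family == "normal":
            return stats.norm(loc=p["mean"], scale=p["sd"])
        if self.family == "gamma":
            return stats.gamma(a=p["shape"], scale=p["scale"])
        if self.family == "beta":
            return stats.beta(a=p["alpha"], b=p["beta"])
        raise ValidationError(f"unsupported family {self.family!r}")

    def sample(self, rng: np.random.Generator, size: int | None = None):
        return self.frozen().rvs(size=size, random_state=rng)

    @property
    def mean(self) -> float:
        return float(self.frozen().mean())


def fit_distribution(param: UncertainParam, name: str = "parameter") -> DistributionSpec:
    """Fit the declared family to ``(point, low, high)``.

    The interval is read as a 95% CI: lognormal takes its log-scale sd from
    the log-interval width, normal its sd from the interval width, and
    gamma/beta are matched by moments to mean = point and that same sd.
    """
    if param.family == "fixed":
        raise ValidationError(f"{name}: cannot fit a distribution to a fixed parameter")
    if not param.low < param.high:
        raise ValidationError(f"{name}: degenerate interval ({param.low}, {param.high})")
    m = param.point
    sd = (param.high - param.low) / _Z95

    if param.family == "lognormal":
        if param.low <= 0 or m <= 0:
            raise ValidationError(f"{name}: lognormal needs positive support")
        sigma = (np.log(param.high) - np.log(param.low)) / _Z95
        return DistributionSpec("lognormal", {"mu": float(np.log(m)), "sigma": float(sigma)})
    if param.family == "normal":
        return DistributionSpec("normal", {"mean": float(m), "sd": float(sd)})
    if param.family == "gamma":
        if m <= 0:
            raise ValidationError(f"{name}: gamma needs a positive mean")
        shape = (m / sd) ** 2
        scale = sd * sd / m
        return DistributionSpec("gamma", {"shape": float(shape), "scale": float(scale)})
    if param.family == "beta":
        if not 0 < m < 1:
            raise ValidationError(f"{name}: beta mean must lie in (0, 1)")
        nu = m * (1 - m) / (sd * sd) - 1
        if nu <= 0:
            raise ValidationError(f"{name}: beta moments infeasible (sd {sd} too large "
                                  f"for mean {m})")
        return DistributionSpec("beta", {"alpha": float(m * nu), "beta": float((1 - m) * nu)})
    raise ValidationError(f"{name}: unknown family {param.family!r}")


# --------------------------------------------------------------------------
# parameter registry: label -> how to read/write it on ModelParameters

def _resolve(params: ModelParameters, name: str) -> UncertainParam:
    section, _, attr = name.partition(".")
    try:
        return getattr(getattr(params, section), attr)
    except AttributeError as exc:
        raise ValidationError(f"unknown parameter {name!r}") from exc


def _with_value(params: ModelParameters, name: str, value: float) -> ModelParameters:
    """A copy of ``params`` with one named parameter moved to ``value``."""
    if name == "settings.discount_rate":
        return dataclasses.replace(
            params, settings=dataclasses.replace(params.settings, discount_rate=value))
    if name == "inclisiran_price":
        # joint per-dose price swing: scale both annual inclisiran costs
        c = params.costs
        return dataclasses.replace(params, costs=dataclasses.replace(
            c,
            inclisiran_year1=c.inclisiran_year1.with_point(c.inclisiran_year1.point * value),
            inclisiran_later=c.inclisiran_later.with_point(c.inclisiran_later.point * value)))
    if name == "baseline.composite":
        b = params.baseline
        factor = value / b.composite.point
        return dataclasses.replace(params, baseline=dataclasses.replace(
            b,
            composite=b.composite.with_point(value),
            mi=b.mi.with_point(b.mi.point * factor),
            is_=b.is_.with_point(b.is_.point * factor),
            cv_death=b.cv_death.with_point(b.cv_death.point * factor)))

    section, _, attr = name.partition(".")
    sec_obj = getattr(params, section, None)
    if sec_obj is None or not hasattr(sec_obj, attr):
        raise ValidationError(f"unknown parameter {name!r}")
    current: UncertainParam = getattr(sec_obj, attr)
    new_sec = dataclasses.replace(sec_obj, **{attr: current.with_point(value)})
    return dataclasses.replace(params, **{section: new_sec})


def _owsa_bounds(params: ModelParameters, name: str) -> tuple[float, float]:
    if name == "settings.discount_rate":
        return 0.0, 0.05
    if name == "inclisiran_price":
        return 0.8, 1.0   # up-to-20% price reduction vs list price
    if name == "baseline.composite":
        p = params.baseline.composite
        return p.low, p.high
    p = _resolve(params, name)
    return p.low, p.high


DEFAULT_OWSA_PARAMS = [
    "effects.rr_mace",
    "effects.rr_mi",
    "effects.rr_is",
    "effects.rr_cv_death",
    "effects.rr_all_cause",
    "effects.ldl_reduction_abs",
    "effects.hr_recurrent_mi",
    "effects.hr_recurrent_is",
    "effects.hr_post_event_death",
    "inclisiran_price",
    "costs.statin_annual",
    "costs.mi_year1",
    "costs.mi_later",
    "costs.is_year1",
    "costs.is_later",
    "costs.cv_death",
    "costs.non_cv_death",
    "utilities.baseline_ascvd",
    "utilities.mi_year1",
    "utilities.mi_later",
    "utilities.is_year1",
    "utilities.is_later",
    "baseline.composite",
    "settings.discount_rate",
]


@dataclass(frozen=True)
class OwsaRow:
    parameter_name: str
    low_value: float
    high_value: float
    icer_low: float
    icer_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _icer_value(result: CEResult) -> float:
    if result.icer is None:
        raise ValidationError(f"ICER not defined (flag={result.flag}) during sensitivity run")
    return result.icer


def run_owsa(params: ModelParameters, life_table: LifeTable,
             param_list: list[str] | None = None) -> list[OwsaRow]:
    """One-way sweep: rerun both arms at each parameter's lower and upper
    bound, all else at base.  Rows sorted by descending ICER spread (ties
    broken alphabetically)."""
    names = DEFAULT_OWSA_PARAMS if param_list is None else param_list
    rows = []
    for name in names:
        low, high = _owsa_bounds(params, name)
        icer_low = _icer_value(run_comparison(_with_value(params, name, low), life_table)[0])
        icer_high = _icer_value(run_comparison(_with_value(params, name, high), life_table)[0])
        rows.append(OwsaRow(name, low, high, icer_low, icer_high))
    rows.sort(key=lambda r: (-r.spread, r.parameter_name))
    return rows


def owsa_table(rows: list[OwsaRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": r.parameter_name, "low_value": r.low_value,
        "high_value": r.high_value, "icer_low": r.icer_low,
        "icer_high": r.icer_high, "spread": r.spread} for r in rows])


# --------------------------------------------------------------------------
# PSA

@dataclass
class PsaDraws:
    """Sampled parameter sets and per-draw incremental outcomes."""

    parameter_names: list[str]
    samples: np.ndarray     # (draws, n_parameters)
    inc_cost: np.ndarray    # (draws,)
    inc_qaly: np.ndarray    # (draws,)
    rng_seed: int
    resample_count: int = 0
    base_result: CEResult | None = None

    @property
    def n_draws(self) -> int:
        return len(self.inc_cost)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=self.parameter_names)
        df["inc_cost"] = self.inc_cost
        df["inc_qaly"] = self.inc_qaly
        df.insert(0, "draw", np.arange(1, self.n_draws + 1))
        return df


def psa_parameter_names(params: ModelParameters) -> list[str]:
    """Labels of every parameter sampled in the PSA.

    All non-fixed parameters are included, with two wrinkles: the achieved
    LDL-C reduction is sampled on the (wider) percent scale and mapped
    proportionally onto the absolute value the engine consumes, and the
    composite baseline event rate is sampled as a beta-distributed annual
    probability whose draws scale every event component coherently.
    """
    names = []
    for section in ("baseline", "effects", "costs", "utilities"):
        sec = getattr(params, section)
        for f in dataclasses.fields(sec):
            p = getattr(sec, f.name)
            if isinstance(p, UncertainParam) and not p.is_fixed:
                names.append(f"{section}.{f.name}")
    names.remove("effects.ldl_reduction_abs")
    names.append("baseline.composite")
    return names


_SUPPORT = {
    # (lower, upper) hard support bounds used to cap invalid samples
    "utilities": (0.0, 1.0),
}


def _psa_spec(params: ModelParameters, name: str) -> DistributionSpec:
    if name == "baseline.composite":
        p = params.baseline.composite
        # per-100-py rate -> annual probability scale for the beta fit
        return fit_distribution(
            UncertainParam(p.point / 100, p.low / 100, p.high / 100, "beta"), name)
    return fit_distribution(_resolve(params, name), name)


def run_psa(params: ModelParameters, life_table: LifeTable,
            draws: int | None = None, seed: int | None = None) -> PsaDraws:
    """Monte-Carlo resampling of all non-fixed parameters (independently),
    rerunning both arms per draw.  Reproducible for a given seed."""
    draws = params.settings.psa_draws if draws is None else draws
    seed = params.settings.rng_seed if seed is None else seed
    if draws < 1:
        raise ValidationError("draws must be >= 1")
    rng = np.random.default_rng(seed)

    names = psa_parameter_names(params)
    specs = {n: _psa_spec(params, n) for n in names}
    samples = np.empty((draws, len(names)))
    resampled = 0
    for j, n in enumerate(names):
        col = np.asarray(specs[n].sample(rng, draws), dtype=float)
        if n == "baseline.composite":
            col *= 100.0  # back to events per 100 py
        lo, hi = _SUPPORT.get(n.split(".")[0], (0.0, np.inf))
        bad = (col < lo) | (col > hi)
        if bad.any():
            resampled += int(bad.sum())
            col = np.clip(col, lo if lo > 0 else np.nextafter(lo, hi), hi)
        samples[:, j] = col

    e = params.effects
    abs_per_pct = e.ldl_reduction_abs.point / e.ldl_reduction_pct.point
    inc_cost = np.empty(draws)
    inc_qaly = np.empty(draws)
    for i in range(draws):
        p_i = params
        for j, n in enumerate(names):
            if n == "effects.ldl_reduction_pct":
                p_i = _with_value(p_i, "effects.ldl_reduction_abs",
                                  samples[i, j] * abs_per_pct)
            else:
                p_i = _with_value(p_i, n, samples[i, j])
        result, _, _ = run_comparison(p_i, life_table)
        inc_cost[i] = result.inc_cost
        inc_qaly[i] = result.inc_qaly

    base_result, _, _ = run_comparison(params, life_table)
    return PsaDraws(parameter_names=names, samples=samples, inc_cost=inc_cost,
                    inc_qaly=inc_qaly, rng_seed=seed, resample_count=resampled,
                    base_result=base_result)


def ceac(draws: PsaDraws, wtp_grid) -> pd.DataFrame:
    """Probability of cost-effectiveness at each threshold: the fraction of
    draws with strictly positive net monetary benefit."""
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValidationError("wtp grid is empty")
    probs = [float(np.mean(w * draws.inc_qaly - draws.inc_cost > 0)) for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "probability": probs})


def horizon_sweep(params: ModelParameters, life_table: LifeTable,
                  horizons: list[int]) -> pd.DataFrame:
    """Base-case reruns at alternative horizons (all else unchanged)."""
    rows = []
    for h in horizons:
        if h < 1:
            raise ValidationError("horizon must be >= 1")
        p_h = dataclasses.replace(
            params, settings=dataclasses.replace(params.settings, horizon_years=int(h)))
        result, _, _ = run_comparison(p_h, life_table)
        rows.append({"horizon": int(h), "inc_cost": result.inc_cost,
                     "inc_qaly": result.inc_qaly,
                     "icer": result.icer if result.icer is not None else np.nan})
    return pd.DataFrame(rows)
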