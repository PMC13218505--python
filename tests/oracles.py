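"""Independent oracles shared across test modules (kept outside the
package so the implementation under test cannot use them)."""

import numpy as np

from lipidcea.markov import (HealthState, _state_costs, _state_utilities,
                             discount_factor, transition_matrix)


def microsimulate(params, arm, life_table, n_walkers, rng):
    """Individual-level re-simulation using the same per-cycle transition
    matrices; returns per-walker discounted (costs, qalys) arrays."""
    settings = params.settings
    horizon = settings.horizon_years
    util = _state_utilities(params)
    states = np.zeros(n_walkers, dtype=np.int64)
    qalys = np.zeros(n_walkers)
    costs = np.zeros(n_walkers)
    for k in range(1, horizon + 1):
        age = params.population.mean_age + k - 1
        m = transition_matrix(params, arm, life_table, age)
        cum = m.cumsum(axis=1)
        df = discount_factor(settings.discount_rate, k, settings.half_cycle)
        state_cost = _state_costs(params, arm, k)
        qalys += util[states] * df
        costs += state_cost[states] * df
        u = rng.random(n_walkers)
        new_states = (u[:, None] > cum[states]).sum(axis=1)
        died_cv = (new_states == HealthState.DEAD_CV) & (states != HealthState.DEAD_CV)
        died_ncv = ((new_states == HealthState.DEAD_NONCV)
                    & (states != HealthState.DEAD_NONCV))
        costs[died_cv] += params.costs.cv_death.point * df
        costs[died_ncv] += params.costs.non_cv_death.point * df
        states = new_states
    return costs, qalys
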