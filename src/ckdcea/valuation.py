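"""Attach discounted costs and QALYs to a cohort trace.

Accrual convention: cycle ``k`` (k = 1..K) is valued on the occupancy
after the k-th transition, discounted by ``(1 + r)^(-k / cycles_per_year)``;
with the half-cycle correction enabled, state costs and utilities use
the average of start- and end-of-cycle occupancy instead.  One-off
quantities tied to events of cycle k (acute CV costs and disutilities,
death costs) are discounted at the same factor.  Post-acute CV costs
and disutilities apply to the post-CV population from the cycle after
the incident event, with no decay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import CohortTrace
from .params import (
    CV_EVENT_TYPES,
    EVENT_DISUTILITY_GROUP,
    CostTable,
    CVEventMix,
    ParameterSet,
    UtilityTable,
)
from .states import (
    ALIVE_STATES,
    DEAD,
    N_ALIVE,
    PRE_RRT_STATES,
    STRATEGY_DRUGS,
    Strategy,
)


def discount_factor(
    cycle_index: int, annual_rate: float, cycles_per_year: int
) -> float:
    """Discount factor at a cycle: ``(1 + rate)^(-cycle / cycles_per_year)``."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be non-negative")
    return float((1.0 + annual_rate) ** (-cycle_index / cycles_per_year))


@dataclass
class CompositeCVEconomics:
    """Mix-weighted economics of the composite CV event."""

    acute_cost: float
    postacute_cost_per_cycle: float
    acute_disutility: float
    postacute_disutility: float


def composite_cv_economics(
    mix: CVEventMix, costs: CostTable, utils: UtilityTable
) -> CompositeCVEconomics:
    """Weight event-type costs and disutilities by the composite mix.

    Both stroke types share the stroke disutility row.
    """
    acute_cost = postacute_cost = acute_dis = postacute_dis = 0.0
    for ev in CV_EVENT_TYPES:
        w = mix.proportions.get(ev, 0.0)
        acute_cost += w * costs.cv_event_costs[ev]["acute"]
        postacute_cost += w * costs.cv_event_costs[ev]["postacute"]
        grp = EVENT_DISUTILITY_GROUP[ev]
        acute_dis += w * utils.cv_disutility[grp]["acute"]
        postacute_dis += w * utils.cv_disutility[grp]["postacute"]
    return CompositeCVEconomics(
        acute_cost=acute_cost,
        postacute_cost_per_cycle=postacute_cost,
        acute_disutility=acute_dis,
        postacute_disutility=postacute_dis,
    )


@dataclass
class ValuedTrace:
    """Per-cycle discounted and undiscounted cost/QALY streams."""

    strategy: Strategy
    cost_by_cycle: np.ndarray
    qaly_by_cycle: np.ndarray
    cost_by_cycle_undiscounted: np.ndarray
    qaly_by_cycle_undiscounted: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.cost_by_cycle.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.qaly_by_cycle.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self.cost_by_cycle)),
                "cost": self.cost_by_cycle,
                "qaly": self.qaly_by_cycle,
                "cost_undiscounted": self.cost_by_cycle_undiscounted,
                "qaly_undiscounted": self.qaly_by_cycle_undiscounted,
            }
        )


def value_trace(
    trace: CohortTrace, ps: ParameterSet, strategy: Strategy | str
) -> ValuedTrace:
    """Compute the discounted cost and QALY stream of one arm."""
    strategy = Strategy(strategy)
    settings = ps.settings
    cpy = settings.cycles_per_year
    cycle_len = settings.cycle_length_years
    n_cycles = trace.n_cycles

    comp = composite_cv_economics(ps.cv_mix, ps.costs, ps.utilities)
    state_cost = np.array(
        [ps.costs.state_cost_per_cycle[s] for s in ALIVE_STATES]
    )
    state_util = np.array([ps.utilities.state_utility[s] for s in ALIVE_STATES])
    soc_drug = ps.costs.drug_cost_per_cycle["SoC"]
    drug_map = {"finerenone": "finerenone", "SGLT2i": "SGLT2i"}
    try:
        intervention_cost = sum(
            ps.costs.drug_cost_per_cycle[drug_map[d]]
            for d in STRATEGY_DRUGS[strategy]
        )
    except KeyError as exc:
        raise ValueError(f"no drug-cost mapping for strategy {strategy}") from exc
    if settings.drug_continue_on_rrt:
        intervention_mask = np.ones(N_ALIVE)
    else:
        intervention_mask = np.array(
            [1.0 if s in PRE_RRT_STATES else 0.0 for s in ALIVE_STATES]
        )

    cost = np.zeros(n_cycles + 1)
    qaly = np.zeros(n_cycles + 1)
    cost_u = np.zeros(n_cycles + 1)
    qaly_u = np.zeros(n_cycles + 1)

    for k in range(1, n_cycles + 1):
        occ_state = trace.state_occupancy(k)
        if settings.half_cycle_correction:
            occ_state = 0.5 * (occ_state + trace.state_occupancy(k - 1))
            post_cv = 0.5 * (
                trace.post_cv_occupancy(k) + trace.post_cv_occupancy(k - 1)
            )
        else:
            post_cv = trace.post_cv_occupancy(k)

        new_first = trace.new_first_cv[k]
        new_subseq = trace.new_subsequent_cv[k]
        # Post-acute economics start the cycle after the incident event.
        post_acute_pop = max(post_cv - new_first, 0.0)

        c = float(occ_state @ state_cost)
        c += float(occ_state.sum()) * soc_drug
        on_drug = (
            trace.on_drug_fraction[k]
            if settings.discontinuation_stops_drug_cost
            else 1.0
        )
        c += float(occ_state @ intervention_mask) * intervention_cost * on_drug
        c += comp.acute_cost * (new_first + new_subseq)
        c += comp.postacute_cost_per_cycle * post_acute_pop
        c += ps.costs.death_cost * trace.new_deaths[k]
        c += ps.costs.ae_costs.get("hyperkalemia", 0.0) * trace.ae_counts[
            "hyperkalemia"
        ][k]
        c += ps.costs.ae_costs.get("aki", 0.0) * trace.ae_counts["aki"][k]

        q = float(occ_state @ state_util) * cycle_len
        q += comp.acute_disutility * (new_first + new_subseq) * cycle_len
        q += comp.postacute_disutility * post_acute_pop * cycle_len
        q = max(q, 0.0)

        d = discount_factor(k, settings.discount_rate_annual, cpy)
        cost[k] = c * d
        qaly[k] = q * d
        cost_u[k] = c
        qaly_u[k] = q

    return ValuedTrace(
        strategy=strategy,
        cost_by_cycle=cost,
        qaly_by_cycle=qaly,
        cost_by_cycle_undiscounted=cost_u,
        qaly_by_cycle_undiscounted=qaly_u,
    )
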