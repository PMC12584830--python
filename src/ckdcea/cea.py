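"""Arm totals and pairwise incremental cost-effectiveness results.

Net monetary benefit: ``NMB = dQALY x WTP - dCost``; positive at the
chosen willingness-to-pay threshold means the reference strategy is
cost-effective against the comparator.  A strategy is *dominant* when
it is both cheaper and more effective, *dominated* in the reverse case;
the ICER is undefined under dominance and reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .engine import run_model
from .params import ParameterSet
from .states import Strategy
from .valuation import ValuedTrace, value_trace

ICER_EPS = 1e-12


@dataclass
class ArmResult:
    strategy: Strategy
    total_cost: float
    total_qalys: float


@dataclass
class IncrementalResult:
    reference: Strategy
    comparator: Strategy
    incr_cost: float
    incr_qalys: float
    nmb: float
    icer: float | None
    dominance: str  # "dominant" | "dominated" | "none"


def summarize_arm(vt: ValuedTrace, strategy: Strategy | str | None = None) -> ArmResult:
    """Sum the discounted streams of one arm."""
    strat = Strategy(strategy) if strategy is not None else vt.strategy
    return ArmResult(
        strategy=strat,
        total_cost=vt.total_cost,
        total_qalys=vt.total_qalys,
    )


def incremental(a: ArmResult, b: ArmResult, wtp: float) -> IncrementalResult:
    """Pairwise comparison of reference arm ``a`` against comparator ``b``."""
    d_cost = a.total_cost - b.total_cost
    d_qaly = a.total_qalys - b.total_qalys
    nmb = d_qaly * wtp - d_cost
    if d_cost < 0 and d_qaly > 0:
        dominance = "dominant"
    elif d_cost > 0 and d_qaly < 0:
        dominance = "dominated"
    else:
        dominance = "none"
    icer = d_cost / d_qaly if abs(d_qaly) > ICER_EPS else None
    return IncrementalResult(
        reference=a.strategy,
        comparator=b.strategy,
        incr_cost=d_cost,
        incr_qalys=d_qaly,
        nmb=nmb,
        icer=icer,
        dominance=dominance,
    )


def evaluate_arm(
    ps: ParameterSet,
    strategy: Strategy | str,
    horizon_years: float | None = None,
) -> ArmResult:
    """Run the full pipeline (simulate, value, summarize) for one arm."""
    strategy = Strategy(strategy)
    trace = run_model(ps, strategy, horizon_years=horizon_years)
    return summarize_arm(value_trace(trace, ps, strategy))


def run_cea(
    ps: ParameterSet,
    reference: Strategy | str = Strategy.TRIPLE,
    comparators: tuple[Strategy | str, ...] = (Strategy.SGLT2I, Strategy.FINERENONE),
    horizon_years: float | None = None,
) -> tuple[dict[Strategy, ArmResult], list[IncrementalResult]]:
    """Evaluate the reference arm against each comparator.

    Returns per-arm totals and the pairwise incremental results at the
    WTP threshold in the settings.
    """
    reference = Strategy(reference)
    strategies = [reference] + [Strategy(c) for c in comparators]
    arms = {
        s: evaluate_arm(ps, s, horizon_years=horizon_years) for s in strategies
    }
    incr = [
        incremental(arms[reference], arms[Strategy(c)], ps.settings.wtp)
        for c in comparators
    ]
    return arms, incr


def results_table(
    arms: dict[Strategy, ArmResult], incrementals: list[IncrementalResult]
) -> pd.DataFrame:
    """Results table: one block per pairwise comparison.

    Each block lists the comparator (zero incrementals) followed by the
    reference arm with its incremental cost, incremental QALYs, NMB and
    dominance status.  Costs are rounded to 2 decimals and QALYs to 3
    for display; internal values keep full precision.
    """
    rows = []
    for inc in incrementals:
        comp_arm = arms[inc.comparator]
        ref_arm = arms[inc.reference]
        rows.append(
            {
                "comparison": f"{inc.reference.value} vs {inc.comparator.value}",
                "strategy": inc.comparator.value,
                "cost": round(comp_arm.total_cost, 2),
                "incr_cost": 0.0,
                "qalys": round(comp_arm.total_qalys, 3),
                "incr_qalys": 0.0,
                "nmb": 0.0,
                "dominance": "",
            }
        )
        rows.append(
            {
                "comparison": f"{inc.reference.value} vs {inc.comparator.value}",
                "strategy": inc.reference.value,
                "cost": round(ref_arm.total_cost, 2),
                "incr_cost": round(inc.incr_cost, 2),
                "qalys": round(ref_arm.total_qalys, 3),
                "incr_qalys": round(inc.incr_qalys, 3),
                "nmb": round(inc.nmb, 2),
                "dominance": inc.dominance,
            }
        )
    return pd.DataFrame(rows)
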