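"""Cohort simulation over the (health state x CV history) compartments.

The engine tracks the proportion of the cohort in each of 17
compartments (8 alive states x {no prior CV event, post-CV} + Dead)
across discrete four-month cycles, together with per-cycle tallies of
new first CV events, subsequent CV events, deaths, and expected adverse
events.

Within a cycle, under the default ``death_first`` ordering, each
compartment experiences (1) all-cause death at its state's per-cycle
probability, (2) renal-state transition of the survivors, carrying
their CV layer, and (3) CV events: survivors without CV history incur a
first event at their origin state's risk and land in the post-CV layer
of their destination state, while post-CV survivors incur subsequent
events (tallied; no layer change).  Adverse events are expected counts
and never move occupancy.  The alternative ``transition_first``
ordering transitions first and applies death and first-CV risks at the
destination state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adjust import StrategyModel, build_strategy_model
from .params import BaselineDistribution, ParameterSet
from .states import (
    ALIVE_STATES,
    DEAD,
    LAYER_NO_CV,
    LAYER_POST_CV,
    N_ALIVE,
    N_COMPARTMENTS,
    Strategy,
    compartment_index,
    compartment_labels,
)

MASS_TOL = 1e-9

AE_TALLY_TYPES = ("hyperkalemia", "aki", "discontinuation")


@dataclass
class CycleTallies:
    """Expected per-cycle event counts (cohort proportions)."""

    new_deaths: float = 0.0
    new_first_cv: float = 0.0
    new_subsequent_cv: float = 0.0
    ae: dict[str, float] = field(default_factory=dict)


@dataclass
class CohortTrace:
    """Occupancy and event tallies across the simulated horizon.

    ``occupancy[k]`` is the compartment distribution after ``k``
    transition cycles (row 0 is the initial cohort).  Event arrays hold
    the events that occurred during transition ``k`` (index 0 is zero).
    ``on_drug_fraction[k]`` is the fraction of the cohort not yet lost
    to AE-driven treatment discontinuation.
    """

    occupancy: np.ndarray  # (n_cycles + 1, 17)
    new_first_cv: np.ndarray
    new_subsequent_cv: np.ndarray
    new_deaths: np.ndarray
    ae_counts: dict[str, np.ndarray]
    on_drug_fraction: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive(self, cycle: int) -> np.ndarray:
        """Occupancy over the 16 alive compartments at a cycle."""
        return self.occupancy[cycle, :DEAD]

    def state_occupancy(self, cycle: int) -> np.ndarray:
        """Occupancy by alive health state, summed over CV layers."""
        row = self.occupancy[cycle]
        return row[:N_ALIVE] + row[N_ALIVE:DEAD]

    def post_cv_occupancy(self, cycle: int) -> float:
        return float(self.occupancy[cycle, N_ALIVE:DEAD].sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=compartment_labels())
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        df["new_first_cv"] = self.new_first_cv
        df["new_subsequent_cv"] = self.new_subsequent_cv
        df["new_deaths"] = self.new_deaths
        for ae_type, arr in self.ae_counts.items():
            df[f"ae_{ae_type}"] = arr
        df["on_drug_fraction"] = self.on_drug_fraction
        return df


def initialize_cohort(bd: BaselineDistribution, n_cycles: int) -> CohortTrace:
    """Allocate a trace with the cycle-0 occupancy set from ``bd``."""
    problems = bd.validate()
    if problems:
        raise ValueError("; ".join(problems))
    occ = np.zeros((n_cycles + 1, N_COMPARTMENTS))
    for s in ALIVE_STATES:
        share = bd.share.get(s, 0.0)
        occ[0, compartment_index(s, LAYER_NO_CV)] = share * (1 - bd.cv_history_share)
        occ[0, compartment_index(s, LAYER_POST_CV)] = share * bd.cv_history_share
    zeros = np.zeros(n_cycles + 1)
    return CohortTrace(
        occupancy=occ,
        new_first_cv=zeros.copy(),
        new_subsequent_cv=zeros.copy(),
        new_deaths=zeros.copy(),
        ae_counts={t: zeros.copy() for t in AE_TALLY_TYPES},
        on_drug_fraction=np.ones(n_cycles + 1),
    )


def step_cycle(
    occ: np.ndarray,
    sm: StrategyModel,
    event_order: str = "death_first",
) -> tuple[np.ndarray, CycleTallies]:
    """Advance the cohort one cycle; returns new occupancy and tallies."""
    occ = np.asarray(occ, dtype=float)
    if occ.shape != (N_COMPARTMENTS,):
        raise ValueError(f"occupancy must have shape ({N_COMPARTMENTS},)")
    if abs(occ.sum() - 1.0) > MASS_TOL:
        raise ValueError(f"occupancy sums to {occ.sum():.12f}, expected 1")

    m = sm.matrix.probs
    no_cv = occ[:N_ALIVE]
    post_cv = occ[N_ALIVE:DEAD]
    alive_by_state = no_cv + post_cv

    tallies = CycleTallies()
    # AEs accrue on the cohort alive at the start of the cycle and do not
    # alter occupancy.
    alive_total = float(alive_by_state.sum())
    tallies.ae = {t: alive_total * sm.ae.get(t, 0.0) for t in AE_TALLY_TYPES}

    if event_order == "death_first":
        deaths = float(no_cv @ sm.death + post_cv @ sm.death)
        surv_no = no_cv * (1 - sm.death)
        surv_post = post_cv * (1 - sm.death)
        # First events at origin-state risk; the eventing fraction lands in
        # the post-CV layer of its destination state.
        eventing = surv_no * sm.first_cv
        new_no_cv = (surv_no - eventing) @ m
        new_post_cv = (surv_post + eventing) @ m
        tallies.new_first_cv = float(eventing.sum())
        tallies.new_subsequent_cv = float(surv_post.sum() * sm.subsequent_cv)
    elif event_order == "transition_first":
        moved_no = no_cv @ m
        moved_post = post_cv @ m
        deaths = float(moved_no @ sm.death + moved_post @ sm.death)
        surv_no = moved_no * (1 - sm.death)
        surv_post = moved_post * (1 - sm.death)
        eventing = surv_no * sm.first_cv
        new_no_cv = surv_no - eventing
        new_post_cv = surv_post + eventing
        tallies.new_first_cv = float(eventing.sum())
        tallies.new_subsequent_cv = float(surv_post.sum() * sm.subsequent_cv)
    else:
        raise ValueError(f"unknown event_order {event_order!r}")

    tallies.new_deaths = deaths
    new_occ = np.empty(N_COMPARTMENTS)
    new_occ[:N_ALIVE] = new_no_cv
    new_occ[N_ALIVE:DEAD] = new_post_cv
    new_occ[DEAD] = occ[DEAD] + deaths
    return new_occ, tallies


def run_model(
    ps: ParameterSet,
    strategy: Strategy | str,
    horizon_years: float | None = None,
) -> CohortTrace:
    """Simulate one strategy over the horizon; deterministic.

    ``horizon_years`` overrides the value in the settings (e.g. 4 for
    the short-horizon scenario analysis).
    """
    strategy = Strategy(strategy)
    settings = ps.settings
    horizon = settings.horizon_years if horizon_years is None else horizon_years
    ratio = horizon / settings.cycle_length_years
    n_cycles = round(ratio)
    if n_cycles <= 0 or abs(ratio - n_cycles) > 1e-9:
        raise ValueError(
            f"horizon {horizon} is not a positive multiple of the cycle "
            f"length {settings.cycle_length_years}"
        )
    sm = build_strategy_model(ps, strategy)
    trace = initialize_cohort(ps.baseline, n_cycles)
    disc = sm.ae.get("discontinuation", 0.0)
    for k in range(1, n_cycles + 1):
        occ, tallies = step_cycle(
            trace.occupancy[k - 1], sm, event_order=settings.event_order
        )
        trace.occupancy[k] = occ
        trace.new_first_cv[k] = tallies.new_first_cv
        trace.new_subsequent_cv[k] = tallies.new_subsequent_cv
        trace.new_deaths[k] = tallies.new_deaths
        for t in AE_TALLY_TYPES:
            trace.ae_counts[t][k] = tallies.ae[t]
        trace.on_drug_fraction[k] = trace.on_drug_fraction[k - 1] * (1 - disc)
    return trace
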