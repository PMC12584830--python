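"""Health-state and compartment bookkeeping for the CKD Markov model.

The cohort is tracked over eight alive health states -- four chronic
kidney disease (CKD) stages plus acute/post-acute dialysis and
transplant phases -- crossed with a cardiovascular (CV) history layer
(no prior CV event vs. post-CV), and one absorbing Dead state:
8 states x 2 layers + Dead = 17 compartments.
"""

from __future__ import annotations

from enum import Enum


class HealthState(str, Enum):
    """Alive health states, ordered from least to most severe renal status."""

    CKD12 = "CKD1/2"
    CKD3 = "CKD3"
    CKD4 = "CKD4"
    CKD5_NORRT = "CKD5_noRRT"
    DIALYSIS_ACUTE = "Dialysis_acute"
    DIALYSIS_POSTACUTE = "Dialysis_postacute"
    TRANSPLANT_ACUTE = "Transplant_acute"
    TRANSPLANT_POSTACUTE = "Transplant_postacute"

    @property
    def index(self) -> int:
        return ALIVE_STATES.index(self)


ALIVE_STATES: tuple[HealthState, ...] = tuple(HealthState)
N_ALIVE = len(ALIVE_STATES)  # 8

#: CKD-stage states whose mutual progression is governed by the eGFR slope.
EARLY_STAGES = (HealthState.CKD12, HealthState.CKD3, HealthState.CKD4)

#: Origin states whose entries into late-stage renal events are governed by
#: the renal-composite hazard ratio.
LATE_EVENT_ORIGINS = (HealthState.CKD3, HealthState.CKD4, HealthState.CKD5_NORRT)

#: Destination states counted as late-stage renal events.
LATE_EVENT_TARGETS = (
    HealthState.CKD5_NORRT,
    HealthState.DIALYSIS_ACUTE,
    HealthState.TRANSPLANT_ACUTE,
)

#: Tunnel states: occupied for exactly one cycle before a mandatory move.
TUNNEL_STATES = (HealthState.DIALYSIS_ACUTE, HealthState.TRANSPLANT_ACUTE)

#: States in which intervention drugs (finerenone, SGLT2i) are given by
#: default; renal-replacement states drop them unless configured otherwise.
PRE_RRT_STATES = (
    HealthState.CKD12,
    HealthState.CKD3,
    HealthState.CKD4,
    HealthState.CKD5_NORRT,
)

# Compartment layout: [no-CV x 8 states | post-CV x 8 states | Dead]
N_COMPARTMENTS = 2 * N_ALIVE + 1
DEAD = 2 * N_ALIVE  # index 16

LAYER_NO_CV = 0
LAYER_POST_CV = 1


def compartment_index(state: HealthState, layer: int) -> int:
    """Flat index of an (alive state, CV layer) compartment."""
    if layer not in (LAYER_NO_CV, LAYER_POST_CV):
        raise ValueError(f"invalid CV layer {layer!r}")
    return layer * N_ALIVE + state.index


def compartment_labels() -> list[str]:
    """Human-readable labels in flat-index order (for trace exports)."""
    labels = [f"{s.value}|noCV" for s in ALIVE_STATES]
    labels += [f"{s.value}|postCV" for s in ALIVE_STATES]
    labels.append("Dead")
    return labels


class Strategy(str, Enum):
    """Treatment strategies compared by the model."""

    SOC = "SoC"
    FINERENONE = "finerenone"
    SGLT2I = "SGLT2i"
    TRIPLE = "triple"


#: Which intervention drugs each strategy adds on top of SoC.
STRATEGY_DRUGS: dict[Strategy, tuple[str, ...]] = {
    Strategy.SOC: (),
    Strategy.FINERENONE: ("finerenone",),
    Strategy.SGLT2I: ("SGLT2i",),
    Strategy.TRIPLE: ("finerenone", "SGLT2i"),
}
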