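"""Rate/probability conversions and strategy-specific model construction.

Relative treatment effects (hazard ratios, the relative eGFR decline
rate) are applied on the rate scale: a per-cycle probability ``p`` under
standard of care becomes ``1 - (1 - p)**ratio`` under a strategy with
rate ratio ``ratio``.  This is equivalent to converting the probability
to a constant instantaneous rate via ``r = -ln(1 - p)/t``, multiplying
the rate, and converting back, and keeps probabilities in ``[0, 1]`` for
any positive ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ParameterSet, TransitionMatrix
from .states import (
    ALIVE_STATES,
    EARLY_STAGES,
    LATE_EVENT_ORIGINS,
    LATE_EVENT_TARGETS,
    HealthState,
    Strategy,
)


class InfeasibleAdjustmentError(ValueError):
    """An effect adjustment drove a row's stay-probability negative."""


def prob_to_rate(p: float, t: float = 1.0) -> float:
    """Instantaneous rate per year from a probability over period ``t``.

    ``r = -ln(1 - p) / t``; inverse of :func:`rate_to_prob`.
    """
    if not 0 <= p < 1:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    if t <= 0:
        raise ValueError(f"period must be positive, got {t}")
    return -math.log1p(-p) / t

def rate_to_prob(r: float, t: float = 1.0) -> float:
    """Probability over period ``t`` from a constant rate: ``1 - exp(-r t)``."""
    if r < 0:
        raise ValueError(f"rate must be non-negative, got {r}")
    if t <= 0:
        raise ValueError(f"period must be positive, got {t}")
    return -math.expm1(-r * t)


def apply_ratio_to_prob(p, ratio: float):
    """Apply a hazard/rate ratio to a per-cycle probability.

    ``p' = 1 - (1 - p)**ratio``.  Accepts scalars or arrays; period
    length cancels, so none is needed.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 1):
        raise ValueError("probabilities must be in [0, 1) to apply a ratio")
    if ratio < 0:
        raise ValueError(f"ratio must be non-negative, got {ratio}")
    out = -np.expm1(ratio * np.log1p(-arr))
    return float(out) if np.isscalar(p) else out


def _rescale_rows(
    m: TransitionMatrix,
    rows: tuple[HealthState, ...],
    cols: tuple[HealthState, ...],
    ratio: float,
) -> TransitionMatrix:
    """Apply a ratio to selected off-diagonal transitions.

    The diagonal (stay) probability absorbs the change so each touched
    row re-sums to 1.
    """
    out = m.copy()
    probs = out.probs
    for frm in rows:
        i = frm.index
        delta = 0.0
        for to in cols:
            j = to.index
            if i == j:
                continue
            old = probs[i, j]
            if old == 0.0:
                continue
            new = apply_ratio_to_prob(old, ratio)
            probs[i, j] = new
            delta += new - old
        stay = probs[i, i] - delta
        if stay < -1e-12:
            raise InfeasibleAdjustmentError(
                f"row {frm.value}: stay-probability {stay:.6f} < 0 after "
                f"applying ratio {ratio}"
            )
        probs[i, i] = max(stay, 0.0)
    return out


def scale_progression(m: TransitionMatrix, rel_decline: float) -> TransitionMatrix:
    """Scale CKD-stage progression by the relative eGFR decline rate.

    Transitions from CKD 1/2, 3 or 4 to a strictly worse stage within
    {CKD 1/2, CKD 3, CKD 4} are adjusted on the rate scale; regressions
    (e.g. CKD 3 -> CKD 1/2) are left untouched and the stay-probability
    absorbs the difference.
    """
    if rel_decline <= 0:
        raise ValueError(f"rel_decline must be positive, got {rel_decline}")
    out = m.copy()
    probs = out.probs
    for frm in EARLY_STAGES:
        i = frm.index
        delta = 0.0
        for to in EARLY_STAGES:
            j = to.index
            if j <= i:  # stay or regression: untouched
                continue
            old = probs[i, j]
            if old == 0.0:
                continue
            new = apply_ratio_to_prob(old, rel_decline)
            probs[i, j] = new
            delta += new - old
        stay = probs[i, i] - delta
        if stay < -1e-12:
            raise InfeasibleAdjustmentError(
                f"row {frm.value}: stay-probability {stay:.6f} < 0 after "
                f"progression scaling by {rel_decline}"
            )
        probs[i, i] = max(stay, 0.0)
    return out


def scale_late_stage(m: TransitionMatrix, hr_renal: float) -> TransitionMatrix:
    """Scale late-stage renal events by the renal-composite hazard ratio.

    Entries into CKD 5 without RRT, acute dialysis and acute transplant
    from CKD 3, CKD 4 and CKD 5 rows are adjusted; tunnel rows (acute
    dialysis/transplant) are never touched.
    """
    if hr_renal <= 0:
        raise ValueError(f"hr_renal must be positive, got {hr_renal}")
    return _rescale_rows(m, LATE_EVENT_ORIGINS, LATE_EVENT_TARGETS, hr_renal)


@dataclass
class StrategyModel:
    """Per-cycle dynamics of one treatment strategy.

    Holds the effect-adjusted transition matrix and state-indexed event
    probabilities, plus the per-cycle adverse-event risks, ready for the
    cohort engine.
    """

    strategy: Strategy
    matrix: TransitionMatrix
    first_cv: np.ndarray  # per alive state
    subsequent_cv: float
    death: np.ndarray  # per alive state
    ae: dict[str, float]

    def validate(self) -> list[str]:
        problems = self.matrix.validate()
        for name, arr in (("first_cv", self.first_cv), ("death", self.death)):
            if np.any(arr < 0) or np.any(arr > 1):
                problems.append(f"StrategyModel.{name}: probability outside [0, 1]")
        return problems


def build_strategy_model(ps: ParameterSet, strategy: Strategy | str) -> StrategyModel:
    """Construct the adjusted model for one strategy.

    The SoC matrix is scaled first for eGFR-slope progression then for
    late-stage renal events; first-CV and death probabilities are
    adjusted with the strategy's hazard ratios.  SoC itself (all ratios
    1) returns the inputs unchanged.
    """
    strategy = Strategy(strategy)
    eff = ps.effects
    matrix = scale_late_stage(
        scale_progression(ps.matrix, eff.rel_egfr_decline[strategy]),
        eff.hr_renal_composite[strategy],
    )
    first_cv = np.array(
        [
            apply_ratio_to_prob(ps.risks.first_cv[s], eff.hr_first_cv[strategy])
            for s in ALIVE_STATES
        ]
    )
    death = np.array(
        [
            apply_ratio_to_prob(ps.risks.death[s], eff.hr_mortality[strategy])
            for s in ALIVE_STATES
        ]
    )
    return StrategyModel(
        strategy=strategy,
        matrix=matrix,
        first_cv=first_cv,
        subsequent_cv=ps.risks.subsequent_cv,
        death=death,
        ae=dict(ps.risks.ae.get(strategy, {})),
    )
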