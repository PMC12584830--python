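"""Random, structurally valid parameter sets for testing and demos.

The generator emulates the statistical structure the analysis assumes
-- a row-stochastic CKD progression matrix with the reference zero
pattern (tunnel states, no return from transplant, rare late-stage
jumps), per-cycle event risks well below 1, positive costs, utilities
in [0.5, 1], and relative effects near 1 -- not any patient-level
data, since the model consumes only aggregate parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    AE_TYPES,
    CV_DISUTILITY_GROUPS,
    CV_EVENT_TYPES,
    BaselineDistribution,
    ClinicalRisks,
    CostTable,
    CVEventMix,
    ModelSettings,
    ParameterRange,
    ParameterSet,
    TransitionMatrix,
    TreatmentEffects,
    UtilityTable,
)
from .states import ALIVE_STATES, N_ALIVE, HealthState as H, Strategy as S

#: Reachability mask of the reference matrix layout: 1 where a transition
#: may carry probability.  Tunnel rows and the absorbing transplant
#: (post-acute) row are fixed and not randomised.
STRUCTURAL_MASK = np.array(
    [
        [1, 1, 1, 0, 0, 0, 0, 0],  # CKD 1/2
        [1, 1, 1, 1, 1, 0, 1, 0],  # CKD 3
        [0, 1, 1, 1, 1, 0, 0, 0],  # CKD 4
        [0, 1, 1, 1, 1, 0, 1, 0],  # CKD 5 w/o RRT
        [0, 0, 0, 0, 0, 1, 0, 0],  # Dialysis (acute): tunnel
        [0, 0, 0, 0, 0, 1, 1, 0],  # Dialysis (post-acute)
        [0, 0, 0, 0, 0, 0, 0, 1],  # Transplant (acute): tunnel
        [0, 0, 0, 0, 0, 0, 0, 1],  # Transplant (post-acute): absorbing
    ],
    dtype=bool,
)

_FIXED_ROWS = (
    H.DIALYSIS_ACUTE.index,
    H.TRANSPLANT_ACUTE.index,
    H.TRANSPLANT_POSTACUTE.index,
)


@dataclass
class GeneratorConfig:
    """Knobs of the random generator.

    ``risk_scale`` and ``cost_scale`` multiply the typical magnitudes;
    ``effect_range`` bounds the sampled treatment-effect ratios.
    """

    seed: int = 0
    risk_scale: float = 1.0
    cost_scale: float = 1.0
    effect_range: tuple[float, float] = (0.3, 1.2)

    def validate(self) -> None:
        if self.risk_scale <= 0 or self.cost_scale <= 0:
            raise ValueError("scales must be positive")
        lo, hi = self.effect_range
        if not 0 < lo <= hi:
            raise ValueError("effect_range must be a positive interval")


def random_transition_matrix(cfg: GeneratorConfig) -> TransitionMatrix:
    """Row-stochastic matrix respecting the reference structural zeros.

    Each free row draws Dirichlet weights over its reachable targets,
    tilted so the diagonal dominates (slow progression); tunnel and
    absorbing rows are deterministic.  Seed-reproducible.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    m = np.zeros((N_ALIVE, N_ALIVE))
    for i in range(N_ALIVE):
        mask = STRUCTURAL_MASK[i]
        if i in _FIXED_ROWS:
            j = int(np.flatnonzero(mask)[0])
            m[i, j] = 1.0
            continue
        idx = np.flatnonzero(mask)
        alpha = np.where(idx == i, 50.0, 1.0)
        m[i, idx] = rng.dirichlet(alpha)
    return TransitionMatrix(m)


def random_parameter_set(cfg: GeneratorConfig) -> ParameterSet:
    """Full random ParameterSet passing validation.

    Ranges are generated as base x (0.8, 1.2), clipped to each
    parameter's support, so the sensitivity machinery is exercisable on
    generated sets.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    matrix = random_transition_matrix(
        GeneratorConfig(seed=cfg.seed, effect_range=cfg.effect_range)
    )

    ranges: dict[str, ParameterRange] = {}

    def ranged(pid: str, base: float, family: str, upper: float | None = None) -> float:
        lo, hi = base * 0.8, base * 1.2
        if base < 0:
            lo, hi = hi, lo
        if upper is not None:
            hi = min(hi, upper)
        if lo != hi:
            ranges[pid] = ParameterRange(base, lo, hi, family)
        return base

    def prob(scale: float) -> float:
        return float(np.clip(rng.uniform(0.2, 1.0) * scale * cfg.risk_scale, 0, 0.5))

    first_cv = {
        s: ranged(f"first_cv.{s.value}", prob(0.03), "beta", upper=0.99)
        for s in ALIVE_STATES
    }
    subsequent_cv = ranged("subsequent_cv", prob(0.15), "beta", upper=0.99)
    death = {
        s: ranged(f"death.{s.value}", prob(0.04), "beta", upper=0.99)
        for s in ALIVE_STATES
    }
    ae = {
        strat: {
            t: ranged(f"ae.{strat.value}.{t}", prob(0.01), "beta", upper=0.99)
            for t in AE_TYPES
        }
        for strat in (S.FINERENONE, S.SGLT2I, S.TRIPLE)
    }
    ae[S.SOC] = {t: 0.0 for t in AE_TYPES}

    lo, hi = cfg.effect_range
    effects = {}
    for name in ("hr_first_cv", "hr_mortality", "rel_egfr_decline", "hr_renal_composite"):
        d = {S.SOC: 1.0}
        for strat in (S.FINERENONE, S.SGLT2I, S.TRIPLE):
            d[strat] = ranged(
                f"{name}.{strat.value}", float(rng.uniform(lo, hi)), "lognormal"
            )
        effects[name] = d

    def cost(scale: float) -> float:
        return float(rng.uniform(0.5, 1.5) * scale * cfg.cost_scale)

    state_costs = {
        s: ranged(f"cost.state.{s.value}", cost(5000.0), "gamma")
        for s in ALIVE_STATES
    }
    cv_costs = {
        ev: {
            "acute": ranged(f"cost.cv.{ev}.acute", cost(30000.0), "gamma"),
            "postacute": ranged(f"cost.cv.{ev}.postacute", cost(8000.0), "gamma"),
        }
        for ev in CV_EVENT_TYPES
    }
    ae_costs = {
        "hyperkalemia": ranged("cost.ae.hyperkalemia", cost(1500.0), "gamma"),
        "aki": ranged("cost.ae.aki", cost(30000.0), "gamma"),
    }
    drug_costs = {
        k: ranged(f"cost.drug.{k}", cost(1500.0), "gamma")
        for k in ("SoC", "finerenone", "SGLT2i")
    }
    death_cost = ranged("cost.death", cost(30000.0), "gamma")

    utilities = {
        s: ranged(f"utility.{s.value}", float(rng.uniform(0.5, 1.0)), "beta",
                  upper=1.0)
        for s in ALIVE_STATES
    }
    disutilities = {
        grp: {
            "acute": ranged(
                f"disutility.{grp}.acute", -float(rng.uniform(0.01, 0.1)), "beta"
            ),
            "postacute": ranged(
                f"disutility.{grp}.postacute", -float(rng.uniform(0.005, 0.05)),
                "beta",
            ),
        }
        for grp in CV_DISUTILITY_GROUPS
    }

    shares = rng.dirichlet(np.ones(3))
    share = {s: 0.0 for s in ALIVE_STATES}
    share[H.CKD12], share[H.CKD3], share[H.CKD4] = map(float, shares)
    mix = rng.dirichlet(np.ones(len(CV_EVENT_TYPES)))
    return ParameterSet(
        settings=ModelSettings(seed=cfg.seed),
        matrix=matrix,
        risks=ClinicalRisks(
            first_cv=first_cv, subsequent_cv=subsequent_cv, death=death, ae=ae
        ),
        effects=TreatmentEffects(**effects),
        costs=CostTable(
            state_cost_per_cycle=state_costs,
            cv_event_costs=cv_costs,
            ae_costs=ae_costs,
            drug_cost_per_cycle=drug_costs,
            death_cost=death_cost,
        ),
        utilities=UtilityTable(
            state_utility=utilities, cv_disutility=disutilities
        ),
        baseline=BaselineDistribution(share=share),
        cv_mix=CVEventMix(
            {ev: float(w) for ev, w in zip(CV_EVENT_TYPES, mix)}
        ),
        ranges=ranges,
    )
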