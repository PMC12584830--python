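"""Built-in reference inputs for the Chinese CKD + T2D analysis.

These are the published base-case parameter tables of the analysis this
package implements: the standard-of-care transition matrix, per-cycle
CV-event/death/adverse-event risks, FIDELITY-derived relative treatment
effects, 2023-CNY cost inputs, EQ-5D-5L utilities, and run settings
(four-month cycles, ten-year horizon, 5% annual discounting, WTP of
268,074 CNY per QALY).

Percentages are converted to proportions.  The baseline CKD-stage
distribution and the composite CV event-type mix were published only in
supplementary material not redistributed here; documented defaults are
supplied instead (see :func:`ckdcea.params.default_baseline` and
:func:`ckdcea.params.default_cv_mix`) and can be overridden via config.
"""

from __future__ import annotations

import numpy as np

from .params import (
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
    default_baseline,
    default_cv_mix,
)
from .states import ALIVE_STATES, HealthState as H, Strategy as S

# Standard-of-care transition matrix, printed as percentages, rows = from.
_SOC_MATRIX_PCT = np.array(
    [
        # CKD12   CKD3   CKD4   CKD5  D_ac   D_pa   T_ac   T_pa
        [59.38, 40.38, 0.24, 0.00, 0.00, 0.00, 0.00, 0.00],   # CKD 1/2
        [2.85, 87.35, 9.51, 0.09, 0.13, 0.00, 0.07, 0.00],    # CKD 3
        [0.00, 10.92, 81.24, 5.22, 2.62, 0.00, 0.00, 0.00],   # CKD 4
        [0.00, 0.39, 4.25, 43.70, 49.67, 0.00, 1.99, 0.00],   # CKD 5 w/o RRT
        [0.00, 0.00, 0.00, 0.00, 0.00, 100.00, 0.00, 0.00],   # Dialysis (acute)
        [0.00, 0.00, 0.00, 0.00, 0.00, 98.73, 1.27, 0.00],    # Dialysis (post-acute)
        [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 100.00],   # Transplant (acute)
        [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 100.00],   # Transplant (post-acute)
    ]
)

# (base, low, high) triples, probabilities as proportions.
_FIRST_CV = {
    H.CKD12: (0.0126, 0.0041, 0.0256),
    H.CKD3: (0.0095, 0.0069, 0.0126),
    H.CKD4: (0.0171, 0.0112, 0.0242),
    H.CKD5_NORRT: (0.0224, 0.0047, 0.0533),
    H.DIALYSIS_ACUTE: (0.0224, 0.0047, 0.0533),
    H.DIALYSIS_POSTACUTE: (0.0224, 0.0047, 0.0533),
    H.TRANSPLANT_ACUTE: (0.0171, 0.0112, 0.0242),
    H.TRANSPLANT_POSTACUTE: (0.0171, 0.0112, 0.0242),
}

_SUBSEQUENT_CV = (0.085, 0.0597, 0.1142)

# Death risks: dialysis states share one value, transplant states another.
_DEATH = {
    H.CKD12: (0.0092, 0.0060, 0.0166),
    H.CKD3: (0.0058, 0.0045, 0.0076),
    H.CKD4: (0.0085, 0.0055, 0.0127),
    H.CKD5_NORRT: (0.0160, 0.0034, 0.0506),
}
_DEATH_DIALYSIS = (0.0501, 0.0057, 0.0634)
_DEATH_TRANSPLANT = (0.0085, 0.0055, 0.0127)

_AE = {
    S.FINERENONE: {
        "hyperkalemia": (0.0016, 0.0012, 0.0020),
        "aki": (0.0040, 0.0031, 0.0051),
        "discontinuation": (0.0075, 0.0059, 0.0097),
    },
    S.SGLT2I: {
        "hyperkalemia": (0.0, 0.0, 0.0),
        "aki": (0.0038, 0.0030, 0.0050),
        "discontinuation": (0.0059, 0.0047, 0.0077),
    },
    S.TRIPLE: {
        "hyperkalemia": (0.0003, 0.0002, 0.0003),
        "aki": (0.0012, 0.0009, 0.0016),
        "discontinuation": (0.0047, 0.0037, 0.0061),
    },
}

_EFFECTS = {
    "hr_first_cv": {
        S.FINERENONE: (0.87, 0.70, 1.04),
        S.SGLT2I: (0.80, 0.64, 0.96),
        S.TRIPLE: (0.57, 0.46, 0.69),
    },
    "hr_mortality": {
        S.FINERENONE: (0.90, 0.72, 1.08),
        S.SGLT2I: (0.70, 0.56, 0.84),
        S.TRIPLE: (0.46, 0.37, 0.55),
    },
    "rel_egfr_decline": {
        S.FINERENONE: (0.68, 0.55, 0.82),
        S.SGLT2I: (0.93, 0.74, 1.11),
        S.TRIPLE: (0.52, 0.41, 0.62),
    },
    "hr_renal_composite": {
        S.FINERENONE: (0.78, 0.62, 0.94),
        S.SGLT2I: (0.52, 0.42, 0.62),
        S.TRIPLE: (0.27, 0.21, 0.32),
    },
}

_STATE_COSTS = {
    H.CKD12: (269.0, 215.0, 323.0),
    H.CKD3: (269.0, 215.0, 323.0),
    H.CKD4: (269.0, 215.0, 323.0),
    H.CKD5_NORRT: (1800.0, 1440.0, 2160.0),
    H.DIALYSIS_ACUTE: (54604.0, 43683.0, 65525.0),
    H.DIALYSIS_POSTACUTE: (50106.0, 40085.0, 60128.0),
    H.TRANSPLANT_ACUTE: (228571.0, 182857.0, 274286.0),
    H.TRANSPLANT_POSTACUTE: (44337.0, 35470.0, 53025.0),
}

_CV_COSTS = {
    "MI": {"acute": (31267.0, 25014.0, 37520.0),
           "postacute": (12068.0, 9654.0, 14482.0)},
    "ischemic_stroke": {"acute": (10181.0, 8145.0, 12217.0),
                        "postacute": (10567.0, 8453.0, 12680.0)},
    "hemorrhagic_stroke": {"acute": (21355.0, 17084.0, 25626.0),
                           "postacute": (7455.0, 5964.0, 8946.0)},
    "HF": {"acute": (48429.0, 38743.0, 58115.0),
           "postacute": (6177.0, 4942.0, 7413.0)},
}

_AE_COSTS = {
    "hyperkalemia": (1000.0, 800.0, 1200.0),
    "aki": (40445.0, 18727.0, 95320.0),
}

_DRUG_COSTS = {
    "SoC": (1561.0, 1249.024, 1874.0),
    "finerenone": (1445.0, 1156.0, 1733.0),
    "SGLT2i": (494.0, 285.0, 703.0),
}

_DEATH_COST = (36487.0, 29189.0, 43784.0)

_UTILITIES = {
    H.CKD12: (0.884, 0.707, 1.000),
    H.CKD3: (0.884, 0.707, 1.000),
    H.CKD4: (0.884, 0.707, 1.000),
    H.CKD5_NORRT: (0.871, 0.696, 1.000),
    H.DIALYSIS_ACUTE: (0.804, 0.643, 0.964),
    H.DIALYSIS_POSTACUTE: (0.782, 0.625, 0.938),
    H.TRANSPLANT_ACUTE: (0.813, 0.650, 0.975),
    H.TRANSPLANT_POSTACUTE: (0.972, 0.777, 1.000),
}

_DISUTILITIES = {
    "MI": {"acute": (-0.075, -0.090, -0.060),
           "postacute": (-0.009, -0.011, -0.007)},
    "stroke": {"acute": (-0.059, -0.071, -0.047),
               "postacute": (-0.018, -0.022, -0.014)},
    "HF": {"acute": (-0.012, -0.014, -0.010),
           "postacute": (-0.07, -0.084, -0.056)},
}


def reference_parameter_set(
    baseline: BaselineDistribution | None = None,
    cv_mix: CVEventMix | None = None,
) -> ParameterSet:
    """Return the packaged reference inputs as a validated ParameterSet.

    Deterministic; every call returns an independent copy.  ``baseline``
    and ``cv_mix`` override the documented defaults for the two tables
    published only in supplementary material.
    """
    ranges: dict[str, ParameterRange] = {}

    def rng(pid: str, triple: tuple[float, float, float], family: str) -> float:
        base, low, high = triple
        if low == high == base or family == "none":
            # no usable range printed (e.g. the zero SGLT2i hyperkalemia risk)
            if not (low == high == base):
                ranges[pid] = ParameterRange(base, low, high, "none")
            return base
        ranges[pid] = ParameterRange(base, low, high, family)
        return base

    first_cv = {s: rng(f"first_cv.{s.value}", t, "beta")
                for s, t in _FIRST_CV.items()}
    subsequent_cv = rng("subsequent_cv", _SUBSEQUENT_CV, "beta")
    death = {s: rng(f"death.{s.value}", t, "beta") for s, t in _DEATH.items()}
    d_dial = rng("death.dialysis", _DEATH_DIALYSIS, "beta")
    death[H.DIALYSIS_ACUTE] = d_dial
    death[H.DIALYSIS_POSTACUTE] = d_dial
    d_tx = rng("death.transplant", _DEATH_TRANSPLANT, "beta")
    death[H.TRANSPLANT_ACUTE] = d_tx
    death[H.TRANSPLANT_POSTACUTE] = d_tx

    ae = {
        strat: {
            ae_type: rng(f"ae.{strat.value}.{ae_type}", t, "beta")
            for ae_type, t in d.items()
        }
        for strat, d in _AE.items()
    }
    ae[S.SOC] = {k: 0.0 for k in ("hyperkalemia", "aki", "discontinuation")}

    effects = {}
    for name, d in _EFFECTS.items():
        vals = {S.SOC: 1.0}
        for strat, t in d.items():
            vals[strat] = rng(f"{name}.{strat.value}", t, "lognormal")
        effects[name] = vals

    state_costs = {s: rng(f"cost.state.{s.value}", t, "gamma")
                   for s, t in _STATE_COSTS.items()}
    cv_costs = {
        ev: {phase: rng(f"cost.cv.{ev}.{phase}", t, "gamma")
             for phase, t in d.items()}
        for ev, d in _CV_COSTS.items()
    }
    ae_costs = {k: rng(f"cost.ae.{k}", t, "gamma") for k, t in _AE_COSTS.items()}
    drug_costs = {k: rng(f"cost.drug.{k}", t, "gamma")
                  for k, t in _DRUG_COSTS.items()}
    death_cost = rng("cost.death", _DEATH_COST, "gamma")

    utilities = {s: rng(f"utility.{s.value}", t, "beta")
                 for s, t in _UTILITIES.items()}
    disutilities = {
        grp: {phase: rng(f"disutility.{grp}.{phase}", t, "beta")
              for phase, t in d.items()}
        for grp, d in _DISUTILITIES.items()
    }

    return ParameterSet(
        settings=ModelSettings(),
        matrix=TransitionMatrix(_SOC_MATRIX_PCT / 100.0),
        risks=ClinicalRisks(
            first_cv=first_cv,
            subsequent_cv=subsequent_cv,
            death=death,
            ae=ae,
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
            state_utility=utilities,
            cv_disutility=disutilities,
        ),
        baseline=baseline if baseline is not None else default_baseline(),
        cv_mix=cv_mix if cv_mix is not None else default_cv_mix(),
        ranges=ranges,
    )
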