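"""Typed containers for every model input, with validation and config I/O.

All probabilities are stored as proportions (a printed ``9.51%`` is held
as ``0.0951``), all monetary amounts as CNY floats, and all utilities as
per-year preference weights.  A :class:`ParameterSet` bundles the
standard-of-care transition matrix, per-cycle clinical risks, relative
treatment effects, cost and utility tables, baseline cohort
distribution, composite CV event mix, and run settings, together with
the low/high ranges and distribution families used by the sensitivity
analyses.
"""

from __future__ import annotations

import copy
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterator

import numpy as np
import yaml

from .states import (
    ALIVE_STATES,
    N_ALIVE,
    HealthState,
    Strategy,
)

logger = logging.getLogger(__name__)

#: Component CV event types of the modelled composite event.
CV_EVENT_TYPES = ("MI", "ischemic_stroke", "hemorrhagic_stroke", "HF")

#: Disutility groups; both stroke types share one decrement.
CV_DISUTILITY_GROUPS = ("MI", "stroke", "HF")

#: Mapping from event type to its disutility group.
EVENT_DISUTILITY_GROUP = {
    "MI": "MI",
    "ischemic_stroke": "stroke",
    "hemorrhagic_stroke": "stroke",
    "HF": "HF",
}

AE_TYPES = ("hyperkalemia", "aki", "discontinuation")

ROW_SUM_TOL = 1e-9


class ValidationError(ValueError):
    """A parameter table violates one of its invariants."""


class ConfigError(ValueError):
    """A config file is malformed or incomplete."""


# ---------------------------------------------------------------------------
# Settings
# ---------------------------------------------------------------------------


@dataclass
class ModelSettings:
    """Run configuration.

    cycle_length_years
        Markov cycle length; 1/3 year (four months).
    horizon_years
        Simulated horizon; 10 years in the base case, 4 in the scenario
        analysis.
    discount_rate_annual
        Annual discount rate applied to both costs and QALYs (0.05).
    wtp
        Willingness-to-pay threshold, CNY per QALY (three times 2023
        GDP per capita, 268,074).
    psa_iterations
        Monte Carlo iterations for the probabilistic sensitivity
        analysis.
    half_cycle_correction
        Average start- and end-of-cycle occupancy when accruing state
        costs and QALYs.  Off by default.
    event_order
        Within-cycle ordering: ``"death_first"`` applies the death risk
        of the origin state before the survivors transition;
        ``"transition_first"`` transitions first and applies the death
        risk of the destination state.
    drug_continue_on_rrt
        Whether finerenone/SGLT2i costs continue to accrue in dialysis
        and transplant states (off by default).
    discontinuation_stops_drug_cost
        Whether the cumulative AE-discontinuation fraction stops paying
        for the intervention drugs (tally-only by default).
    """

    cycle_length_years: float = 1.0 / 3.0
    horizon_years: float = 10.0
    discount_rate_annual: float = 0.05
    wtp: float = 268_074.0
    psa_iterations: int = 1000
    seed: int | None = None
    half_cycle_correction: bool = False
    event_order: str = "death_first"
    drug_continue_on_rrt: bool = False
    discontinuation_stops_drug_cost: bool = False

    @property
    def cycles_per_year(self) -> int:
        return round(1.0 / self.cycle_length_years)

    @property
    def n_cycles(self) -> int:
        return round(self.horizon_years / self.cycle_length_years)

    def validate(self) -> list[str]:
        problems = []
        if not self.cycle_length_years > 0:
            problems.append("settings: cycle_length_years must be positive")
        else:
            ratio = self.horizon_years / self.cycle_length_years
            if abs(ratio - round(ratio)) > 1e-9:
                problems.append(
                    "settings: horizon_years must be an integer multiple of "
                    "cycle_length_years"
                )
        if not 0 <= self.discount_rate_annual < 1:
            problems.append("settings: discount_rate_annual must be in [0, 1)")
        if not self.wtp > 0:
            problems.append("settings: wtp must be positive")
        if self.event_order not in ("death_first", "transition_first"):
            problems.append(f"settings: unknown event_order {self.event_order!r}")
        return problems


# ---------------------------------------------------------------------------
# Core tables
# ---------------------------------------------------------------------------


@dataclass
class TransitionMatrix:
    """Row-stochastic per-cycle transition matrix over the 8 alive states."""

    probs: np.ndarray  # shape (8, 8)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_ALIVE, N_ALIVE):
            raise ValidationError(
                f"TransitionMatrix: expected shape {(N_ALIVE, N_ALIVE)}, "
                f"got {self.probs.shape}"
            )

    def validate(self) -> list[str]:
        problems = []
        if np.any(self.probs < -1e-15) or np.any(self.probs > 1 + 1e-15):
            problems.append("TransitionMatrix: entries must lie in [0, 1]")
        sums = self.probs.sum(axis=1)
        for i, s in enumerate(sums):
            if abs(s - 1.0) > ROW_SUM_TOL:
                problems.append(
                    f"TransitionMatrix: row {ALIVE_STATES[i].value} sums to "
                    f"{s:.12f}, expected 1"
                )
        return problems

    def copy(self) -> "TransitionMatrix":
        return TransitionMatrix(self.probs.copy())

    def __getitem__(self, key: tuple[HealthState, HealthState]) -> float:
        frm, to = key
        return float(self.probs[frm.index, to.index])

    def to_frame(self):
        import pandas as pd

        names = [s.value for s in ALIVE_STATES]
        return pd.DataFrame(self.probs, index=names, columns=names)

    @classmethod
    def from_rows(cls, rows: dict[str, dict[str, float]]) -> "TransitionMatrix":
        """Build from a nested mapping ``{from_state: {to_state: p}}``."""
        m = np.zeros((N_ALIVE, N_ALIVE))
        for frm_name, row in rows.items():
            frm = HealthState(frm_name)
            for to_name, p in row.items():
                m[frm.index, HealthState(to_name).index] = float(p)
        return cls(m)

    def to_rows(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for frm in ALIVE_STATES:
            out[frm.value] = {
                to.value: float(self.probs[frm.index, to.index])
                for to in ALIVE_STATES
                if self.probs[frm.index, to.index] != 0.0
            }
        return out


@dataclass
class ClinicalRisks:
    """Per-cycle event and death probabilities under standard of care."""

    first_cv: dict[HealthState, float]
    subsequent_cv: float
    death: dict[HealthState, float]
    ae: dict[Strategy, dict[str, float]]  # per-cycle AE probabilities

    def validate(self) -> list[str]:
        problems = []
        for table, d in (("first_cv", self.first_cv), ("death", self.death)):
            for s in ALIVE_STATES:
                p = d.get(s)
                if p is None:
                    problems.append(f"ClinicalRisks.{table}: missing {s.value}")
                elif not 0 <= p <= 1:
                    problems.append(
                        f"ClinicalRisks.{table}[{s.value}] = {p} outside [0, 1]"
                    )
        if not 0 <= self.subsequent_cv <= 1:
            problems.append(
                f"ClinicalRisks.subsequent_cv = {self.subsequent_cv} outside [0, 1]"
            )
        for strat, d in self.ae.items():
            for ae_type, p in d.items():
                if not 0 <= p <= 1:
                    problems.append(
                        f"ClinicalRisks.ae[{strat.value}][{ae_type}] = {p} "
                        "outside [0, 1]"
                    )
        return problems


@dataclass
class TreatmentEffects:
    """Relative effects of each strategy vs. standard of care.

    Hazard ratios act on the rate scale; the relative eGFR decline rate
    scales CKD-stage progression hazards.  SoC carries ratio 1 for
    every effect.
    """

    hr_first_cv: dict[Strategy, float]
    hr_mortality: dict[Strategy, float]
    rel_egfr_decline: dict[Strategy, float]
    hr_renal_composite: dict[Strategy, float]

    def validate(self) -> list[str]:
        problems = []
        for name in ("hr_first_cv", "hr_mortality", "rel_egfr_decline", "hr_renal_composite"):
            d = getattr(self, name)
            for strat in Strategy:
                v = d.get(strat)
                if v is None:
                    problems.append(f"TreatmentEffects.{name}: missing {strat.value}")
                elif not v > 0:
                    problems.append(
                        f"TreatmentEffects.{name}[{strat.value}] = {v} not positive"
                    )
        return problems


@dataclass
class CostTable:
    """All cost inputs in CNY.

    ``state_cost_per_cycle`` holds per-cycle management costs; for the
    acute (tunnel) states the entry is the one-off acute cost, charged
    for the single cycle of residence.  CV event costs are split into a
    one-off acute cost and a per-cycle post-acute cost by event type.
    """

    state_cost_per_cycle: dict[HealthState, float]
    cv_event_costs: dict[str, dict[str, float]]  # event -> {acute, postacute}
    ae_costs: dict[str, float]  # hyperkalemia, aki
    drug_cost_per_cycle: dict[str, float]  # SoC, finerenone, SGLT2i
    death_cost: float

    def validate(self) -> list[str]:
        problems = []
        for s in ALIVE_STATES:
            c = self.state_cost_per_cycle.get(s)
            if c is None:
                problems.append(f"CostTable.state_cost_per_cycle: missing {s.value}")
            elif c < 0:
                problems.append(
                    f"CostTable.state_cost_per_cycle[{s.value}] = {c} negative"
                )
        for ev in CV_EVENT_TYPES:
            row = self.cv_event_costs.get(ev)
            if row is None:
                problems.append(f"CostTable.cv_event_costs: missing {ev}")
                continue
            for phase in ("acute", "postacute"):
                c = row.get(phase)
                if c is None or c < 0:
                    problems.append(
                        f"CostTable.cv_event_costs[{ev}][{phase}] = {c} invalid"
                    )
        for k, c in self.ae_costs.items():
            if c < 0:
                problems.append(f"CostTable.ae_costs[{k}] = {c} negative")
        for k, c in self.drug_cost_per_cycle.items():
            if c < 0:
                problems.append(f"CostTable.drug_cost_per_cycle[{k}] = {c} negative")
        if self.death_cost < 0:
            problems.append(f"CostTable.death_cost = {self.death_cost} negative")
        return problems


@dataclass
class UtilityTable:
    """Per-year state utilities and additive CV-event disutilities."""

    state_utility: dict[HealthState, float]
    cv_disutility: dict[str, dict[str, float]]  # group -> {acute, postacute}

    def validate(self) -> list[str]:
        problems = []
        for s in ALIVE_STATES:
            u = self.state_utility.get(s)
            if u is None:
                problems.append(f"UtilityTable.state_utility: missing {s.value}")
            elif not 0 <= u <= 1:
                problems.append(
                    f"UtilityTable.state_utility[{s.value}] = {u} outside [0, 1]"
                )
        for grp in CV_DISUTILITY_GROUPS:
            row = self.cv_disutility.get(grp)
            if row is None:
                problems.append(f"UtilityTable.cv_disutility: missing {grp}")
                continue
            for phase in ("acute", "postacute"):
                d = row.get(phase)
                if d is None or d > 0:
                    problems.append(
                        f"UtilityTable.cv_disutility[{grp}][{phase}] = {d} "
                        "must be <= 0"
                    )
        return problems


@dataclass
class BaselineDistribution:
    """Cohort distribution over alive states at cycle 0."""

    share: dict[HealthState, float]
    cv_history_share: float = 0.0

    def validate(self) -> list[str]:
        problems = []
        total = 0.0
        for s, v in self.share.items():
            if v < 0:
                problems.append(f"BaselineDistribution.share[{s.value}] = {v} negative")
            total += v
        if abs(total - 1.0) > 1e-9:
            problems.append(f"BaselineDistribution: shares sum to {total}, expected 1")
        if not 0 <= self.cv_history_share <= 1:
            problems.append(
                f"BaselineDistribution.cv_history_share = {self.cv_history_share} "
                "outside [0, 1]"
            )
        return problems


@dataclass
class CVEventMix:
    """Proportion of each event type among composite CV events."""

    proportions: dict[str, float]

    def validate(self) -> list[str]:
        problems = []
        total = 0.0
        for ev in CV_EVENT_TYPES:
            p = self.proportions.get(ev)
            if p is None:
                problems.append(f"CVEventMix: missing {ev}")
            elif p < 0:
                problems.append(f"CVEventMix[{ev}] = {p} negative")
            else:
                total += p
        if abs(total - 1.0) > 1e-9:
            problems.append(f"CVEventMix: proportions sum to {total}, expected 1")
        return problems


@dataclass
class ParameterRange:
    """Base value with plausible low/high bounds and a sampling family."""

    base: float
    low: float
    high: float
    family: str = "none"  # beta | gamma | lognormal | none

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high or
                self.high <= self.base <= self.low):
            raise ValidationError(
                f"ParameterRange: base {self.base} outside [{self.low}, {self.high}]"
            )
        # Normalise so low <= high even for negative (disutility) ranges.
        if self.low > self.high:
            self.low, self.high = self.high, self.low
        if self.family not in ("beta", "gamma", "lognormal", "none"):
            raise ValidationError(f"ParameterRange: unknown family {self.family!r}")

    @property
    def degenerate(self) -> bool:
        return self.low == self.high


# ---------------------------------------------------------------------------
# Parameter set
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """Complete set of model inputs."""

    settings: ModelSettings
    matrix: TransitionMatrix
    risks: ClinicalRisks
    effects: TreatmentEffects
    costs: CostTable
    utilities: UtilityTable
    baseline: BaselineDistribution
    cv_mix: CVEventMix
    ranges: dict[str, ParameterRange] = field(default_factory=dict)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "settings": {
                "cycle_length_years": self.settings.cycle_length_years,
                "horizon_years": self.settings.horizon_years,
                "discount_rate_annual": self.settings.discount_rate_annual,
                "wtp": self.settings.wtp,
                "psa_iterations": self.settings.psa_iterations,
                "seed": self.settings.seed,
                "half_cycle_correction": self.settings.half_cycle_correction,
                "event_order": self.settings.event_order,
                "drug_continue_on_rrt": self.settings.drug_continue_on_rrt,
                "discontinuation_stops_drug_cost": (
                    self.settings.discontinuation_stops_drug_cost
                ),
            },
            "transition_matrix": self.matrix.to_rows(),
            "risks": {
                "first_cv": {s.value: self.risks.first_cv[s] for s in ALIVE_STATES},
                "subsequent_cv": self.risks.subsequent_cv,
                "death": {s.value: self.risks.death[s] for s in ALIVE_STATES},
                "ae": {
                    strat.value: dict(d) for strat, d in self.risks.ae.items()
                },
            },
            "effects": {
                name: {s.value: getattr(self.effects, name)[s] for s in Strategy}
                for name in (
                    "hr_first_cv",
                    "hr_mortality",
                    "rel_egfr_decline",
                    "hr_renal_composite",
                )
            },
            "costs": {
                "state_cost_per_cycle": {
                    s.value: self.costs.state_cost_per_cycle[s] for s in ALIVE_STATES
                },
                "cv_event_costs": {
                    ev: dict(d) for ev, d in self.costs.cv_event_costs.items()
                },
                "ae_costs": dict(self.costs.ae_costs),
                "drug_cost_per_cycle": dict(self.costs.drug_cost_per_cycle),
                "death_cost": self.costs.death_cost,
            },
            "utilities": {
                "state_utility": {
                    s.value: self.utilities.state_utility[s] for s in ALIVE_STATES
                },
                "cv_disutility": {
                    g: dict(d) for g, d in self.utilities.cv_disutility.items()
                },
            },
            "baseline": {
                "share": {s.value: v for s, v in self.baseline.share.items() if v},
                "cv_history_share": self.baseline.cv_history_share,
            },
            "cv_mix": dict(self.cv_mix.proportions),
            "ranges": {
                pid: {
                    "base": r.base,
                    "low": r.low,
                    "high": r.high,
                    "family": r.family,
                }
                for pid, r in self.ranges.items()
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        try:
            st = data.get("settings", {})
            settings = ModelSettings(**st)
            matrix = TransitionMatrix.from_rows(data["transition_matrix"])
            rk = data["risks"]
            risks = ClinicalRisks(
                first_cv={HealthState(k): float(v) for k, v in rk["first_cv"].items()},
                subsequent_cv=float(rk["subsequent_cv"]),
                death={HealthState(k): float(v) for k, v in rk["death"].items()},
                ae={
                    Strategy(k): {a: float(p) for a, p in d.items()}
                    for k, d in rk.get("ae", {}).items()
                },
            )
            ef = data["effects"]
            effects = TreatmentEffects(
                **{
                    name: {Strategy(k): float(v) for k, v in ef[name].items()}
                    for name in (
                        "hr_first_cv",
                        "hr_mortality",
                        "rel_egfr_decline",
                        "hr_renal_composite",
                    )
                }
            )
            co = data["costs"]
            costs = CostTable(
                state_cost_per_cycle={
                    HealthState(k): float(v)
                    for k, v in co["state_cost_per_cycle"].items()
                },
                cv_event_costs={
                    ev: {p: float(c) for p, c in d.items()}
                    for ev, d in co["cv_event_costs"].items()
                },
                ae_costs={k: float(v) for k, v in co["ae_costs"].items()},
                drug_cost_per_cycle={
                    k: float(v) for k, v in co["drug_cost_per_cycle"].items()
                },
                death_cost=float(co["death_cost"]),
            )
            ut = data["utilities"]
            utilities = UtilityTable(
                state_utility={
                    HealthState(k): float(v) for k, v in ut["state_utility"].items()
                },
                cv_disutility={
                    g: {p: float(v) for p, v in d.items()}
                    for g, d in ut["cv_disutility"].items()
                },
            )
        except KeyError as exc:
            raise ConfigError(f"config missing required key: {exc}") from exc
        except ValueError as exc:
            raise ConfigError(f"config has invalid value: {exc}") from exc

        if "baseline" in data:
            bl = data["baseline"]
            share = {s: 0.0 for s in ALIVE_STATES}
            for k, v in bl.get("share", {}).items():
                share[HealthState(k)] = float(v)
            baseline = BaselineDistribution(
                share=share, cv_history_share=float(bl.get("cv_history_share", 0.0))
            )
        else:
            baseline = default_baseline()
            logger.warning(
                "config omits baseline distribution; using default CKD-stage "
                "shares %s",
                {s.value: v for s, v in baseline.share.items() if v},
            )
        if "cv_mix" in data:
            cv_mix = CVEventMix({k: float(v) for k, v in data["cv_mix"].items()})
        else:
            cv_mix = default_cv_mix()
            logger.warning(
                "config omits CV event mix; using equal weights across %s",
                CV_EVENT_TYPES,
            )
        ranges = {
            pid: ParameterRange(**r) for pid, r in data.get("ranges", {}).items()
        }
        return cls(
            settings=settings,
            matrix=matrix,
            risks=risks,
            effects=effects,
            costs=costs,
            utilities=utilities,
            baseline=baseline,
            cv_mix=cv_mix,
            ranges=ranges,
        )


def default_baseline() -> BaselineDistribution:
    """Fallback baseline CKD-stage distribution.

    Used when a config supplies no cohort distribution; places the
    cohort across CKD 1/2, CKD 3 and CKD 4 (0.15/0.60/0.25), everyone
    without prior CV events.
    """
    share = {s: 0.0 for s in ALIVE_STATES}
    share[HealthState.CKD12] = 0.15
    share[HealthState.CKD3] = 0.60
    share[HealthState.CKD4] = 0.25
    return BaselineDistribution(share=share, cv_history_share=0.0)


def default_cv_mix() -> CVEventMix:
    """Fallback composite-event mix: equal weight to the four event types."""
    return CVEventMix({ev: 0.25 for ev in CV_EVENT_TYPES})


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    problems: list[str]

    @property
    def ok(self) -> bool:
        return not self.problems

    def __bool__(self) -> bool:
        return self.ok

    def __str__(self) -> str:
        return "OK" if self.ok else "\n".join(self.problems)


def validate_parameters(ps: ParameterSet) -> ValidationReport:
    """Check every table invariant; returns a report listing violations."""
    problems: list[str] = []
    problems += ps.settings.validate()
    problems += ps.matrix.validate()
    problems += ps.risks.validate()
    problems += ps.effects.validate()
    problems += ps.costs.validate()
    problems += ps.utilities.validate()
    problems += ps.baseline.validate()
    problems += ps.cv_mix.validate()
    return ValidationReport(problems)


# ---------------------------------------------------------------------------
# Config file I/O
# ---------------------------------------------------------------------------


def load_parameter_set(config_path: str | Path) -> ParameterSet:
    """Load a parameter set from a YAML or JSON config file.

    A config containing ``use_reference_inputs: true`` starts from the
    packaged reference inputs and applies any other keys as overrides.
    Raises :class:`ConfigError` for malformed files and
    :class:`ValidationError` when a table violates an invariant.
    """
    path = Path(config_path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    if data.pop("use_reference_inputs", False):
        from .fixtures import reference_parameter_set

        base = reference_parameter_set().to_dict()
        _deep_update(base, data)
        data = base

    ps = ParameterSet.from_dict(data)
    report = validate_parameters(ps)
    if not report.ok:
        raise ValidationError(str(report))
    return ps


def save_parameter_set(ps: ParameterSet, config_path: str | Path) -> None:
    """Write a parameter set to YAML (default) or JSON by extension."""
    path = Path(config_path)
    data = ps.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def _deep_update(base: dict, overrides: dict) -> None:
    for k, v in overrides.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


# ---------------------------------------------------------------------------
# Parameter registry (scalar access by id, for OWSA / PSA)
# ---------------------------------------------------------------------------

Getter = Callable[[ParameterSet], float]
Setter = Callable[[ParameterSet, float], None]


def _accessors(pid: str) -> tuple[Getter, Setter]:
    parts = pid.split(".")
    kind = parts[0]
    if kind == "first_cv":
        s = HealthState(parts[1])
        return (lambda ps: ps.risks.first_cv[s],
                lambda ps, v: ps.risks.first_cv.__setitem__(s, v))
    if kind == "subsequent_cv":
        def set_sub(ps: ParameterSet, v: float) -> None:
            ps.risks.subsequent_cv = v
        return (lambda ps: ps.risks.subsequent_cv, set_sub)
    if kind == "death":
        group = parts[1]
        if group == "dialysis":
            states = [HealthState.DIALYSIS_ACUTE, HealthState.DIALYSIS_POSTACUTE]
        elif group == "transplant":
            states = [HealthState.TRANSPLANT_ACUTE, HealthState.TRANSPLANT_POSTACUTE]
        else:
            states = [HealthState(group)]

        def set_death(ps: ParameterSet, v: float) -> None:
            for s in states:
                ps.risks.death[s] = v

        return (lambda ps: ps.risks.death[states[0]], set_death)
    if kind == "ae":
        strat, ae_type = Strategy(parts[1]), parts[2]
        return (lambda ps: ps.risks.ae[strat][ae_type],
                lambda ps, v: ps.risks.ae[strat].__setitem__(ae_type, v))
    if kind in ("hr_first_cv", "hr_mortality", "rel_egfr_decline", "hr_renal_composite"):
        strat = Strategy(parts[1])
        return (lambda ps: getattr(ps.effects, kind)[strat],
                lambda ps, v: getattr(ps.effects, kind).__setitem__(strat, v))
    if kind == "cost":
        sub = parts[1]
        if sub == "state":
            s = HealthState(parts[2])
            return (lambda ps: ps.costs.state_cost_per_cycle[s],
                    lambda ps, v: ps.costs.state_cost_per_cycle.__setitem__(s, v))
        if sub == "cv":
            ev, phase = parts[2], parts[3]
            return (lambda ps: ps.costs.cv_event_costs[ev][phase],
                    lambda ps, v: ps.costs.cv_event_costs[ev].__setitem__(phase, v))
        if sub == "ae":
            ae_type = parts[2]
            return (lambda ps: ps.costs.ae_costs[ae_type],
                    lambda ps, v: ps.costs.ae_costs.__setitem__(ae_type, v))
        if sub == "drug":
            drug = parts[2]
            return (lambda ps: ps.costs.drug_cost_per_cycle[drug],
                    lambda ps, v: ps.costs.drug_cost_per_cycle.__setitem__(drug, v))
        if sub == "death":
            def set_death_cost(ps: ParameterSet, v: float) -> None:
                ps.costs.death_cost = v
            return (lambda ps: ps.costs.death_cost, set_death_cost)
    if kind == "utility":
        s = HealthState(parts[1])
        return (lambda ps: ps.utilities.state_utility[s],
                lambda ps, v: ps.utilities.state_utility.__setitem__(s, v))
    if kind == "disutility":
        grp, phase = parts[1], parts[2]
        return (lambda ps: ps.utilities.cv_disutility[grp][phase],
                lambda ps, v: ps.utilities.cv_disutility[grp].__setitem__(phase, v))
    raise KeyError(f"unknown parameter id {pid!r}")


def get_param(ps: ParameterSet, pid: str) -> float:
    """Read the scalar value of a registered parameter."""
    return _accessors(pid)[0](ps)


def set_param(ps: ParameterSet, pid: str, value: float) -> None:
    """Set the scalar value of a registered parameter in place.

    Grouped parameters (shared dialysis/transplant death risks) update
    every state they cover.
    """
    _accessors(pid)[1](ps, value)


def with_param(ps: ParameterSet, pid: str, value: float) -> ParameterSet:
    """Return a deep copy of ``ps`` with one parameter replaced."""
    out = ps.copy()
    set_param(out, pid, value)
    return out


def iter_ranged_parameters(ps: ParameterSet) -> Iterator[tuple[str, ParameterRange]]:
    """Yield (parameter id, range) for every parameter with a usable range."""
    for pid, r in ps.ranges.items():
        yield pid, r
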