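"""One-way and probabilistic sensitivity analyses.

One-way analysis re-runs the model with a single parameter at its low
and then high bound, all else at base case, and ranks parameters by the
swing in net monetary benefit (tornado ordering).  Probabilistic
analysis samples every ranged parameter independently from a
distribution fitted to its base case and range -- beta for
probabilities and utilities, gamma for costs, lognormal for hazard
ratios -- and records the incremental results of each Monte Carlo
iteration.

Ranges are interpreted as 95% intervals, ``sd = (high - low) / 3.92``,
and distributions are fitted by the method of moments on the natural
scale.  When a beta fit is infeasible (variance too large for the
mean) the parameter falls back to a uniform draw over its range.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adjust import InfeasibleAdjustmentError
from .cea import evaluate_arm, incremental
from .params import (
    ParameterRange,
    ParameterSet,
    get_param,
    set_param,
    with_param,
)
from .states import Strategy

logger = logging.getLogger(__name__)

MEAN_TOL = 0.02  # fitted mean must sit within 2% of base


@dataclass
class DistSpec:
    """A fitted sampling distribution for one parameter.

    ``sign`` carries negative-valued parameters (disutilities): the
    distribution is fitted to the magnitude and the draw is negated.
    """

    family: str  # beta | gamma | lognormal | uniform | point
    params: dict[str, float]
    base: float
    sign: float = 1.0

    @property
    def mean(self) -> float:
        p = self.params
        if self.family == "point":
            return self.base
        if self.family == "beta":
            return self.sign * p["alpha"] / (p["alpha"] + p["beta"])
        if self.family == "gamma":
            return self.sign * p["shape"] * p["scale"]
        if self.family == "lognormal":
            return self.sign * math.exp(p["mu"] + p["sigma"] ** 2 / 2)
        if self.family == "uniform":
            return (p["low"] + p["high"]) / 2
        raise ValueError(self.family)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        p = self.params
        if self.family == "point":
            draw = np.full(size, self.base) if size else self.base
            return draw
        if self.family == "beta":
            draw = rng.beta(p["alpha"], p["beta"], size=size)
        elif self.family == "gamma":
            draw = rng.gamma(p["shape"], p["scale"], size=size)
        elif self.family == "lognormal":
            draw = rng.lognormal(p["mu"], p["sigma"], size=size)
        elif self.family == "uniform":
            draw = rng.uniform(p["low"], p["high"], size=size)
        else:
            raise ValueError(self.family)
        return self.sign * draw


def fit_distribution(pr: ParameterRange) -> DistSpec:
    """Fit a sampling distribution from base value and range.

    The range is read as a 95% interval; moments are matched so the
    fitted mean equals the base value.  Degenerate ranges collapse to a
    point mass.
    """
    if pr.degenerate or pr.family == "none":
        return DistSpec("point", {}, pr.base)

    sign = -1.0 if pr.base < 0 else 1.0
    m = abs(pr.base)
    lo, hi = sorted((abs(pr.low), abs(pr.high)))
    s = (pr.high - pr.low) / 3.92
    if s <= 0:
        return DistSpec("point", {}, pr.base)

    if pr.family == "beta":
        if not 0 < m < 1 or s * s >= m * (1 - m):
            logger.warning(
                "beta fit infeasible for base %s sd %s; falling back to "
                "uniform over the range",
                pr.base,
                s,
            )
            return DistSpec(
                "uniform", {"low": lo, "high": hi}, pr.base, sign=sign
            )
        nu = m * (1 - m) / (s * s) - 1
        return DistSpec(
            "beta", {"alpha": m * nu, "beta": (1 - m) * nu}, pr.base, sign=sign
        )
    if pr.family == "gamma":
        if m <= 0:
            return DistSpec("point", {}, pr.base)
        return DistSpec(
            "gamma", {"shape": m * m / (s * s), "scale": s * s / m},
            pr.base, sign=sign,
        )
    if pr.family == "lognormal":
        # moment match on the natural scale of the ratio
        sigma2 = math.log1p((s / m) ** 2)
        mu = math.log(m) - sigma2 / 2
        return DistSpec(
            "lognormal", {"mu": mu, "sigma": math.sqrt(sigma2)}, pr.base,
            sign=sign,
        )
    raise ValueError(f"unknown family {pr.family!r}")


def fit_distribution_log_ci(pr: ParameterRange) -> DistSpec:
    """Alternative lognormal fit treating (low, high) as a CI on the log scale."""
    if pr.degenerate:
        return DistSpec("point", {}, pr.base)
    mu = math.log(pr.base)
    sigma = (math.log(pr.high) - math.log(pr.low)) / 3.92
    return DistSpec("lognormal", {"mu": mu, "sigma": sigma}, pr.base)


# ---------------------------------------------------------------------------
# One-way sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class TornadoEntry:
    parameter: str
    low: float
    high: float
    nmb_low: float
    nmb_high: float

    @property
    def swing(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def _nmb(
    ps: ParameterSet,
    reference: Strategy,
    comparator: Strategy,
    wtp: float,
    horizon_years: float | None = None,
) -> float:
    a = evaluate_arm(ps, reference, horizon_years=horizon_years)
    b = evaluate_arm(ps, comparator, horizon_years=horizon_years)
    return incremental(a, b, wtp).nmb


def owsa(
    ps: ParameterSet,
    param_id: str,
    reference: Strategy | str = Strategy.TRIPLE,
    comparator: Strategy | str = Strategy.SGLT2I,
    wtp: float | None = None,
) -> TornadoEntry:
    """NMB of one comparison with a parameter at its low and high bound."""
    reference, comparator = Strategy(reference), Strategy(comparator)
    wtp = ps.settings.wtp if wtp is None else wtp
    pr = ps.ranges.get(param_id)
    if pr is None:
        raise KeyError(f"parameter {param_id!r} has no range")
    nmb_low = _nmb(with_param(ps, param_id, pr.low), reference, comparator, wtp)
    nmb_high = _nmb(with_param(ps, param_id, pr.high), reference, comparator, wtp)
    return TornadoEntry(param_id, pr.low, pr.high, nmb_low, nmb_high)


def tornado(
    ps: ParameterSet,
    reference: Strategy | str = Strategy.TRIPLE,
    comparator: Strategy | str = Strategy.SGLT2I,
    wtp: float | None = None,
    param_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Full one-way sweep, sorted descending by NMB swing.

    Parameters without a usable range are skipped with a warning.
    """
    reference, comparator = Strategy(reference), Strategy(comparator)
    wtp = ps.settings.wtp if wtp is None else wtp
    ids = param_ids if param_ids is not None else sorted(ps.ranges)
    entries = []
    for pid in ids:
        pr = ps.ranges.get(pid)
        if pr is None or pr.degenerate:
            logger.warning("skipping %s: no usable range", pid)
            continue
        entries.append(owsa(ps, pid, reference, comparator, wtp))
    base_nmb = _nmb(ps, reference, comparator, wtp)
    df = pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "nmb_low": [e.nmb_low for e in entries],
            "nmb_high": [e.nmb_high for e in entries],
            "swing": [e.swing for e in entries],
        }
    )
    df["nmb_base"] = base_nmb
    return df.sort_values("swing", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PSAResult:
    """Per-iteration incremental results of the Monte Carlo analysis."""

    seed: int
    n_iterations: int
    wtp: float
    comparisons: list[tuple[Strategy, Strategy]]
    draws: dict[tuple[Strategy, Strategy], pd.DataFrame]
    n_redraws: int = 0
    arm_draws: pd.DataFrame | None = None

    def dominant_fraction(self, comparison: tuple[Strategy, Strategy]) -> float:
        df = self.draws[comparison]
        return float(((df.incr_cost < 0) & (df.incr_qalys > 0)).mean())

    def ce_fraction(self, comparison: tuple[Strategy, Strategy]) -> float:
        return float((self.draws[comparison].nmb > 0).mean())


def run_psa(
    ps: ParameterSet,
    n: int | None = None,
    seed: int | None = None,
    wtp: float | None = None,
    reference: Strategy | str = Strategy.TRIPLE,
    comparators: tuple[Strategy | str, ...] = (Strategy.SGLT2I, Strategy.FINERENONE),
    horizon_years: float | None = None,
) -> PSAResult:
    """Monte Carlo sensitivity analysis with independent parameter draws.

    Every ranged parameter is sampled from its fitted distribution,
    strategy models are rebuilt, the cohort model is run for every arm,
    and the incremental results are recorded.  A draw that produces an
    infeasible transition matrix is rejected and redrawn (counted in
    ``n_redraws``).  Identical seeds give identical results.
    """
    reference = Strategy(reference)
    comparators = tuple(Strategy(c) for c in comparators)
    n = ps.settings.psa_iterations if n is None else n
    if n < 1:
        raise ValueError("n must be >= 1")
    seed = ps.settings.seed if seed is None else seed
    if seed is None:
        seed = 0
    wtp = ps.settings.wtp if wtp is None else wtp
    rng = np.random.default_rng(seed)

    specs = {pid: fit_distribution(pr) for pid, pr in sorted(ps.ranges.items())}
    strategies = [reference, *comparators]
    comps = [(reference, c) for c in comparators]
    records: dict[tuple[Strategy, Strategy], list[tuple[float, float, float]]] = {
        c: [] for c in comps
    }
    arm_records = []
    n_redraws = 0

    for _ in range(n):
        while True:
            sampled = ps.copy()
            for pid, spec in specs.items():
                set_param(sampled, pid, float(spec.sample(rng)))
            try:
                arms = {
                    s: evaluate_arm(sampled, s, horizon_years=horizon_years)
                    for s in strategies
                }
            except (InfeasibleAdjustmentError, ValueError):
                n_redraws += 1
                continue
            break
        arm_records.append(
            {
                f"{s.value}_{kind}": getattr(arms[s], f"total_{kind}")
                for s in strategies
                for kind in ("cost", "qalys")
            }
        )
        for ref, comp in comps:
            inc = incremental(arms[ref], arms[comp], wtp)
            records[(ref, comp)].append((inc.incr_cost, inc.incr_qalys, inc.nmb))

    if n_redraws:
        logger.info("PSA rejected and redrew %d infeasible samples", n_redraws)
    draws = {
        c: pd.DataFrame(v, columns=["incr_cost", "incr_qalys", "nmb"])
        for c, v in records.items()
    }
    return PSAResult(
        seed=seed,
        n_iterations=n,
        wtp=wtp,
        comparisons=comps,
        draws=draws,
        n_redraws=n_redraws,
        arm_draws=pd.DataFrame(arm_records),
    )


def ceac(
    psa: PSAResult, wtp_grid: np.ndarray | list[float]
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve(s).

    For each WTP value, the fraction of draws with positive NMB
    (``incr_qalys * wtp - incr_cost > 0``) for every comparison.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    out = {"wtp": wtp_grid}
    for (ref, comp), df in psa.draws.items():
        dq = df.incr_qalys.to_numpy()
        dc = df.incr_cost.to_numpy()
        out[f"{ref.value}_vs_{comp.value}"] = [
            float((dq * w - dc > 0).mean()) for w in wtp_grid
        ]
    return pd.DataFrame(out)
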