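# Methods

## The model

`ckdcea` implements a Markov cohort decision model for patients with
chronic kidney disease (CKD) and type 2 diabetes, comparing triple
therapy (finerenone + SGLT2 inhibitor + standard of care) against
finerenone + SoC and SGLT2i + SoC from a healthcare-system
perspective.  The cohort is deterministic: we track the *proportion*
of patients in each compartment, not individuals.

**States.** Eight alive health states — CKD stages 1/2, 3, 4, 5
without renal replacement therapy, and acute/post-acute phases of
dialysis and kidney transplantation — crossed with a cardiovascular
history layer (no prior CV event vs. post-CV), plus an absorbing Dead
state: 17 compartments.  The acute dialysis and acute transplant
states are tunnels occupied for exactly one cycle; their transition
rows place all mass on the post-acute successor, which lets the one-off
acute cost be charged simply as that state's single-cycle cost.

**Cycles and horizon.** Four-month cycles (3 per year), ten-year
horizon in the base case (30 cycles) and four years (12 cycles) in the
scenario analysis.

**Competing risks.** The printed standard-of-care transition matrix
covers only the alive states (its rows sum to 100%), so all-cause
death is modelled as a separate per-cycle competing risk applied
before the survivors transition.  Within a cycle the default order is:

1. death at the origin state's per-cycle probability;
2. renal-state transition of survivors, carrying their CV layer;
3. CV events: survivors with no CV history incur a first event at
   their *origin* state's per-cycle risk and land in the post-CV layer
   of their destination state; post-CV survivors incur subsequent
   events at a single per-cycle probability (8.5%), which are tallied
   but change no state.

The source analysis does not state its within-cycle ordering, so the
alternative (`transition_first`: transition, then death and first-CV
risk at the destination state) is available as a setting, and the
acceptance machinery sweeps both.  The two orderings move ten-year NMB
by well under 1%.

Adverse events (hyperkalemia hospitalization, acute kidney injury,
discontinuation) are pure cost/tally modifiers: expected counts accrue
as alive occupancy × per-cycle probability and never move occupancy.
Discontinuation is tally-only by default; an optional setting stops
add-on drug costs for the cumulative discontinued fraction.

## Treatment-effect adjustment

Strategy-specific dynamics are derived from the SoC inputs using
relative effects, applied on the **rate scale**:
`p' = 1 − (1 − p)^ratio`, equivalent to converting the probability to
a constant hazard with `r = −ln(1 − p)/t`, multiplying by the ratio,
and converting back with `P = 1 − exp(−r·t)`.  This keeps adjusted
probabilities inside [0, 1] for any positive ratio, which direct
multiplication does not.

* Progression among CKD stages 1/2 → 3 → 4 (and the direct 1/2 → 4
  jump) is scaled by the strategy's relative eGFR decline rate
  (triple 0.52, finerenone 0.68, SGLT2i 0.93).  Regression
  transitions are untouched; the stay-probability absorbs the freed
  mass so rows re-sum to 1.
* Entries into CKD 5, acute dialysis, and acute transplant from the
  CKD 3, CKD 4 and CKD 5 rows are scaled by the hazard ratio for the
  composite kidney outcome (triple 0.27, finerenone 0.78, SGLT2i
  0.52).  The CKD 3 row is included because it feeds dialysis and
  transplant directly in the printed matrix; the scope is a module
  constant.  The CKD 5 → CKD 4 regression (4.25%) is left unchanged.
* First-CV and death probabilities are scaled per state by the
  strategy's hazard ratios.  No hazard ratio is printed for subsequent
  CV events, so that risk is common to all strategies.

The two matrix scalings touch disjoint off-diagonal entries and
therefore commute (tested).  An adjustment that would drive a
stay-probability negative raises an infeasibility error; the
probabilistic analysis rejects and redraws such samples.

## Economics

Costs (2023 CNY) and QALYs accrue per cycle on end-of-cycle occupancy
and are discounted at 5%/year via `(1.05)^(−k/3)`; a half-cycle
correction (average of start- and end-of-cycle occupancy for state
costs and utilities) is available but off by default, as the source
analysis never mentions one.

The four CV event types (MI, ischemic stroke, hemorrhagic stroke, HF
hospitalization) form one composite event whose acute cost, per-cycle
post-acute cost, and acute/post-acute disutilities are incidence-
weighted means.  Acute economics are charged once per incident event
(first and subsequent); post-acute economics apply to the entire
post-CV population from the cycle *after* the event, with no decay.
Disutilities are additive per-year decrements, scaled by the 1/3-year
cycle like utilities; the aggregate cycle QALY is floored at zero.
Death incurs a one-off terminal-care cost.  Hyperkalemia and AKI carry
costs only: the printed utility table assigns them no disutility.

Drug costs: the SoC regimen cost applies to every alive state in every
arm; finerenone and/or SGLT2i costs apply in the pre-RRT states
(CKD 1/2 through CKD 5) and stop at dialysis/transplant by default,
configurable via `drug_continue_on_rrt` — the source is silent and the
flag is part of the documented sweep.

Cost-effectiveness: `NMB = ΔQALY × WTP − ΔCost` at WTP = 268,074
CNY/QALY (three times 2023 Chinese GDP per capita).  A strategy is
dominant when it is cheaper and more effective; the ICER is reported
only when |ΔQALY| > 1e−12 and flagged otherwise.

## Inputs the main text does not print

Two inputs appeared only in supplementary material that is not
redistributed with this package:

* **Baseline CKD-stage distribution** — default 0.15 / 0.60 / 0.25
  across CKD 1/2, CKD 3, CKD 4, nobody with prior CV events.
* **CV event-type mix** — default equal quarters.

Both defaults are deliberate, documented stand-ins, overridable via
config.  Absolute per-arm totals, NMB magnitudes and the tornado
ordering are sensitive to the baseline severity mix (a sicker cohort
spends more person-cycles in dialysis, raising costs and lowering
QALYs in every arm); dominance directions and NMB signs are not, and
reproduce under every documented flag setting.  Passing results on the
defaults therefore demonstrate the pipeline's internal correctness and
the qualitative conclusions, not agreement with any particular
cohort's absolute totals.

## Sensitivity analyses

**One-way (tornado).** Each of the ~70 ranged scalars is set to its
low and high bound with everything else at base; both arms are re-run
and the NMB swing `|NMB_high − NMB_low|` ranks the parameters.
Grouped rows (shared dialysis/transplant death risks) move together as
printed.  Parameters without a usable range (the 0.00% SGLT2i
hyperkalemia risk) are skipped with a warning.

**Distribution fitting.** Ranges are read as 95% intervals,
`sd = (high − low)/3.92`, and distributions are fitted by the method
of moments so the fitted mean equals the base case: beta
(α = m(m(1−m)/s² − 1), β = (1−m)(·)), gamma (shape m²/s², scale s²/m),
lognormal matched on the natural scale (σ² = ln(1 + s²/m²),
μ = ln m − σ²/2; a CI-on-log-scale alternative is provided).
Negative-valued disutilities are fitted on their magnitude and the
draw negated.  An infeasible beta (s² ≥ m(1−m)) falls back to a
uniform over the range with a warning; degenerate ranges collapse to
point masses.

**Probabilistic (PSA).** 1,000 Monte Carlo iterations by default;
every ranged parameter is drawn independently (no correlation
structure is published), all strategy models are rebuilt, the cohort
model is run per arm, and per-iteration incrementals are recorded.
Infeasible draws are rejected and redrawn (counted).  A single
`numpy.random.default_rng(seed)` drives all draws, so results are
bitwise reproducible for a given seed and iteration count.  The CEAC
reports, per WTP value, the fraction of draws with positive NMB.

## Synthetic inputs

`ckdcea.synthetic` generates random parameter sets with the same
structure as the reference inputs: a row-stochastic matrix respecting
the reference zero pattern (Dirichlet rows tilted toward the
diagonal, deterministic tunnel/absorbing rows), per-cycle risks well
below 1, positive costs, utilities in [0.5, 1], effect ratios in a
configurable interval (default [0.3, 1.2]), and ±20% ranges for the
sensitivity machinery.  It emulates the aggregate parameter structure
only — no patient-level heterogeneity, correlation between inputs, or
time-varying effects — so tests that pass on generated sets establish
structural correctness (conservation, identities, determinism), not
clinical realism.

## Numerical choices and limitations

* Conservation of cohort mass is enforced to 1e−9 per cycle; matrix
  rows to 1e−9 after percentage conversion; config round trips are
  exact to 1e−12.
* Probability/rate conversions use `log1p`/`expm1` for small-risk
  accuracy.
* Treatment effects are constant over the horizon (trial-average
  effects extrapolated); no time-varying efficacy, adherence decay, or
  treatment switching.
* No microsimulation mode, societal costs, price-index adjustment, or
  EVPI analysis.
* Problem sizes used by the shipped analyses: 30 (or 12) cycles × 17
  compartments per arm, ~70-parameter tornado, 1,000-iteration PSA —
  a full run of everything completes in seconds on one core.
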