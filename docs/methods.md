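# Methods

## Model structure

The engine (`markov_engine`) propagates a cohort over a monthly-cycle
Markov chain on 16 expanded states: depressive episode on treatment, six
remission-on-treatment tunnel months, episode off treatment, six
remission-off-treatment tunnel months, well, and dead. The tunnel states
encode the requirement of six consecutive remission months before
recovery; they also carry the time-in-remission clock that the Weibull
relapse hazard needs, so the chain stays first-order Markov. The cohort
starts with unit mass in episode-on-treatment at age 45.

### Event composition within a cycle

Model inputs are *marginal* monthly probabilities, so the joint routing of
two events in one cycle is a modelling choice. Death is resolved first:
the annual life-table probability at the cohort's current integer age is
converted to monthly on the rate scale (`1 − (1−q)^{1/12}`) and, in the
two episode states, multiplied by the suicide-risk factor 20.35 on the
same rate scale (`1 − (1−q_m)^{20.35}`), which is exact for proportional
hazards and never leaves [0, 1]. Surviving mass then splits with
independent marginals:

- from an episode on treatment: remit-and-not-discontinue → first
  remission tunnel month; discontinue-and-not-remit → episode off
  treatment; *both* → first **off-treatment** remission month (remit, then
  stop the drug); neither → stay. The both-events destination is pinned by
  the constant `EPISODE_BOTH_EVENTS_STATE` and a test; routing it to
  on-treatment remission instead is defensible, and changing the constant
  is the one-line experiment.
- from remission on treatment: relapse wins any tie with discontinuation
  (`REMISSION_BOTH_EVENTS_STATE`), because relapse returns the patient to
  the original treatment by assumption; discontinue-and-not-relapse moves
  to the off-treatment tunnel month of the same index; neither advances
  the tunnel (month 6 → well).
- off treatment: remission occurs at a config-level untreated rate,
  relapse follows the placebo curve, there is no discontinuation, and
  relapse/recurrence return to episode **on** treatment.

No half-cycle correction is applied; accruals are booked on end-of-cycle
occupancy. Discounting at 3.5%/year starts only after cycle 12
(`(1+r)^{−(c−12)/12}`), reflecting the convention that costs and outcomes
within the first year are not discounted.

### Accrual details

QALYs accrue as state utility/12 with the expected ADR disutility
subtracted *inside* the on-treatment states (sleep disorder only in the
episode state), clamped at zero utility. The one-time discontinuation
event books, per unit of newly discontinued mass: symptom probability ×
0.065 decrement × (7/30 month)/12 QALYs, and symptom probability × €52
management cost. The €52 is not duration-scaled — it is the price of
managing the syndrome, not a monthly rate — while the disutility is. The
discontinuation-symptom cost is carried in the adverse-event cost
component. Indirect (productivity) costs are accrued as their own stream
unconditionally; the perspective gates their inclusion when an arm is
summarised, so switching perspective never requires re-running the
cohort. Hepatic monitoring for agomelatine (€75/test at weeks 3, 6, 12,
24) maps to cycles 1, 2, 3 and 6, weighted by on-treatment occupancy, and
is not re-billed after relapse-and-resume. Dose escalation applies the
double-dose fraction to drug cost from model cycle 2 onward; since the
cohort starts treatment at cycle 1 and relapse resumes an ongoing
prescription, the model cycle is used as the cycle-on-treatment index.

## Key parameters and defaults

| parameter | default | units | basis |
|---|---|---|---|
| cycle length | 1 | month | model definition |
| horizon | 24 | cycles | 2-year evaluation |
| start age | 45 | years | cohort entry age |
| discount rate | 0.035 | /year, after cycle 12 | standard national practice |
| recurrence | 0.20 | /year (→ 0.0184/month) | published input; the period is not printed — annual is the conservative reading |
| suicide-risk multiplier | 20.35 | rate ratio in episode | published input |
| WTP thresholds | 40k/50k/60k | €/QALY | published thresholds |
| off-treatment remission | 0.20 | /month | assumption — never published; config knob |
| treatment relapse curve | Weibull k=1, λ=24.15 mo | S(6)=0.78 | calibration default (see below) |
| placebo relapse curve | Weibull k=1, λ=11.75 mo | S(6)=0.60 | calibration default (see below) |
| PSA sd rule | 0.10 × mean | — | published assumption |

The relapse-prevention survival curve behind the agomelatine/venlafaxine
arms was never published; the packaged default fixes 6-month relapse-free
survival at 0.78 with constant hazard (shape 1 — no decreasing-hazard
assumption is smuggled in). The placebo curve is set to S(6) = 0.60 so
that the published relative risks (0.513–0.633 vs placebo) place the SSRI
arms near the active curve (0.60^0.513 ≈ 0.77), keeping the arms mutually
coherent. Both are ordinary config entries (`placebo_relapse`,
per-treatment `relapse`) and can be replaced by a curve fitted with
`fit_weibull` from `(time, survival)` points.

The life table is a Gompertz stand-in (`gompertz_life_table`, hazard
a·e^{bx}, defaults a = 2e−5, b = 0.1): monotone in age, two parameters,
and adult annual mortality of realistic order (≈0.002 at 45, ≈0.005 at
55). Any table can be supplied via YAML or `age,annual_death_prob` CSV.

## Synthetic data and what tests show

`synthetic_data` generates the three inputs the base case cannot carry
from print: life tables, exact Weibull survival points, and fully random
but structurally valid configurations (`random_scenario`), used heavily in
property tests (mass conservation, component-sum consistency, validation
closure). The generator emulates *structure*, not clinical reality: ADR
frequencies are drawn independently, arms are exchangeable, and no
correlation between effectiveness and price exists. Passing property
tests therefore demonstrates the engine's arithmetic and invariants, not
the external validity of any particular configuration.

A first-order microsimulation oracle (tests only) samples 200,000
individual trajectories from the same one-cycle transition rules and
checks the cohort expectation within Monte Carlo error (1% relative on
discounted totals).

## Sensitivity and probabilistic analysis

One-way DSA re-runs a pairwise comparison at configured extremes (default
±20%, clamped to type bounds — the published analysis never lists its
ranges) and ranks parameters by |NMB span| at a reference threshold of
€50,000/QALY. The break-even search bisects a comparator's monthly
remission probability for the smallest value at which the reference arm
is dominated (ΔQ ≤ 0 and ΔC ≥ 0) — the dominance boundary, not an ICER
threshold — returning 1.0 as a sentinel when no crossing exists.

The PSA assigns beta (probabilities, utilities) and lognormal (costs,
relative risks) distributions by method of moments; Weibull shape/scale
are classed with the positive-scale lognormal group. Parameters whose
point estimate sits on a degenerate boundary (probability 0 or 1, zero
cost) are held fixed. Draws are independent across parameters (no
published correlation structure) and shared across arms within an
iteration, so common inputs move together. Draws that fail validation are
redrawn wholesale (truncation would bias moments) with the redraw count
logged and a warning above a 1% rate.

## Numerical choices

- Row stochasticity is asserted at 1e−9 on every matrix build.
- The relative-risk transform `1 − (1−p)^{rr}` is used everywhere a risk
  multiplier meets a probability; it differs from naive `p·rr` by O(p²)
  and cannot leave [0, 1].
- Weibull fitting is ordinary least squares on the linearised form
  `ln(−ln S) = k·ln t − k·ln λ`; points with t = 0 or S ∉ (0, 1) are
  excluded; two usable points are interpolated exactly.
- Bisection tolerance for break-even defaults to 1e−4 on the probability
  scale with the bracket re-verified at both ends.
- Human-readable tables round to whole euros and 3-decimal QALYs; JSON
  keeps full precision.

## Problem sizes

The shipped suite runs the full 9-arm base case, 100-scenario property
sweeps, a 200k-trajectory microsimulation check, a 400-iteration PSA
consistency check on a two-arm configuration, and 10⁶-draw moment checks
(≈10 s total). A full PSA at the published scale (1,000 iterations × 9
arms) takes ≈25 s via `mddcea psa`.

## Known limitations

- The altered discontinuation-symptom risk on reaching the well state is
  mentioned qualitatively in the source literature but never quantified;
  only the one-time event at discontinuation is modelled.
- Off-treatment remission and relapse behaviour are assumptions exposed
  as config knobs; absolute cost/QALY totals are sensitive to them, and
  the packaged defaults reproduce the published *ordering* of arms (the
  reference arm accrues the most QALYs; all ICERs fall below the stated
  thresholds) but not strict dominance over the SSRI comparators.
- No efficiency frontier across more than two arms, no EVPI/EVPPI, no
  age-dependent utilities, and no correlation structure in the PSA.
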