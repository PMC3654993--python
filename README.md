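# mddcea

A Markov cohort cost-utility model for antidepressant pharmacotherapy in
major depressive disorder (MDD), built for health-economics analysts who
want a tested, scriptable implementation of a classic six-state
episode/remission/recovery model: base-case incremental analysis,
deterministic sensitivity analysis (tornado), and second-order Monte Carlo
probabilistic sensitivity analysis (PSA) with cost-effectiveness
acceptability curves (CEACs).

## The model

A cohort enters a depressive episode on treatment at age 45 and moves
monthly between six clinical states — depressive episode and remission
(each on or off the original treatment), well (recovered) and dead. A
patient must spend six consecutive months in remission before recovery, so
each remission state is expanded into six one-month tunnel states (16
expanded states in total). Per cycle:

- remission occurs with a treatment-specific monthly probability;
  off-treatment patients remit at a slower, treatment-independent rate;
- relapse from remission follows a Weibull relapse-free survival curve
  `S(t) = exp(−(t/λ)^k)` via the conditional probability
  `p(t) = 1 − S(t+1)/S(t)`; comparators without their own curve apply a
  relative risk to the placebo curve on the rate scale,
  `p′ = 1 − (1 − p)^RR`. Relapse always returns the patient to the
  original treatment;
- recurrence from the well state uses a 20%/year probability converted to
  monthly; background mortality comes from an age-indexed life table, with
  the rate multiplied by 20.35 during a depressive episode (suicide risk);
- adverse drug reactions contribute expected disutility and management
  cost (`Σ freq × decrement`, `Σ freq × cost`); the sleep-disorder term is
  attributed to the episode itself and suppressed in remission;
- discontinuation triggers a one-week, one-time symptom disutility and
  management cost; drug cost rises from cycle 2 by the double-dose
  fraction; agomelatine additionally incurs four €75 hepatic tests.

Health outcome is the quality-adjusted life year (QALY, state utility/12
per cycle); costs split into drug, direct medical, indirect
(productivity), adverse-event and monitoring components, with the indirect
stream included only under the societal perspective. Everything after the
first year is discounted at 3.5%/year. Pairwise comparisons report
ΔC, ΔQ, the ICER ΔC/ΔQ or a dominance label, and net monetary benefit
NMB(λ) = λ·ΔQ − ΔC.

The PSA assigns beta distributions to probabilities and utilities and
lognormal distributions to costs, relative risks and survival parameters,
moment-matched to mean ± 10% of the mean, draws one joint parameter set
per iteration, and summarises dominance fractions, percentile bootstrap
intervals and CEACs.

## Worked example

```python
from mddcea import (incremental_analysis, paper_base_case, run_cohort,
                    summarize_arm)

config = paper_base_case()          # 5 branded + 4 generic arms
arms = [summarize_arm(run_cohort(t, config), t, config)
        for t in config.treatments]
ago = arms[0]
print(f"{ago.treatment}: cost {ago.total_cost:.0f} EUR, "
      f"{ago.total_qalys:.3f} QALYs")
ven = next(a for a in arms if a.treatment == "Venlafaxine")
res = incremental_analysis(ago, ven, config.econ.wtp_thresholds)
print(f"vs {ven.treatment}: dC {res.incremental_cost:+.0f} EUR, "
      f"dQ {res.incremental_qalys:+.4f}, ICER {res.icer_display()}")
```

prints

```
Agomelatine: cost 5034 EUR, 1.522 QALYs
vs Venlafaxine: dC +311 EUR, dQ +0.0167, ICER 18560/QALY
```

i.e. under the packaged inputs agomelatine accrues 0.017 more QALYs than
venlafaxine over two years at €311 extra cost — €18,560 per QALY gained,
well below the €40,000–60,000/QALY willingness-to-pay thresholds. (The
unpublished inputs — life table, relapse curves, off-treatment remission —
use documented package defaults, so absolute totals differ from any
specific published adaptation; see `docs/methods.md`.)

The same analyses are available from the shell:

```bash
mddcea base-case --out out/base
mddcea psa --out out/psa --n 1000 --seed 1
mddcea dsa --out out/dsa --comparator Venlafaxine
mddcea breakeven --out out/be --comparator Venlafaxine
```

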