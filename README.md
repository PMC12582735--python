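# cohortcea

A Markov cohort cost-effectiveness model for adjunctive antiseizure
medications in pharmacoresistant focal-onset seizures, built for health
economists and formulary decision analysts. It compares brivaracetam
(BRV) against eslicarbazepine (ESL), lacosamide (LCM), and perampanel
(PER) from a payer perspective in Jordanian dinar (JOD), and is fully
reconfigurable to other drugs, prices, and settings.

## The model

A cohort moves through four states — seizure free (complete response,
CR), partial response (≥50% seizure reduction), non-response,
discontinuation — in 3-month cycles over a 2-year horizon (8 cycles),
with constant per-cycle transition probabilities per treatment. Costs
accrue from drug doses (per-mg prices, titration then maintenance),
per-state healthcare service bundles, and adverse-event management;
year-2 flows are discounted at 3.5%. The headline statistic is the
pairwise incremental cost-effectiveness ratio

    ICER = (C_BRV − C_comp) / (E_BRV − E_comp)

with the effect E as the CR proportion (read as "JOD per 1% CR"), plus
dominance classification, net monetary benefit `NMB = λ·E − C` at a
willingness-to-pay λ of JOD 9000, and a second-order probabilistic
sensitivity analysis (2000 iterations; beta distributions for
probabilities, gamma for costs, moment-matched from mean and SE) with
ICER-plane quadrant shares and cost-effectiveness acceptability curves.
See `docs/methods.md` for assumptions and limitations.

## Worked example

```python
from cohortcea import default_config, run_deterministic, icer

config = default_config()          # published Jordanian inputs
results = run_deterministic(config)
inc = icer(results["BRV"], results["LCM"])
print(f"BRV: {100*results['BRV'].effect:.2f}% CR at JOD {results['BRV'].cost:.2f}")
print(f"vs LCM: dCost {inc.delta_cost:+.2f}, dCR {100*inc.delta_effect:+.2f} pts, "
      f"ICER {inc.icer:.0f} ({inc.dominance.value})")
```

prints

```
BRV: 21.83% CR at JOD 1898.11
vs LCM: dCost -73.65, dCR +10.85 pts, ICER -679 (saving_se)
```

i.e. under the default absorbing structure and the shipped label-range
dose assumptions, 21.83% of the BRV cohort is ever seizure-free over two
years at an expected discounted cost of JOD 1898.11, and BRV is
cost-saving against LCM (more effective, less costly). Absolute levels
depend on the dose assumptions — the published median doses are not in
the main text — which is why incremental worked examples in the tests use
the published cost/effect pairs directly.

Command line:

```
cohortcea --mode ceac --seed 1 --out-dir results --plots
```

writes deterministic results, PSA iterations, quadrant shares, and CEAC
tables as CSV (plus optional plots).

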