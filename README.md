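# effectpath

**Is the adjusted coefficient a total effect, a controlled direct effect,
or biased?**

When regression models compare immigrants and non-immigrants (or any
groups observed through a selection-sampled dataset), it is routine to
adjust for outcome risk factors — smoking, BMI, SES, maternal age — that
differ between the groups. But such a risk factor can be a **mediator** on
the causal path from country of birth `E` to the health outcome `D`, a
**selection factor** that determines membership in the analyzed dataset
(`S = 1`), or **both at once**. Depending on that role, adjusting for it
either removes a genuine part of the effect, removes a collider bias, or
does both — and the estimand silently changes between the *total effect*
and the *controlled direct effect (CDE)*, or becomes biased outright.

`effectpath` is a toolkit for epidemiologists and biostatisticians that
makes this decision explicit and testable:

- a **graphical classifier**: given a causal DAG with node roles and an
  adjustment set, it enumerates exposure-outcome paths, applies the
  d-separation open/closed rules with the dataset restriction `S = 1`
  conditioned in, and returns `TOTAL`, `CONTROLLED_DIRECT`, or `BIASED`
  with the open biasing paths / blocked causal paths as evidence;
- a **structural causal model simulator**: linear-Gaussian risk factors
  and outcomes with Bernoulli exposure and logistic selection, ground
  truth via do-interventions (total effect
  `E[D|do(E=1)] − E[D|do(E=0)]`; CDE with the mediator fixed at `m`),
  and replicate-level bias reports for unadjusted, adjusted, and
  inverse-probability-of-selection-weighted (IPW, weights `1/p`)
  regression estimators;
- **pre-built experiments** verifying that the two routes agree cell by
  cell across the canonical model structures, plus a worked preeclampsia
  adjustment example, an attenuation sweep, and an exposure-mediator
  interaction demonstration.

See `docs/methods.md` for the model, defaults, and design choices.

## Worked example

The canonical structure where the risk factor is both a mediator and a
selection factor: `E -> D`, `E -> R0 -> R -> D`, with selection
`E -> S <- R0` and the analysis restricted to `S = 1` (`R0` is the
unmeasured pre-migration risk factor, `R` its measured post-migration
value).

```sh
$ effectpath classify --template fig1b --adjust R
effect type: CONTROLLED_DIRECT
conditioning set: {R, S}
blocked causal paths:
  E -> R0 -> R -> D

$ effectpath classify --template fig1b
effect type: BIASED
conditioning set: {S}
open non-causal (biasing) paths:
  E -> S <- R0 -> R -> D
```

Adjusting for `R` closes the collider path *and* the indirect effect, so
the estimand is the controlled direct effect — not the total effect, and
not unbiased-by-default if you skip the adjustment. The simulator shows
the same thing quantitatively:

```python
>>> from effectpath import (make_model, analytic_effects, simulate_cohort,
...                         fit_adjusted_difference)
>>> model = make_model("fig1b")          # defaults: direct 0.3, mediated 0.2
>>> truths = analytic_effects(model)
>>> truths.total_effect, truths.cde
(0.5, 0.3)
>>> cohort = simulate_cohort(model, 200_000, seed=20230210)
>>> len(cohort.selected)                 # the observed "immigrant dataset"
109667
>>> fit_adjusted_difference(cohort).value            # unadjusted: neither truth
0.26637430071978985
>>> fit_adjusted_difference(cohort, {"R"}).value     # adjusted: the CDE
0.2977462710265103
```

The unadjusted estimate (0.266) is collider-biased away from both the
total effect (0.5) and the CDE (0.3); the R-adjusted estimate recovers
the CDE. To recover the *total* effect under this structure, weight the
selected rows by inverse selection probabilities modelled on `(E, R0)`
from the full population (`estimate_selection_weights` +
`fit_adjusted_difference(..., weights=...)`).

The full concordance experiment — every model template crossed with every
applicable strategy, graphical verdict vs simulation verdict —
is one command:

```sh
effectpath grid --out results/grid        # writes grid.csv + run_log.json
effectpath example-preeclampsia           # the worked DAG example
effectpath attenuation                    # residual-confounding sweep
effectpath interaction                    # CDE with/without the product term
```

Every command accepts `--config FILE` (YAML), `--seed`, `--n`, `--reps`,
`--out`; the run log echoes the effective configuration so any run can be
reproduced exactly.

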