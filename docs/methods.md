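# Methods

## The problem

Health comparisons between immigrants and non-immigrants (and, more
generally, between groups observed through a selection-sampled dataset)
routinely adjust regression models for observed differences in outcome risk
factors such as smoking, BMI, SES, or maternal age. Whether the resulting
exposure coefficient is a **total effect**, a **controlled direct effect
(CDE)**, or simply **biased** depends on the causal role of the adjusted
risk factor:

- a **mediator** transmits part of the exposure effect
  (`E -> R0 -> R -> D`): adjusting removes the indirect pathway and leaves
  a controlled direct effect;
- a **selection factor** affects membership in the analyzed dataset
  (`R0 -> S`, with the data restricted to `S = 1`): the restriction
  conditions on a collider and manufactures a spurious exposure-risk-factor
  association, which adjustment removes;
- a **combined mediator/selection factor** does both, so adjustment is
  simultaneously necessary (to close the collider path) and
  effect-removing (the estimand becomes the CDE).

`effectpath` makes this decision executable in two independent ways and
checks that they agree: a graphical classifier over a causal DAG, and a
parametric structural causal model whose simulated estimator behaviour is
compared with interventional ground truth.

## Graphical classifier

A DAG over labelled nodes carries role annotations: exposure `E`, outcome
`D`, optional binary selection indicator `S` (always conditioned — the
analyzed data are the `S = 1` rows), unmeasured pre-migration risk factors
(`R0`-type), their measured post-migration counterparts (`R`-type),
mediator-outcome confounders (`C`-type), and the set of measured
(adjustable) nodes.

For a user-supplied adjustment set `Z` (measured nodes only; `E`, `D`, `S`
rejected), the classifier enumerates every simple path between `E` and `D`
in deterministic lexicographic order and applies the standard open/closed
rules with conditioning set `Z ∪ {S}`: a chain or fork node blocks a path
when conditioned; a collider blocks it unless it or one of its descendants
is conditioned. A path is *causal* when every edge points from `E` toward
`D` in the full DAG (causality is a property of the graph, not of the
conditioning). The verdict is:

- `BIASED` iff some non-causal path is open;
- else `CONTROLLED_DIRECT` iff some causal path is blocked — including a
  directed path through `S` blocked by the `S = 1` restriction itself;
- else `TOTAL`.

`d_separated` (used for the exhaustive equivalence checks) delegates to
networkx's d-separation routine, which is an algorithmically independent
route from the path enumeration above; the test suite verifies exact
agreement over thousands of random DAGs, every node pair, and every
conditioning subset.

Two deliberate strictness choices. First, the "adjusting for R largely
also adjusts for R0" near-blocking argument is *not* modelled graphically:
the classifier treats a path through unmeasured `R0` as open unless a node
on it is literally conditioned. The quantitative side of that argument
lives in the attenuation experiment below. Second, the time-constant case
(a risk factor such as sex, or one measured at the point of immigration)
is represented by contracting `R0` and `R` into a single measured node:
that is what "R0 = R" means graphically, and it is what makes adjustment
for `R` close the confounding path through `C` in that case.

## Structural causal models

Each node has a structural assignment: the exposure is Bernoulli
(`p_E = 0.5`, two origin countries equally represented in the full
population); the selection indicator is Bernoulli with a logistic link on
its parents; every other node is linear in its parents with Gaussian
noise, optionally with an exposure-by-mediator product term on the
outcome. Default coefficients (unitless, on standardized continuous
scales):

| parameter | value | meaning |
|---|---|---|
| `E -> D` | 0.3 | direct exposure effect |
| `E -> R0` | 0.5 | pre-migration national difference in the risk factor |
| `R0 -> R` | 1.0 | measurement tracks the pre-migration value |
| `R -> D` | 0.4 | risk factor effect on the outcome |
| selection intercept | 2.0 | most of the receiving country is selected |
| `E -> S` | -2.5 | migrants are a small subsample of their origin country |
| `R0 -> S` | -1.5 | selection on the risk factor |
| `C -> R0`, `C -> D` | 0.5 | mediator-outcome confounding |
| `S -> R` | 0.5 | post-migration change variant |
| noise SD | 1.0 | structural noise on continuous nodes |

These give roughly 59% of the population selected (about 75% of
non-migrants, 43% of migrants), a selected-sample collider correlation of
about -0.22 between `E` and `R0` under the selection-only model, and
effect sizes (total 0.5 vs CDE 0.3 under the combined model) that are
separated decisively at the default replicate budget.

Effects are reported on the mean-difference scale because it is
collapsible; odds-ratio non-collapsibility would confound the qualitative
verdicts with a scale artifact. A logistic-outcome estimator
(`fit_adjusted_odds_ratio`) exists and flags its scale, but all verdicts
and acceptance checks are on the linear scale.

### Ground truth

`apply_do` performs graph surgery (sever incoming edges, fix constants).
The total effect is `E[D | do(E=1)] - E[D | do(E=0)]`; the CDE fixes every
measured mediator at a reference value `m` (default 0) in both arms, so
with an interaction coefficient `γ` the CDE is `β_direct + γ·m`.

`analytic_effects` propagates interventional means through the linear
system — equivalent to summing coefficient products over directed paths,
and exact for the product term because the exposure is constant under
`do(E)`. It is refused whenever `S` is an ancestor of `D` (the
post-migration `S -> R` arrow): the logistic link breaks linearity there,
and `mc_effects` must be used. Because selection then mediates a real part
of the exposure effect, the target population of "the" total effect is
genuinely ambiguous; both the headline total (through all paths, 0.224 at
defaults) and the total excluding `S`-paths (0.3) are reported rather than
choosing.

`mc_effects` simulates both do-arms with *common random numbers* — every
node draws from its own seed-derived stream, so arms differ only through
the intervention. Paired contrasts are exact for fully linear systems and
have MC standard errors around 1e-4 at n = 10^6 for `S`-mediated ones.

### Seeding

One master integer seeds everything. Sub-streams are derived as
`sha256(master | labels...)` truncated below 2^31: replicate `r` of model
`M` under strategy `s` uses `derive_seed(master, M, s, r)`, and node `X`
of a cohort simulated with seed `q` uses `derive_seed(q, "node", X)`.
Identical configurations are bit-identical; do-variants of a model share
exogenous noise.

## Estimators and the verdict rule

`fit_adjusted_difference` is OLS of `D` on `E` plus the adjustment set,
fitted on the selected view (classical SEs). When the generating model has
an interaction and the mediator is adjusted, the product term is included
and the estimate read at `m` (delta-method SE); the deliberately
misspecified fit omits it. IPW weights come from a logistic fit of `S` on
chosen predictors over the *full* population (the procedure requires the
origin-population risk-factor distribution), evaluated on selected rows as
`1/p` with a positivity floor of 1e-6; weighted fits use
heteroscedasticity-robust (HC1) SEs.

`replicate_bias` runs `R` simulate-then-estimate replicates (default
20 × 200,000) and applies a fixed decision rule at tolerance `t = 3`:
the strategy *recovers* a truth when the replicate mean is within
`t` Monte-Carlo SEs of it and the competing truth is excluded at the same
criterion; *biased* when both are excluded; ties with coincident truths
(no mediated effect) resolve to `recovers_total`. The rule is applied
mechanically — verdicts are never set by hand.

## Experiments

**Effect grid.** Six models (A combined mediator/selection = `fig1b`;
A_with_C adds the confounder = `fig1c`; B selection-only, time-constant
measurement = `fig1d_timeconstant`; C mediator-only = `modelC`; D neither
= `modelD`; post-migration variant = `fig1d_postmigration`) crossed with
strategies none / adjust R / adjust R+C (where C exists) / IPW — 18 cells.
For IPW cells the classifier is evaluated with `S` unconditioned (the
weights undo the sampling restriction). IPW is masked where the selection
node has no risk-factor parent (nothing to reweight) or has children
(weighting who is sampled cannot undo a causal effect of being sampled on
the mediator, so no estimand in the correspondence is targeted). Each cell
checks classifier verdict == simulation verdict under the fixed
correspondence TOTAL ↔ recovers_total, CONTROLLED_DIRECT ↔ recovers_cde,
BIASED ↔ biased.

**Attenuation.** Under the selection-only model with confounder C
(`fig1d`), the R-adjusted, C-omitted estimator is run over the
R-measurement noise grid {0, 0.1, 0.25, 0.5, 1.0} with replicate seeds
shared across levels (common random numbers), so the bias curve is smooth
and paired. |bias| at noise 0 is statistically zero (the time-constant
limit) and grows to ≈ 0.048 at noise SD 1. The monotonicity flag clamps
levels whose |bias| is within 3 SE of zero to zero before the
non-decreasing comparison: below the Monte Carlo resolution of the sweep
the sign and magnitude of a bias estimate are sampling noise, and folding
that noise through the absolute value would spuriously fail an honest
curve. Distinguishable levels are compared strictly.

**Interaction.** With `γ = 0.2` on `E × R`, the product-term fit recovers
the CDE at `m = 0` (0.3); the fit omitting the term lands near 0.248 and
is excluded at 3 MC SEs.

**Preeclampsia example.** A reconstruction of a published refugee-vs-
non-immigrant preeclampsia analysis as a DAG: three unmeasured
pre-migration factor groups (combined "other", SES, maternal age), their
measured post-migration versions, all acting as combined
mediator/selection factors. Adjusting everything except SES leaves the
biasing path `E -> S <- R02 -> R2 -> D` open (verdict BIASED); adding SES
closes it (CONTROLLED_DIRECT). Adding the plausible `S -> SES` and
`SES -> maternal age` arrows changes neither verdict, because every
measured factor is an adjusted mediator. Only the qualitative verdicts are
reproduced; the published registry odds ratios come from external national
data and are out of scope.

## What the simulator does and does not emulate

The generator produces linear-Gaussian risk factors and outcomes with a
logistic selection model — enough to realize every qualitative structure
the classifier reasons about, with known ground truth. It does not emulate
nonlinear or non-Gaussian mediators, time-varying confounding, survival
outcomes, measurement error beyond Gaussian noise on `R`, or real-world
selection mechanisms richer than a logistic link. Passing tests therefore
show that the graphical verdicts and the estimators behave as the theory
predicts *under the stated structures*, not that any particular applied
dataset satisfies those structures.

## Numerical choices and limitations

- Problem sizes: 20 replicates × 200,000 individuals per grid cell,
  n = 10^6 for Monte Carlo truths, n = 10^5 for the correlation and
  parameter-recovery checks — chosen so the 0.3 vs 0.5 estimands are
  separated by an order of magnitude more than the MC error while a full
  grid run stays under a minute on one core.
- The 3-SE verdict rule with 20 replicates is a coarse t-test; a cell
  whose estimator has a heavy-tailed replicate distribution (the IPW cell:
  weights reach ~e^4) will occasionally produce a ≥3-SE excursion under a
  valid null, so a rare seed can flip a single grid cell.
- Degenerate inputs are rejected loudly: cycles and duplicate edges at DAG
  construction, coefficients on absent edges at model construction,
  zero-variance design columns, perfect separation, empty selected views,
  fitted selection probabilities at the positivity floor, and
  selected-view statistics after a do-intervention on `S` (a
  contradiction).
- Path enumeration is exponential in the worst case and intended for the
  small DAGs of this domain (≤ a dozen nodes); d-separation via networkx
  remains polynomial.
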