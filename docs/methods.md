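# Methods

This note documents the models, algorithms and design choices behind
`riskeq`: how risk-equalization (RE) models are calibrated, how the two
diagnosis-based cost group (DCG) designs are built and evaluated, what
the synthetic population generator emulates, and the numerical
conventions the tests rely on.

## The payment model

An RE model predicts a person's annual health spending from categorical
risk classes and pays insurers the prediction.  We calibrate it as a
weighted least-squares regression at the individual level:

- **Outcome** `y_i`: spending in euros per person-year.  Raw spending of
  a person enrolled for a fraction `f` of the year is annualized to
  `raw / f`; the fraction becomes the observation weight, so
  `weight × annualized = raw` and euro totals are conserved.  Every
  aggregate in the package (prevalences, group means, marginals) is
  insured-year weighted.
- **Design**: no global intercept.  The exhaustive age×gender block (12
  cells: two genders × six bands from 1–17 to 65+) plays the intercept's
  role — its columns sum to one in every row, which yields the exact
  orthogonality identities used throughout the tests.  Every other
  classification is exclusive and omits its `none` reference class.
  DCG columns are appended as 0/1 dummies (two-layer scheme) or
  non-negative counts (multi-qualification scheme).  Persons aged 0 are
  rejected at validation because their spending year cannot be linked
  to prior-year morbidity.
- **Solver**: normal equations with a Cholesky factorization, followed
  by three rounds of iterative refinement against the original
  least-squares residual.  Refinement drives the weighted orthogonality
  defect `max_j |Σ_i w_i x_ij r_i|` to rounding level (relative defects
  around 1e-16 in practice; the enforced invariant is 1e-6 relative,
  chosen so the invariant tests are portable across BLAS builds).  Rank
  deficiency is detected with a pivoted QR of the normal matrix and
  raised as an error naming the dependent columns — silent dropping
  inside the solver would corrupt the alignment between scheme classes
  and payment weights.  The *pipeline*, by contrast, knowingly removes
  DCG columns that no sampled person occupies before fitting (a payment
  class with no members has no estimable weight); the removal is logged
  and the remaining labels keep the alignment.

Four model variants are calibrated on each population:

| model  | DCG adjuster                                   |
|--------|------------------------------------------------|
| M0     | none (all other classifications)               |
| M1     | traditional two-layer pDCG/sDCG dummies        |
| Mfull  | one dummy per dxgroup                          |
| M2     | interval-clustered multi-qualification counts  |

Only one dxgroup catalogue exists in the synthetic setting, so the
"baseline" M0 is the model without a DCG adjuster; the historical
distinction between a baseline and a revised-catalogue variant (which
differ only in which dxgroups exist) has no synthetic counterpart.
M2's columns are sums of Mfull's columns, so M0 ⊂ M1 and M0 ⊂ M2 ⊂
Mfull as column spaces; training R² is therefore monotone along both
chains, and the M2-versus-Mfull gap measures what the €500 clustering
gives up (a few 1e-4 on the default generator).

## Building DCG schemes

**Screening.**  Candidate diagnoses are retained when (inclusively) at
least one third of year-1 patients are diagnosed again in year 2, and
prevalence and mean related spending meet configurable floors.  The
report lists every failed criterion per candidate.

**Traditional two-layer scheme.**  Per dxgroup we compute mean residual
spending — the insured-year weighted mean, over its members, of the
residuals from the *partial* model that adjusts for age×gender and
pharmacy cost groups only.  Dxgroups are ranked by this statistic (the
severity order used at assignment time) and clustered by weighted 1-D
Ward agglomeration: repeatedly merge the pair `(a, b)` minimizing
`W_a·W_b/(W_a+W_b)·(m_a − m_b)²`, the merged cluster taking the
weighted mean.  Ties break on the smaller combined mean, then on
lexicographic member ids, making the merge trace fully deterministic;
the implementation searches all pairs (not only mean-adjacent ones,
which with unequal weights need not contain the optimum).  The same
means are clustered once into 15 primary and once into 7 secondary
clusters.  How the historical secondary layer was actually derived is
not documented; clustering the same statistic into 7 is our
approximation, and the layer counts are configuration.  A person's
pDCG comes from their highest-ranked dxgroup, the sDCG from the
second-highest; anything further is ignored.

**Interval multi-qualification scheme.**  The full-dummy model's
per-dxgroup coefficients are sorted ascending and swept left to right,
opening a new cluster whenever the current value exceeds the open
cluster's minimum by more than the configured range (default €500).
For a range constraint on sorted one-dimensional data this greedy sweep
provably minimizes the number of clusters among contiguous partitions;
the tests verify the count against a dynamic-programming oracle.  The
resulting cluster count is an outcome of the €500 rule, not a
parameter (17–21 clusters on default populations).  At assignment time
a person contributes one count per qualifying dxgroup to that
dxgroup's DCG — several counts in the same DCG are possible and no cap
applies.

## Rebalancing the GP-style subsample

Condition-level results are computed on a morbidity-enriched subsample
emulating GP-practice data.  Its weights are raked to the population's
risk-class margins by iterative proportional fitting: starting from the
insured fractions, each classification's class weights are scaled by
target-share over current-share, cycling through the classifications in
scheme order; convergence is the maximum relative marginal discrepancy
after a full cycle (default tolerance 1e-8, maximum 1,000 cycles, both
recorded in the report together with the iteration order).  Because
each dimension partitions the sample and targets sum to one, the total
weight is invariant.  A residual gap in mean spending survives raking;
the spending correction removes it multiplicatively (ratio of means),
which preserves non-negativity and scale-invariance — an additive-shift
variant is available as an option since either reading of a "linear
correction" is defensible.

## Evaluation metrics

`R²` and CPM are computed in weighted form with the weighted mean as
the reference predictor.  Subgroup under/overcompensation is the mean
financial result, **predicted minus actual**, so negative values flag
undercompensated (unattractive) groups.  Families of groups are
summarized by the WMAFR `Σ N_g·|MFR_g| / Σ N_g` with `N_g` the group's
insured-years, and by bracket shares with inclusive boundaries
(`|MFR| ≤ €500`), plus sub-brackets among undercompensated groups.
Multimorbidity strata partition persons by dxgroup (or chronic
condition) count into `0, 1, …, 7, 8+`.

Significance of a nonzero MFR uses a weighted one-sample z-test with
the Kish effective sample size `(Σw)²/Σw²`; two models are compared on
a group through the paired per-person prediction difference, whose
group mean equals the difference of the two MFRs (actual spending
cancels).  The normal approximation is pragmatic for heavily skewed
spending and is labelled as such in reports; no multiple-testing
correction is applied across groups.

## The synthetic population generator

The generator produces populations whose headline shape matches the
documented descriptive statistics of a national calibration dataset,
with known true payment weights so that calibration can be checked by
parameter recovery.  Defaults (all configurable, all driven by one
seed):

- **Demographics**: 12 age×gender cells with registry-like insured-year
  shares; 90% of persons enrolled the full year, the rest a uniform
  number of whole months.
- **Morbidity adjusters**: five exclusive blocks (pharmacy cost groups
  16.9%, multi-year high cost 6.1%, medical equipment 3.8%, home care
  2.4%, physiotherapy 1.9%), each split into severity classes with
  fixed true coefficients.
- **Dxgroups**: a catalogue of 209 groups with log-normal base rates
  clipped to [3e-4, 8e-3].  Membership is Bernoulli with probability
  `min(rate_j × frailty_i, 0.5)`, where the person-level frailty is
  log-normal (σ = 3, unit mean) capped at 80 — the cap bounds a
  person's expected dxgroup count at realistic multimorbidity levels
  (≈ 15–25) and keeps spending variances finite-sample friendly.  Base
  rates are rescaled so that the any-dxgroup share hits its 11.4%
  target; the rescaling solves the exact expectation over the frailty
  distribution on a fixed normal quadrature grid, so it is
  deterministic and seed-independent.  The same construction calibrates
  each morbidity block (coupled to frailty^0.5, hence correlated with,
  but less extreme than, dxgroup membership).  The shared frailty is
  the single knob producing correlated flags and the 2+-dxgroup mass
  the multi-qualification design exists for.
- **True coefficients**: age×gender levels rising from €300 to €3,050;
  block classes €700–€9,000; dxgroup coefficients gamma-distributed
  (shape 1.2, scale €620, clipped at €13,000), with the 12 rarest
  groups reassigned "severe" coefficients uniform on €6,000–€13,000 —
  expensive conditions are rare, and anchoring them on the rarest
  groups stabilizes the population mean across seeds.  Combined, the
  defaults put mean spending near €2,333 per person-year.
- **Spending noise**: two-part.  A zero-spending probability decaying
  exponentially in expected spending (25% at the healthy baseline,
  negligible for the morbid), then gamma-distributed positive spending
  with mean `μ/(1−π)` and shape 8, so `E[y|X] = μ` exactly and the
  variance grows with the mean.  `noise_scale ∈ [0,1]` interpolates
  linearly between the deterministic expectation (0, used by the
  noiseless recovery tests) and the full two-part draw (1).  Shape 8
  (conditional coefficient of variation ≈ 0.35) is deliberately
  moderate: it keeps spending right-skewed and heteroskedastic while
  letting stratum-level systematic effects of a few hundred euros
  dominate Monte-Carlo noise at the default population size of
  200,000.  Real claims data are substantially more dispersed
  (conditional cv well above 1); analyses that depend on absolute
  noise levels should lower the shape parameter and raise `n`.
- **Chronic conditions**: persons flagged by any morbidity adjuster or
  dxgroup are chronic with probability 0.9; unflagged persons with the
  probability that makes the overall chronic share 55% — so roughly
  55% of persons carry a GP-style chronic condition while only ~25%
  qualify for any morbidity adjuster, reproducing the structural gap
  between GP records and claims-based adjusters.  Chronic persons draw
  1 + Poisson(0.8) condition codes from a popularity-weighted
  catalogue of 109.
- **Subsample**: a 7.7% draw with persons carrying any morbidity flag
  over-sampled by factor 1.1, giving the slightly older, sicker,
  higher-spending profile typical of GP panels.
- **Claims history**: per candidate diagnosis, a year-1 patient set at
  the configured prevalence, a year-2 set formed by retaining each
  patient with the persistence probability and topping up with new
  patients (so persistence 1 reproduces the set exactly), and
  per-patient spending around the configured mean.

### The parameter-recovery benchmark

Root-n error scaling is demonstrated on a dedicated benchmark
configuration rather than the default multimorbid population:
frailty is switched off (independent flags), all 209 dxgroups share one
low base rate (about 10 expected carriers per group at n = 50,000,
via `dx_rate_log_sigma = 0`, `dx_rate_floor = 1e-4` and an any-dxgroup
share of 2.07%), and the zero-spending mass is disabled so the noise is
pure gamma.  Two things motivate this: recovering payment weights for
*rare* classes is exactly where estimation instability matters, and the
heavy upper tail of the default multimorbid population makes realized
squared-error averages converge slowly, so a 10-replication experiment
would measure tail realizations rather than scaling.  The 50,000-person
fit uses the leading quarter of each 200,000-person draw (common random
numbers), classes unobserved in a subsample are dropped from that fit,
and errors are pooled over ten replications before taking the RMSE
ratio.  Quadrupling the sample more than halves the pooled RMSE
because rare classes also shed the finite-sample information deficit
(`E[1/N] > 1/E[N]`) they suffer at the smaller size.

### What the generator does not emulate

True spending is exactly linear in the design with independent
two-part noise — there are no nonlinear interactions, no persistence of
individual spending across years, no regional or socioeconomic
structure, and prediction-year drift is absent (calibration-year fit
doubles as the evaluation).  Dxgroup membership given frailty is
independent across groups, so clinically structured comorbidity
patterns (disease hierarchies) are not represented.  Consequently,
passing tests show that the *methods* behave as designed — the
full-dummy model zeroes every dxgroup's financial result by
orthogonality, interval clustering concedes almost no fit, raking hits
its margins, multi-qualification repairs compensation for multimorbid
strata that a two-flag scheme structurally cannot — but absolute
levels (R² near 0.85, WMAFR magnitudes, cluster counts) are properties
of the synthetic regime, not forecasts for any real payment system,
where fit measures are far lower and group results noisier.

## Problem sizes and determinism

Default analyses run at n = 200,000 persons with 209 dxgroups; the
orthogonality anchor runs at n = 50,000 and the scaling benchmark pools
ten 200,000-person replications.  These sizes resolve every systematic
effect the package asserts while keeping a full test run in minutes on
one core.  All randomness flows from a single integer seed through
spawned generator streams (truth, persons, subsample, claims);
identical seeds yield byte-identical artifacts, and the experiment
report records the seed and stage timings as JSON-lines logs.
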