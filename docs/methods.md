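# Methods

## The model

`gebma` analyses case-control data with a Bayes-model-averaged logistic
regression over a structured space of candidate terms. Writing `X_c` for the
adjustment covariates carried by every model (age, family history of breast
cancer, menopausal status) and `X_v` for the selectable terms (a cumulative
smoking exposure in packyears, six genotype codings, exposure-by-gene
interactions and within-pathway gene-gene interactions), the disease model at
any point of the chain is

    logit P(Y = 1 | X) = sum_c beta_c X_c + sum_v Ieff_v beta_v X_v

with latent binary inclusion indicators. The effective indicator of a main
effect is its own Bernoulli indicator `I_v`; an interaction between parents
`r` and `s` is decomposed as `Ieff_rs = I_r * I_s * J_rs` with a free
indicator `J_rs`, so strong heredity (no interaction without both parents)
holds by construction. Each indicator's success probability `p_v` has a beta
prior: Beta(1, 3) for main effects (marginal prior inclusion 0.25, favouring
sparse models) and Beta(2, 2) for the free interaction indicator, giving a
conditional interaction inclusion probability of 0.5 given both parents and a
marginal of 0.25 x 0.25 x 0.5 = 0.03125. Each term has its own `p_v`; with
that choice the closed-form prior probability of the covariates-only null
model in the default 20-term universe is 0.75^7 ~= 0.1335, of any
one-main-effect model 0.25 x 0.75^6 ~= 0.0445, and the prior normalises to 1
over the heredity-legal model space (verified by exhaustive enumeration,
17,946 models).

Coefficients follow the spike-and-slab

    beta_v ~ N(0, (psi_t * sigma)^2)   (the coefficient keeps its prior when
                                        the term is excluded; only Ieff*beta
                                        enters the linear predictor)

where `sigma` is a shared scale with a half-Cauchy(scale = 100) prior —
placed on the scale `sigma` itself, following the standard weakly-informative
construction for hierarchical scale parameters; a configuration switch
(`half_cauchy_on = "sigma2"`) places it on `sigma^2` instead. The variance
inflation `psi_t` is 1 for main effects and, for interactions,
`log(psi_int) ~ N(2.3, 1)` (1 is the variance), a slightly informative prior
that keeps the update proper when no interaction is currently in the model.
Adjustment coefficients get a diffuse N(0, 10^2) prior.

## Sampling

`run_chain` is a Metropolis-within-Gibbs sweep:

1. **Indicators**, random-scan order, by Metropolised toggles. A toggle
   proposes a fresh coefficient for the term. Two proposal flavours exist:
   the *prior draw* (prior and proposal densities cancel; acceptance is the
   likelihood ratio times the Bernoulli prior odds) and, default when data
   are present, a *likelihood-informed* normal approximation built once per
   term from a lightly ridge-penalised adjusted GLM fit, with the
   prior/proposal density ratio kept in the acceptance probability. The
   informed proposal matters: under the vague half-Cauchy slab the scale
   `sigma` wanders to the order of its prior median (~100) whenever no term
   is included, and prior draws then essentially never propose coefficients
   in the likelihood's support, freezing the null model in place. The
   informed toggle behaves like an independence sampler whose acceptance
   approximates the true posterior odds, so regime switches are frequent.
   Both kernels target the same posterior; the choice is
   `ChainConfig.indicator_proposal`.
2. **Coefficients**: random-walk Metropolis for the adjustment block and
   every effectively included term, with Robbins-Monro adaptation of each
   proposal scale towards 0.35 acceptance during the first `n_adapt`
   iterations only (scales freeze afterwards, preserving detailed balance
   for the retained draws).
3. **Inclusion probabilities**: the exact conjugate draw
   `p_v ~ Beta(a_t + ind, b_t + 1 - ind)`.
4. **Scales**: random-walk Metropolis on `log sigma` (Jacobian-corrected)
   and `log psi_int`, with the coefficients of currently excluded terms
   integrated out of the target (their priors integrate to one), followed by
5. a **refresh** of every excluded coefficient from its prior under the new
   scales. Steps 4-5 together are a partially collapsed Gibbs update; the
   collapse decouples the scales from the purely prior-driven coefficients
   and is what lets `log psi_int` mix essentially like its prior when no
   interaction is active.

With `prior_only` the likelihood is identically zero, every coefficient
conditional reduces to its prior and is drawn exactly, and the indicator,
probability and scale kernels run unchanged. This mode is the sampler's
primary correctness oracle: the chain must reproduce every analytic prior
marginal (main inclusion 0.25, effective interaction inclusion 0.03125,
`log psi_int ~ N(2.3, 1)`, half-Cauchy `sigma`), and the tests assert it at
the default 16,000-retained protocol. Two further oracles validate the
data-path kernels against brute force: on a fixed 40-subject, two-term
problem with `sigma` fixed, sampled model probabilities match quadrature
enumeration of all four models to well under 0.01; and on a one-term problem
with `sigma` *sampled*, the posterior inclusion matches numerical
integration over `(beta, sigma)`, validating the collapsed scale kernel.

Chain protocol defaults: 20,000 iterations, the first 2,000 for adaptation
and the next 2,000 as burn-in, so inference uses 16,000 retained draws.
Initialisation is the null model (all indicators off, coefficients zero,
`p` at its prior mean, `sigma = 1`, `psi_int = e^2.3`). There is no
automated convergence rule; `gebma.diagnostics` provides trace plots and
lag-autocorrelation summaries for visual inspection.

## Reporting

Marginal odds ratios are `exp(E[Ieff * beta])` (zeros included — these
shrink heavily towards 1 under sparse priors); conditional odds ratios
average `beta` only over draws with the term included. Intervals come in two
flavours, both reported: an equal-tailed 95% posterior credible interval,
and a Monte-Carlo-error band for the posterior mean (mean +/- 1.96 x batch-
means MCSE), which is the extremely tight kind of interval that matches
published tables of the form "1.05 (1.05-1.05)". The variable Bayes factor
is the posterior-to-prior odds ratio of inclusion, read against the
Kass-Raftery calibration (boundaries assigned to the lower bin: BF = 1 is
"none", BF = 3 "very mild", BF = 20 "positive", BF = 150 "strong"). At the
model level the posterior probability is the visit frequency of the
effective-indicator pattern, the prior is the closed-form beta-Bernoulli
product, `BF_all` is by default the posterior/prior *probability* ratio and
`BF_0` the posterior/posterior ratio against the covariates-only null model
— the conventions that reproduce the published model-level tables
(e.g. 0.59/0.154 = 3.8); posterior/prior *odds* versions are available via
`convention="odds"`.

## Synthetic cohorts

The generator emulates the marginal structure of the motivating
breast-cancer case-control study (654 cases, 1085 controls, diagnosis by age
50): genotype category frequencies for NAT1*10 and CYP1B1*3 allele counts
and binary NAT2 slow-acetylator, CYP1A1 variant, GSTT1 and GSTM1 deletion
codings; age as a truncated normal on [18, 50] whose latent location is
solved so the truncated mean hits 42.6 (SD 5.7); family history as
Bernoulli(0.052); menopausal status as a three-level categorical
(pre/post/unknown). Packyears is zero-inflated gamma: zero with probability
1 - `smoker_prob` (default 0.5 — the never-smoker fraction is not published
and is exposed as a `CohortSpec` field), else gamma with shape/scale solved
from the
smoker mean/SD (13.92, 11.83), chosen so the overall control mixture
reproduces the published 6.96 +/- 10.88.

Outcomes come from a configurable logistic model on the raw columns: a
superpopulation (default 20x the cohort) is generated, the intercept is
calibrated by bisection to a 10% population risk unless given explicitly,
case status is drawn Bernoulli, and exactly the requested numbers of cases
and controls are sampled without replacement. Controls share the age
distribution of cases (frequency matching); individually matched designs,
missing data and genotyping error are out of scope, and genotype frequencies
are taken as given category probabilities without Hardy-Weinberg
enforcement. Because cohorts are frequency-matched draws from a logistic
superpopulation, passing tests demonstrate correct recovery of odds ratios
and selection behaviour under the assumed generating model — not robustness
to the matching artefacts, measurement error or confounding structure of the
real study.

## Design choices and numerical notes

* Menopause enters as two dummy columns (post-vs-pre, unknown-vs-pre) inside
  the adjustment block, despite the "all variables continuous" convention of
  the source analysis: a single ordinal coding of a nominal variable is
  statistically dubious, and the choice only affects nuisance adjustment.
  An `ordinal` switch is provided. Family history is dichotomised 0 / >=1.
* All fixed and main columns are mean-centered; interaction columns are
  products of centered parents and are *not* re-centered (a flag enables
  re-centering), preserving the product structure the heredity logic
  assumes. Centering means are stored so new data can be scored on the
  training scale.
* Canonical term order — adjustment block, mains (exposure first, genes
  alphabetical), interactions lexicographic — fixes trace layouts and
  stepwise tie-breaking, making runs bit-reproducible under a fixed seed.
* The backward stepwise baseline removes only (pure backward selection), a
  main effect is ineligible for removal while any of its interactions
  remains, the adjustment block is never removed, ties break towards the
  earlier canonical term, and the AIC path is non-increasing by
  construction. Wald (not profile) confidence intervals are reported.
* Degenerate cases: a term never included in a trace reports marginal OR 1,
  no conditional OR, and Bayes factor 0; inclusion probabilities of exactly
  0 or 1 yield BF 0 or infinity rather than an exception; a sensitivity
  scenario that fails records its error and the grid continues.
* `fit_logistic` refuses rank-deficient designs and suspected separation,
  naming the offending columns.

## A coupling property worth knowing

The hierarchy couples terms through `sigma`: the coefficient scale is
learned from whichever coefficients are currently included. When a cohort
contains several clearly-supported effects, `sigma` stays identified in
every prior scenario and the posterior inclusion of a *weak* term responds
to its prior essentially proportionally — doubling the prior inclusion
probability roughly doubles the posterior, matching the qualitative
behaviour reported for the original analysis, and conditional odds ratios
barely move. When instead nothing (or only one weak term) anchors `sigma`,
raising the expected prior inclusion also raises the co-inclusion of null
terms, which anchors `sigma` low more often, reduces the vague-slab
(Lindley) penalty and amplifies the prior's effect beyond proportionality —
we measure posterior-odds ratios of 4-6 where the prior-odds ratio is 3.
The sensitivity tests therefore evaluate proportionality in the anchored
regime (three strong generating effects plus one weak signal) and scale
stability on null cohorts, where shifts from changing `mu_int` or the
half-Cauchy scale stay within Monte-Carlo replication tolerance.

## Problem sizes used by the test suite

Cohorts are generated at the study size (654/1085) for parameter-recovery
and sensitivity checks, with smaller cohorts (a few hundred subjects) for
structural and estimator tests; sensitivity scenarios use 5,000 retained
draws each, prior recovery the full 16,000, and the brute-force oracles
small fixed datasets (40 subjects) where exhaustive enumeration is exact.

## Known limitations

* Exact numerical agreement with the original study's posterior quantities
  is impossible without its (undeposited) cohort; data-dependent published
  values are used only as worked-example inputs to the Bayes-factor
  arithmetic.
* Analyses of this kind have traditionally been run in general-purpose Gibbs
  samplers such as WinBUGS; no attempt is made to replicate any particular
  engine's per-node sampler choices — agreement is at the level of the
  target posterior, verified against independent oracles.
* `predict_proba` of the averaged estimator is a plug-in of posterior-mean
  effective coefficients, not a fully Bayesian posterior-predictive average.
* Marginal-likelihood estimation beyond indicator visit frequencies,
  gradient-based samplers and higher-order interactions are out of scope.
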