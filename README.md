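# gebma — Bayes model averaging for gene–environment case-control studies

`gebma` implements a hierarchical Bayesian model-averaging analysis of
gene–environment effects on disease risk, of the kind used to study genetic
variants in tobacco-smoke carcinogen-metabolism pathways (NAT1/NAT2 in the
aromatic-amine pathway; CYP1A1/CYP1B1/GSTM1/GSTT1 in the polycyclic-aromatic-
hydrocarbon pathway) and cumulative smoking exposure in breast-cancer
case-control data. It is aimed at statistical geneticists and epidemiologists
who want selection-aware inference — posterior inclusion probabilities and
Bayes factors instead of a forest of unadjusted p-values — together with the
standard frequentist comparators.

## The model

At every MCMC iteration the disease model is a logistic regression with
latent term-inclusion indicators,

```
logit P(Y=1 | X) = Σ_c β_c X_c  +  Σ_ν Ieff_ν β_ν X_ν
```

where the adjustment block `X_c` (age, family history, menopausal status) is
always present and the selectable terms `X_ν` are the exposure (packyears),
six genotype codings, exposure×gene interactions and within-pathway
gene–gene interactions. Strong heredity is built in: an interaction's
effective indicator is `Ieff_rs = I_r · I_s · J_rs`, so it can only be
included when both parent main effects are. Priors: per-term inclusion
probabilities `p_ν ~ Beta(1,3)` for mains (marginal inclusion 0.25) and
`Beta(2,2)` for the free interaction indicator (conditional 0.5, marginal
0.03125); spike-and-slab coefficients `β_ν ~ N(0, (ψ_t σ)²)` with
`ψ_main = 1`, `log ψ_int ~ N(2.3, 1)` and a half-Cauchy(100) prior on σ. A
Metropolis-within-Gibbs sampler (20,000 iterations by default: 2,000
adaptation + 2,000 burn-in + 16,000 retained) explores models and
coefficients jointly; see `docs/methods.md` for the kernels and the
correctness oracles. The frequentist baseline (pointwise logistic fits,
full-model fits, and backward stepwise AIC selection under heredity) is
included for side-by-side comparison.

## Worked example

```python
import numpy as np
from gebma import (BMALogisticRegression, CohortSpec, TrueModel, simulate_cohort,
                   variable_bayes_factor, kass_raftery_category)

spec = CohortSpec()          # 654 cases / 1085 controls, published marginals
truth = TrueModel(coefficients={"nat1": np.log(1.5)})   # one real effect
cohort = simulate_cohort(spec, truth, seed=8)

est = BMALogisticRegression(n_iter=6000, n_adapt=1000, n_burn=500, random_state=1)
est.fit(cohort.drop(columns=["outcome"]), cohort["outcome"])

cols = ["term", "or_marginal", "or_conditional", "pr_post", "bf", "evidence"]
print(est.term_summary_[cols].head(7).to_string(index=False))
print(est.model_summary_.head(4).to_string(index=False))

bf = variable_bayes_factor(0.26, 0.25)
print(f"BF for inclusion at posterior 0.26 vs prior 0.25: {bf:.2f} "
      f"({kass_raftery_category(bf)})")
```

prints

```
     term  or_marginal  or_conditional  pr_post    bf evidence
packyears        1.000           0.994    0.001  0.00     none
   cyp1a1        0.999           0.953    0.031  0.10     none
   cyp1b1        1.000           1.014    0.014  0.04     none
    gstm1        1.000           0.998    0.024  0.07     none
    gstt1        1.008           1.168    0.054  0.17     none
     nat1        1.417           1.445    0.946 53.02   strong
     nat2        1.002           1.079    0.020  0.06     none

      model  posterior    prior    bf_all      bf_0
       nat1   0.820000 0.044495 18.429191 15.439331
       NULL   0.053111 0.133484  0.397884  1.000000
 gstt1+nat1   0.044444 0.014832  2.996616  0.836820
cyp1a1+nat1   0.023556 0.014832  1.588207  0.443515

BF for inclusion at posterior 0.26 vs prior 0.25: 1.05 (very mild)
```

Reading it: the genuinely associated term (`nat1`, generating OR 1.5 per
allele) is included in 95% of retained models — a variable Bayes factor of
53, "strong" on the Kass–Raftery scale — and its conditional odds ratio
(1.445, averaged over models that contain it) sits near the truth, while the
*marginal* OR (1.417) is shrunk towards 1 by the iterations that exclude it.
Null terms hover at or below their prior inclusion (BF < 1). At the model
level, the single-term `nat1` model dominates (posterior 0.82 vs closed-form
prior 0.044, BF_all ≈ 18) and beats the covariates-only NULL model by
BF_0 ≈ 15. The last line shows the desk arithmetic: a term whose inclusion
probability barely rises from 0.25 to 0.26 has BF 1.05 — only very mild
evidence.

The same pipeline is scriptable from the shell:

```bash
gebma simulate --seed 8 --out cohort.csv
gebma fit-bma --data cohort.csv --seed 1 --out results/
gebma stepwise --data cohort.csv --start all --out stepwise/
gebma sensitivity --data cohort.csv --out sensitivity/
```

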