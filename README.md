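# admixkit

Maximum-likelihood and penalized estimation of **individual ancestry
fractions** and **population allele frequencies** from SNP genotype
matrices, for population geneticists and genetic epidemiologists who
need fast, reproducible model-based ancestry estimates from PLINK-format
data.

## The model

The genotype `n_ij ∈ {0,1,2}` of individual *i* at biallelic SNP *j*
counts the copies of allele 1 and is modelled as

```
n_ij ~ Binomial(2, p_ij),      p_ij = Σ_k q_ik f_kj,
```

where `q_ik` is the fraction of *i*'s genome from ancestral population
*k* (rows of the I×K matrix **Q** lie on the probability simplex) and
`f_kj` is the allele-1 frequency in population *k* (the K×J matrix
**F**). The fit maximizes the biconcave log-likelihood

```
L(Q,F) = Σ_{ij observed} [ n_ij ln p_ij + (2 − n_ij) ln(1 − p_ij) ]
```

by block relaxation — alternating sequential-quadratic-programming
updates of Q (simplex-constrained) and F (box-constrained) — with
safeguarded quasi-Newton extrapolation of the fixed-point map for
acceleration. On top of the plain fit the package provides

* **cross-validation** of K (or of the penalty strength λ) by masking
  random genotype *entries*, refitting, and scoring masked predictions
  with mean squared binomial deviance residuals
  `d²(n, μ̂) = 2[n ln(n/μ̂) + (2−n) ln((2−n)/(2−μ̂))]`, `μ̂ = 2 Σ_k q̂ f̂`;
* **supervised mode**: reference individuals with known single-origin
  ancestry have their Q rows fixed to unit vectors, sharpening the
  allele-frequency estimates and removing most ancestry-fraction bias;
* **penalized estimation**: an approximate-ℓ0 penalty
  `λ Σ ln(1 + q_ik/γ)/ln(1 + 1/γ)` that shrinks and zeroes spurious
  small admixture coefficients;
* a **Balding-Nichols simulator** for two-population benchmark cohorts
  with grid-admixed individuals, plus evaluation statistics
  (frequency RMSE, a Wright-style F_ST estimate, ancestry bias curves).

## Worked example

```python
import numpy as np
from admixkit import (SimulationDesign, simulate_dataset, fit, OptimizerConfig,
                      rmse_frequencies, estimate_fst)
from admixkit.simulate import align_populations, reference_labels
from admixkit.supervised import supervised_fit

# two closely related populations (FST=.01), 10,000 SNPs,
# 100 references per population + 200 grid-admixed individuals
design = SimulationDesign(J=10_000, K=2, fst=0.01,
                          n_ref_per_pop=100, n_admixed=200, seed=11)
genotypes, truth = simulate_dataset(design)

unsup = fit(genotypes, K=2, config=OptimizerConfig(seed=17))
perm = align_populations(unsup.F, truth.F_true)
print("unsupervised  rmse(f1) = %.4f   FST = %.4f"
      % (rmse_frequencies(unsup.F, truth.F_true, 0), estimate_fst(unsup.F[perm])))

sup = supervised_fit(genotypes, reference_labels(design), OptimizerConfig(seed=17))
print("supervised    rmse(f1) = %.4f   FST = %.4f"
      % (rmse_frequencies(sup.F, truth.F_true, 0), estimate_fst(sup.F)))
```

prints

```
unsupervised  rmse(f1) = 0.0247   FST = 0.0178
supervised    rmse(f1) = 0.0226   FST = 0.0142
```

With only 10,000 markers separating two populations at a true F_ST of
.01, the unsupervised fit recovers population-1 allele frequencies with
an RMSE of about .025; fixing the 200 reference individuals' ancestries
(supervised mode) lowers that error and brings the estimated F_ST —
inflated above the true .010 by frequency-estimation error — closer to
the truth. The same pattern holds replicate after replicate.

From the shell, the same fits run off PLINK files:

```sh
admixkit data.bed 3 -j4            # unsupervised, K=3, 4 workers
admixkit data.bed 2 --supervised   # requires data.ind reference labels
admixkit data.bed 2 --cv=5         # 5-fold CV table of K = 1..2
admixkit data.bed 2 --lambda 5     # penalized fit at lambda=5, gamma=.1
```

`workers` (`-jN`) is a throughput knob only: results are identical for
every worker count.

## Layout

| module | contents |
| --- | --- |
| `admixkit.genotype_io` | PLINK `.bed/.bim/.fam` codec, `.ind` labels, `.Q`/`.P` files |
| `admixkit.core_model` | likelihood, gradients/Hessians, dosages, deviance residuals |
| `admixkit.optimize` | block-relaxation optimizer with QP steps and QN acceleration |
| `admixkit.crossval` | entry-masking folds, CV error, selection of K and λ |
| `admixkit.supervised` | fixed-row constraints from reference labels |
| `admixkit.penalized` | approximate-ℓ0 penalty on ancestry fractions |
| `admixkit.simulate` | Balding-Nichols cohorts and evaluation statistics |
| `admixkit.experiments` | replicated benchmark studies used by the acceptance script |
| `admixkit.cli` | the `admixkit` command |
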