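# Methods

## Model and estimation

Genotypes are counts of a designated "allele 1" per individual and
marker, `n_ij ~ Binomial(2, p_ij)` with `p_ij = Σ_k q_ik f_kj`. The
likelihood treats markers as independent (no linkage disequilibrium) and
both alleles of an individual as independent draws given its ancestry
vector — the standard admixture model. Missing genotypes contribute
nothing to any sum; masked entries during cross-validation are treated
identically.

The log-likelihood is concave in Q for fixed F and in F for fixed Q, but
not jointly concave, so the optimizer is a block relaxation:

* **Q block.** With F fixed the likelihood separates over individuals.
  Each ancestry row maximizes its second-order Taylor expansion subject
  to `Σ_k q_ik = 1`, `q_ik ≥ 0`. The equality constraint enters through
  a bordered KKT system; nonnegativity through an active-set loop that
  pins coordinates crossing zero (at most K rounds). All I row problems
  are solved in one batched linear solve per round.
* **F block.** With Q fixed the likelihood separates over markers; each
  frequency column takes the analogous Newton/QP step under box
  constraints `[ε_f, 1−ε_f]` with `ε_f = 1e-6`.

Both steps are *safeguarded*: the candidate's objective contribution is
compared per row (or per marker) with the current one, and any row that
would decrease is halved back toward the current point up to 10 times,
then reverted. The objective trajectory is therefore non-decreasing by
construction. A tiny ridge (`1e-9` scaled by the Hessian diagonal)
keeps the KKT systems nonsingular in degenerate cases (e.g. an
individual with no observed genotypes). Success probabilities are
clamped to `[1e-10, 1−1e-10]` before logs; with F kept inside its box
the clamp never binds at an optimum.

**Acceleration.** The block-relaxation map is extrapolated with a
quasi-Newton step built from the most recent secant differences
(default 3): with `U` and `V` the matrices of successive pre- and
post-step differences, the proposal is
`x⁺ = M(x) + V (UᵀU − UᵀV)⁻¹ Uᵀ (M(x) − x)`, i.e. an approximate
Newton step for the fixed-point residual using a least-squares secant
model of the map's Jacobian. The proposal is projected back to
feasibility (simplex projection for Q rows, clamping for F) and accepted
only when it beats the plain step's objective, so monotone ascent
survives acceleration; on an affine map the extrapolation reaches the
fixed point exactly, which the test suite checks. Convergence is
declared when an accelerated iteration improves the objective by less
than `convergence_tol` (default `1e-4`); the cap is 500 iterations.

**Initialization.** Q rows are drawn from a flat Dirichlet; F starts at
the overall per-marker empirical frequency with population-specific
Gaussian jitter (σ = .05), which breaks the column exchangeability of
the otherwise symmetric start. All randomness flows from a single seed;
two runs with the same seed are bit-identical. The `workers` setting is
validated but never alters results: every subproblem is independent and
reductions run in a fixed order.

**Determinism caveat.** The likelihood is invariant under relabeling of
populations, so independent seeds can return column-permuted solutions;
every evaluation statistic first aligns estimated to true populations by
the permutation minimizing total frequency RMSE.

## Supervised mode

Reference individuals' rows of Q are held at exact unit vectors
(bit-exact in the output, not merely converged); only unlabeled rows and
all of F are estimated. Reference rows are excluded from penalty terms —
their coefficients are constants and penalizing them would only shift
the objective trace — and excluded from bias statistics, since their
estimates are fixed by construction.

## Penalized estimation

The penalty `pen(Q) = λ Σ_{ik} ln(1 + q_ik/γ) / ln(1 + 1/γ)` is a
bounded concave surrogate for counting nonzero coefficients: the
normalization makes a unit coefficient cost exactly λ and, as γ → 0, the
penalty tends to λ × #nonzeros. Defaults: λ = 0 (off); γ = .1 when
penalized mode is enabled without an explicit γ. The penalty applies to
Q only; the F update is untouched.

Because the penalty is concave, folding its (convex, when negated)
second-order term into the Q-block quadratic model could destroy the
model's concavity at large λ and stall the QP. The Q step therefore
*linearizes* the penalty — the standard majorize-minimize treatment of
concave penalties: the linearization minorizes the penalized objective,
so a step that improves the surrogate improves the true objective, and
the safeguarded ascent check applies to the true penalized objective in
any case. Entries driven below `1e-10` are snapped to exact zero and the
row renormalized, realizing exact sparsity in finite arithmetic. The
penalized per-row problem can be multimodal; the safeguard guarantees
ascent, not global optimality — the λ → ∞ limit (all rows at vertices)
and the monotone growth of the zero count with λ are exercised in tests.

## Cross-validation

The observed genotype *cells* are partitioned uniformly at random into v
roughly equal folds (sizes differ by at most one); masking whole
individuals or whole markers would leave nothing to identify their
parameters with. The default is v = 5. Each fold is masked in turn, the
model refit, and each masked count scored by the squared binomial
deviance residual of its predicted dosage; the reported error is the
mean over all masked entries of all folds. Fold fits are re-initialized
with a deterministic seed derived from the master seed and the fold's
own content (its smallest flattened entry index), so fold *labels* are
immaterial and whole runs reproduce exactly. Grids over K or λ select
the minimizer, ties broken toward the smaller (more parsimonious) value.
Fitted dosages at a clamp boundary are used as clamped, keeping the
residual finite. Fold assignment is not stratified by individual or
marker; a fold that happens to mask every observation of some row or
column triggers a warning, and the affected predictions are still made
from the fitted state.

## Simulator

The generator reproduces the standard two-population benchmark for this
model class, and its defaults are the benchmark's study conditions:
J = 10,000 markers; ancestral frequencies `p_j ~ Uniform(0,1)`;
per-population frequencies `f_kj ~ Beta(p_j(1−c)/c, (1−p_j)(1−c)/c)`
with differentiation c = F_ST = .01 (closely related populations within
a continent), so `E[f] = p` and `Var[f] = c·p(1−p)`; 100 unadmixed
reference individuals per population; 200 admixed individuals whose
population-1 fraction lies on the open uniform grid `i/(n+1)` —
endpoints excluded because the unadmixed references already occupy them;
genotypes drawn `Binomial(2, QF)` with no missingness. Independent
markers and the absence of genotyping error or LD mean passing
benchmarks here show correct recovery *under the model's own
assumptions*, not robustness to real-data violations of them.

Evaluation statistics:

* **Frequency RMSE** `sqrt(mean_j (f̂_kj − f_kj)²)` after label
  alignment.
* **F_ST estimate** between two frequency vectors: the ratio-of-averages
  Wright-style form `Σ_j (f_1j−f_2j)²/2 ÷ Σ_j p̄_j(1−p̄_j)` with
  `p̄ = (f_1+f_2)/2`, clipped to [0, 1]. On true Balding-Nichols
  frequencies it is consistent for the generating F_ST up to a factor
  `1/(1−c/2)`, negligible at c = .01.
* **Bias curves**: a 20-bin conditional mean of `q̂_i1` given the true
  `q_i1` over the admixed individuals — a deterministic stand-in for a
  LOESS smoother, chosen so that assertions about the curve are exactly
  reproducible. `mean_absolute_q_bias` summarizes the same comparison as
  one number.

## Benchmark scale and observed behavior

The replicated study (`admixkit.experiments`) uses 10 replicates of the
J = 10,000 design — enough for stable means of the RMSE and F_ST
summaries at desk scale — and one cohort for the λ cross-validation over
{0, 1, 2, 5, 10, 20, 50, 100} at γ = .1. Unit tests exercise the same
properties on smaller cohorts (hundreds to thousands of markers) chosen
so the full suite stays fast.

One observed deviation from the historical reference values for this
benchmark deserves a note: the reference unsupervised frequency RMSE for
this design is about .046, while this implementation lands near .025,
close to the Cramér-Rao bound for the design (with ~300 effective
allele observations per marker informing `f_1j`, the ML standard error
is ≈ √(p(1−p)/333), averaging ≈ .022 over uniform p). Deeply converged
maximum-likelihood fits — multiple random starts reach the identical
log-likelihood, with tiny projected-gradient norms — simply estimate F
more precisely than the reference figures, and the downstream F_ST
inflation (driven by squared frequency errors) is correspondingly
smaller than the reference .024/.019 while preserving the
supervised-below-unsupervised ordering.

The same precision shifts the penalty cross-validation: shrinkage earns
its keep when fits overfit, so an estimator already near the efficiency
bound gains nothing from it, and the CV error curve over λ on this
design is flat-to-increasing with its minimum at λ = 0 rather than at
the reference λ = 5 (the penalty still strictly reduces the mean
absolute ancestry bias of the admixed individuals when applied, and
still produces exact sparsity — both are tested). The package reports
what it computes; no attempt is made to emulate a less converged
optimizer.

## Known limitations

* Only SNP-major PLINK binary input; no VCF, no text `.ped`.
* The grid-admixture cohort design is defined for exactly two ancestral
  populations (K > 2 reference-only designs work fine).
* The penalized objective is non-concave per row; different seeds can
  reach different sparse local optima at moderate λ.
* No modelling of LD, genotyping error, or inbreeding; allele
  frequencies are free parameters per population, so very small
  reference panels in supervised mode will overfit F.
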