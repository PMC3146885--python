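"""Balding-Nichols simulation of admixed cohorts and evaluation statistics.

The generator reproduces a standard two-population benchmark design for
ancestry-estimation methods:

* ancestral allele frequencies p_j drawn uniformly on [0, 1] for J
  markers (J = 10,000 by default);
* per-population frequencies f_kj from the Balding-Nichols model,
  f_kj ~ Beta(p_j (1-F_ST)/F_ST, (1-p_j)(1-F_ST)/F_ST), so that
  E[f_kj] = p_j and Var[f_kj] = F_ST p_j (1-p_j); the default
  differentiation is F_ST = .01, typical of closely related populations
  within a continent;
* a cohort of 100 reference individuals drawn entirely from each of the
  two populations plus 200 admixed individuals whose population-1
  fraction lies on a uniform open grid i/(n+1), i = 1..n (the endpoints
  0 and 1 are the references themselves);
* genotypes n_ij ~ Binomial(2, Σ_k q_ik f_kj), independent across
  markers (no linkage disequilibrium) and with no missingness.

Evaluation helpers measure how well a fit recovers the truth: RMSE of
the estimated allele-frequency vectors, a Wright-style F_ST estimate
between the two fitted frequency vectors, and binned conditional-mean
bias curves of estimated versus true ancestry fractions.  Estimated
populations are matched to true ones by the label assignment minimizing
total frequency RMSE before any statistic is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from pathlib import Path

import numpy as np

from .genotype_io import GenotypeMatrix, PopulationLabels, write_ind_file, write_plink_bed

__all__ = [
    "SimulationDesign",
    "SimulationTruth",
    "draw_balding_nichols",
    "build_cohort",
    "sample_genotypes",
    "simulate_dataset",
    "reference_labels",
    "align_populations",
    "rmse_frequencies",
    "estimate_fst",
    "bias_curve",
    "mean_absolute_q_bias",
    "admixture_grid",
    "write_truth_sidecar",
    "write_dataset",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Cohort and marker layout of one simulated dataset."""

    J: int = 10_000
    K: int = 2
    fst: float = 0.01
    n_ref_per_pop: int = 100
    n_admixed: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must lie in (0, 1)")
        if min(self.J, self.K) < 1 or min(self.n_ref_per_pop, self.n_admixed) < 0:
            raise ValueError("all counts must be nonnegative (J, K >= 1)")
        if self.n_admixed > 0 and self.K != 2:
            raise ValueError("grid admixture is defined between exactly two populations")

    @property
    def n_individuals(self) -> int:
        return self.K * self.n_ref_per_pop + self.n_admixed


@dataclass
class SimulationTruth:
    """Generating parameters retained for evaluation."""

    ancestral_freqs: np.ndarray  # (J,)
    F_true: np.ndarray           # (K, J)
    Q_true: np.ndarray           # (I, K)
    design: SimulationDesign


def draw_balding_nichols(J: int, K: int, fst: float, seed: int):
    """Ancestral frequencies p_j ~ U(0,1) and per-population Balding-Nichols
    frequencies f_kj ~ Beta(p_j (1-F)/F, (1-p_j)(1-F)/F), independent over k, j."""
    if not (0.0 < fst < 1.0):
        raise ValueError("fst must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.0, 1.0, size=J)
    ratio = (1.0 - fst) / fst
    a = np.maximum(p * ratio, 1e-12)
    b = np.maximum((1.0 - p) * ratio, 1e-12)
    F = rng.beta(a[None, :], b[None, :], size=(K, J))
    return p, F


def admixture_grid(n_admixed: int) -> np.ndarray:
    """Population-1 fractions i/(n+1), i = 1..n: uniform, open at 0 and 1."""
    return np.arange(1, n_admixed + 1) / (n_admixed + 1)


def build_cohort(design: SimulationDesign) -> SimulationTruth:
    """Stack reference rows (unit vectors) and grid-admixed rows into Q_true
    and draw the allele-frequency truth for the design."""
    p, F = draw_balding_nichols(design.J, design.K, design.fst, design.seed)
    blocks = []
    for k in range(design.K):
        e = np.zeros(design.K)
        e[k] = 1.0
        blocks.append(np.tile(e, (design.n_ref_per_pop, 1)))
    if design.n_admixed:
        g = admixture_grid(design.n_admixed)
        blocks.append(np.column_stack([g, 1.0 - g]))
    Q = np.vstack(blocks)
    return SimulationTruth(ancestral_freqs=p, F_true=F, Q_true=Q, design=design)


def sample_genotypes(truth: SimulationTruth, seed: int) -> GenotypeMatrix:
    """Draw n_ij ~ Binomial(2, q_i· f·_j) for every individual and marker."""
    rng = np.random.default_rng(seed)
    P = np.clip(truth.Q_true @ truth.F_true, 0.0, 1.0)
    counts = rng.binomial(2, P).astype(np.int8)
    I, J = counts.shape
    ids = [f"ind{i:04d}" for i in range(I)]
    markers = [f"snp{j:06d}" for j in range(J)]
    return GenotypeMatrix(counts, ids, markers)


def simulate_dataset(design: SimulationDesign):
    """Truth plus one genotype draw; the genotype seed is derived from the
    design seed so successive replicates stay independent."""
    truth = build_cohort(design)
    genotypes = sample_genotypes(truth, seed=design.seed + 1_000_003)
    return genotypes, truth


def reference_labels(design: SimulationDesign) -> PopulationLabels:
    """Population labels for the reference rows; admixed rows unlabeled."""
    assignments: list[str | None] = []
    for k in range(design.K):
        assignments += [f"POP{k + 1}"] * design.n_ref_per_pop
    assignments += [None] * design.n_admixed
    return PopulationLabels(assignments, [f"POP{k + 1}" for k in range(design.K)])


def align_populations(F_hat: np.ndarray, F_true: np.ndarray) -> np.ndarray:
    """Permutation putting estimated populations in the order of the true
    ones, chosen to minimize total frequency RMSE (label switching)."""
    F_hat = np.atleast_2d(F_hat)
    F_true = np.atleast_2d(F_true)
    K = F_true.shape[0]
    if F_hat.shape != F_true.shape:
        raise ValueError("F_hat and F_true must have matching shapes")
    best, best_cost = None, np.inf
    for perm in permutations(range(K)):
        cost = float(((F_hat[list(perm)] - F_true) ** 2).sum())
        if cost < best_cost:
            best, best_cost = perm, cost
    return np.asarray(best, dtype=np.intp)


def rmse_frequencies(F_hat: np.ndarray, F_true: np.ndarray, pop: int = 0,
                     align: bool = True) -> float:
    """Root-mean-squared error of the estimated frequency vector of one
    population, after resolving label switching."""
    F_hat = np.atleast_2d(np.asarray(F_hat, dtype=np.float64))
    F_true = np.atleast_2d(np.asarray(F_true, dtype=np.float64))
    if F_hat.shape != F_true.shape:
        raise ValueError("F_hat and F_true must have matching shapes")
    if align:
        F_hat = F_hat[align_populations(F_hat, F_true)]
    diff = F_hat[pop] - F_true[pop]
    return float(np.sqrt(np.mean(diff**2)))


def estimate_fst(F_hat: np.ndarray) -> float:
    """Wright-style ratio-of-averages F_ST between two frequency vectors:

        F̂_ST = Σ_j (f_1j - f_2j)²/2  /  Σ_j p̄_j (1 - p̄_j),   p̄ = (f_1+f_2)/2,

    clipped to [0, 1] (the raw ratio can exceed 1 for maximally divergent
    fixed differences)."""
    F_hat = np.atleast_2d(np.asarray(F_hat, dtype=np.float64))
    if F_hat.shape[0] != 2:
        raise ValueError("estimate_fst expects exactly two frequency vectors")
    f1, f2 = F_hat
    pbar = 0.5 * (f1 + f2)
    denom = float((pbar * (1.0 - pbar)).sum())
    if denom <= 0:
        raise ValueError("degenerate frequencies: every marker fixed, FST undefined")
    num = float(((f1 - f2) ** 2).sum() / 2.0)
    return float(min(num / denom, 1.0))


def bias_curve(Q_hat: np.ndarray, Q_true: np.ndarray, exclude_refs: bool = True,
               n_bins: int = 20, align_to: np.ndarray | None = None):
    """Binned conditional mean of q̂_i1 given the true q_i1.

    A deterministic stand-in for a LOESS smoother: admixed individuals are
    grouped into ``n_bins`` equal-width bins of true q_i1 and the mean
    estimate is reported per nonempty bin.  Reference individuals (true
    rows exactly unit vectors) are excluded by default, since their
    estimates are either fixed (supervised) or uninformative about bias.

    Returns ``(q_true_centers, q_hat_means)`` arrays.  ``align_to`` may
    carry a precomputed column permutation for label switching.
    """
    Q_hat = np.atleast_2d(np.asarray(Q_hat, dtype=np.float64))
    Q_true = np.atleast_2d(np.asarray(Q_true, dtype=np.float64))
    if Q_hat.shape != Q_true.shape:
        raise ValueError("Q_hat and Q_true must have matching shapes")
    if align_to is not None:
        Q_hat = Q_hat[:, np.asarray(align_to, dtype=np.intp)]
    keep = np.ones(Q_true.shape[0], dtype=bool)
    if exclude_refs:
        keep = ~np.isclose(Q_true, 1.0).any(axis=1)
    q = Q_true[keep, 0]
    qh = Q_hat[keep, 0]
    if q.size < 10:
        raise ValueError("need at least 10 admixed individuals to smooth")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(q, edges) - 1, 0, n_bins - 1)
    centers, means = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            centers.append(q[sel].mean())
            means.append(qh[sel].mean())
    return np.asarray(centers), np.asarray(means)


def mean_absolute_q_bias(Q_hat, Q_true, exclude_refs: bool = True) -> float:
    """Mean |q̂_i1 - q_i1| over (by default) the admixed individuals, after
    resolving label switching against the true Q columns."""
    Q_hat = np.atleast_2d(np.asarray(Q_hat, dtype=np.float64))
    Q_true = np.atleast_2d(np.asarray(Q_true, dtype=np.float64))
    K = Q_true.shape[1]
    best = np.inf
    for perm in permutations(range(K)):
        Qp = Q_hat[:, list(perm)]
        keep = np.ones(Q_true.shape[0], dtype=bool)
        if exclude_refs:
            keep = ~np.isclose(Q_true, 1.0).any(axis=1)
        val = float(np.abs(Qp[keep, 0] - Q_true[keep, 0]).mean())
        best = min(best, val)
    return best


def write_truth_sidecar(truth: SimulationTruth, path) -> Path:
    """Plain-text sidecar with the generating parameters, so downstream
    stages are testable without regeneration."""
    path = Path(path)
    d = truth.design
    with open(path, "w") as fh:
        fh.write(f"# J={d.J} K={d.K} fst={d.fst} n_ref_per_pop={d.n_ref_per_pop} "
                 f"n_admixed={d.n_admixed} seed={d.seed}\n")
        fh.write("# ancestral_freqs\n")
        fh.write(" ".join(f"{v:.6f}" for v in truth.ancestral_freqs) + "\n")
        fh.write("# F_true rows\n")
        for row in truth.F_true:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
        fh.write("# Q_true rows\n")
        for row in truth.Q_true:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
    return path


def write_dataset(truth: SimulationTruth, genotypes: GenotypeMatrix, prefix) -> None:
    """Write the PLINK trio, the reference .ind file, and the truth sidecar."""
    prefix = Path(prefix)
    write_plink_bed(genotypes, prefix)
    write_ind_file(reference_labels(truth.design), Path(str(prefix) + ".ind"))
    write_truth_sidecar(truth, Path(str(prefix) + ".truth.txt"))
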