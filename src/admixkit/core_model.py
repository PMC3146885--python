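"""The binomial admixture model.

Each genotype count n_ij (copies of allele 1 carried by individual i at
marker j) is modelled as Binomial(2, p_ij) with success probability

    p_ij = sum_k q_ik * f_kj,

where q_ik is the fraction of i's ancestry drawn from ancestral
population k (rows of Q lie on the probability simplex) and f_kj is the
allele-1 frequency in population k.  This module houses the
log-likelihood, its block gradients and Hessians (the likelihood
separates over individuals with F fixed and over markers with Q fixed),
predicted dosages, and binomial deviance residuals used for
cross-validation scoring.

Missing or masked entries are simply excluded from every sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "EPS_F",
    "EPS_P",
    "ModelState",
    "MaskedGenotypes",
    "success_probability",
    "log_likelihood",
    "row_log_likelihoods",
    "col_log_likelihoods",
    "block_gradients_and_hessians",
    "predicted_dosage",
    "squared_deviance_residual",
]

# Allele frequencies are kept in [EPS_F, 1-EPS_F] and success probabilities
# clamped to [EPS_P, 1-EPS_P] before logs: the log-likelihood is undefined at
# p in {0,1} and the clamp does not move interior optima.
EPS_F: float = 1e-6
EPS_P: float = 1e-10


@dataclass
class ModelState:
    """A point (Q, F) in parameter space.

    Q : I×K row-stochastic ancestry fractions.
    F : K×J allele-1 frequencies in [EPS_F, 1-EPS_F].
    """

    Q: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        self.Q = np.ascontiguousarray(self.Q, dtype=np.float64)
        self.F = np.ascontiguousarray(self.F, dtype=np.float64)
        if self.Q.ndim != 2 or self.F.ndim != 2 or self.Q.shape[1] != self.F.shape[0]:
            raise ValueError("Q must be I x K and F must be K x J")

    @property
    def K(self) -> int:
        return self.Q.shape[1]

    def validate(self, atol: float = 1e-8) -> None:
        if (self.Q < -atol).any():
            raise ValueError("Q has negative entries")
        if np.abs(self.Q.sum(axis=1) - 1.0).max() > atol:
            raise ValueError("rows of Q must sum to 1")
        if (self.F < EPS_F - 1e-15).any() or (self.F > 1 - EPS_F + 1e-15).any():
            raise ValueError("F entries must lie in [EPS_F, 1-EPS_F]")


class MaskedGenotypes:
    """A genotype matrix with a set of observed entries temporarily hidden.

    Used by cross-validation: masked entries are treated as missing during
    fitting, then predicted and scored.  Accessors report an entry as
    observed iff it is non-missing in the base matrix and not masked.
    """

    def __init__(self, base: GenotypeMatrix, masked_set) -> None:
        self.base = base
        rows, cols = _as_index_arrays(masked_set)
        if (base.counts[rows, cols] == MISSING).any():
            raise ValueError("masked_set must be a subset of non-missing entries")
        self._rows, self._cols = rows, cols
        counts = base.counts.copy()
        counts[rows, cols] = MISSING
        self.counts = counts

    @property
    def masked_rows(self) -> np.ndarray:
        return self._rows

    @property
    def masked_cols(self) -> np.ndarray:
        return self._cols

    @property
    def n_masked(self) -> int:
        return self._rows.size

    def observed_mask(self) -> np.ndarray:
        return self.counts != MISSING

    @property
    def n_individuals(self) -> int:
        return self.base.n_individuals

    @property
    def n_markers(self) -> int:
        return self.base.n_markers


def _as_index_arrays(masked_set) -> tuple[np.ndarray, np.ndarray]:
    pairs = list(masked_set) if not isinstance(masked_set, tuple) else masked_set
    if isinstance(masked_set, tuple) and len(masked_set) == 2:
        rows = np.asarray(masked_set[0], dtype=np.intp)
        cols = np.asarray(masked_set[1], dtype=np.intp)
    elif pairs:
        arr = np.asarray(pairs, dtype=np.intp)
        rows, cols = arr[:, 0], arr[:, 1]
    else:
        rows = cols = np.empty(0, dtype=np.intp)
    return rows, cols


class DenseGenotypes:
    """Precomputed float view of a genotype matrix for repeated likelihood work.

    Caches the float64 count matrix (missing entries zeroed), the observed
    mask, and 2*mask, so optimizer inner loops pay the int8 conversion once.
    """

    def __init__(self, genotypes) -> None:
        counts = genotypes.counts if hasattr(genotypes, "counts") else np.asarray(genotypes)
        self.obs = counts != MISSING
        self.N = np.where(self.obs, counts, 0).astype(np.float64)
        self.M = np.where(self.obs, 2.0, 0.0)  # trials per observed entry
        self.MN = self.M - self.N
        self.complete = bool(self.obs.all())
        self.counts = counts

    @property
    def n_individuals(self) -> int:
        return self.N.shape[0]

    @property
    def n_markers(self) -> int:
        return self.N.shape[1]

    def observed_mask(self) -> np.ndarray:
        return self.obs


def _counts_and_mask(genotypes) -> tuple[np.ndarray, np.ndarray]:
    """Float counts (missing zeroed) and the observed mask, as float64."""
    if isinstance(genotypes, DenseGenotypes):
        return genotypes.N, genotypes.obs
    counts = genotypes.counts if hasattr(genotypes, "counts") else np.asarray(genotypes)
    obs = counts != MISSING
    N = np.where(obs, counts, 0).astype(np.float64)
    return N, obs


def success_probability(Q: np.ndarray, F: np.ndarray, i=None, j=None):
    """p_ij = q_i. · f._j, the convex combination of row i of Q with column j of F.

    With ``i``/``j`` omitted, returns the full I×J matrix.
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=np.float64))
    F = np.atleast_2d(np.asarray(F, dtype=np.float64))
    if i is None and j is None:
        return Q @ F
    if i is None or j is None:
        raise ValueError("give both i and j, or neither")
    return float(Q[i] @ F[:, j])


def _clamped_probs(Q: np.ndarray, F: np.ndarray) -> np.ndarray:
    P = Q @ F
    np.clip(P, EPS_P, 1.0 - EPS_P, out=P)
    return P


def log_likelihood(genotypes, Q: np.ndarray, F: np.ndarray) -> float:
    """Binomial log-likelihood summed over observed entries.

    L(Q, F) = sum_{(i,j) observed} [ n_ij ln p_ij + (2 - n_ij) ln(1 - p_ij) ].
    """
    return float(row_log_likelihoods(genotypes, Q, F).sum())


def row_log_likelihoods(genotypes, Q: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Per-individual log-likelihood contributions (length I)."""
    N, obs = _counts_and_mask(genotypes)
    P = _clamped_probs(np.atleast_2d(Q), np.atleast_2d(F))
    terms = N * np.log(P) + (2.0 - N) * np.log1p(-P)
    return np.where(obs, terms, 0.0).sum(axis=1)


def col_log_likelihoods(genotypes, Q: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Per-marker log-likelihood contributions (length J)."""
    N, obs = _counts_and_mask(genotypes)
    P = _clamped_probs(np.atleast_2d(Q), np.atleast_2d(F))
    terms = N * np.log(P) + (2.0 - N) * np.log1p(-P)
    return np.where(obs, terms, 0.0).sum(axis=0)


def block_gradients_and_hessians(genotypes, Q: np.ndarray, F: np.ndarray, block: str):
    """Gradients and Hessians of L for one parameter block.

    With F fixed, L separates over individuals; with Q fixed, over markers.

    block="Q": returns ``(G, H)`` where ``G[i]`` is the K-vector
        dL/dq_ik = sum_j f_kj (n_ij / p_ij - (2 - n_ij) / (1 - p_ij))
    and ``H[i]`` is the K×K matrix
        d²L/dq_ik dq_il = -sum_j f_kj f_lj (n_ij / p_ij² + (2 - n_ij)/(1 - p_ij)²),
    negative semidefinite.  Only observed entries contribute.

    block="F": the symmetric per-marker bundle with multiplier q_ik:
    ``G`` is K×J, ``H`` is (J, K, K).
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=np.float64))
    F = np.atleast_2d(np.asarray(F, dtype=np.float64))
    N, obs = _counts_and_mask(genotypes)
    P = _clamped_probs(Q, F)
    R = 1.0 - P
    A = np.where(obs, N / P - (2.0 - N) / R, 0.0)
    W = np.where(obs, N / P**2 + (2.0 - N) / R**2, 0.0)
    K = Q.shape[1]
    if block == "Q":
        G = A @ F.T  # I x K
        H = -np.einsum("ij,kj,lj->ikl", W, F, F, optimize=True)
        return G, H
    if block == "F":
        G = Q.T @ A  # K x J
        H = -np.einsum("ij,ik,il->jkl", W, Q, Q, optimize=True)
        return G, H
    raise ValueError("block must be 'Q' or 'F'")


def predicted_dosage(Q: np.ndarray, F: np.ndarray, i=None, j=None):
    """Expected genotype count mu_ij = 2 p_ij in [0, 2]."""
    p = success_probability(Q, F, i, j)
    return 2.0 * p


def squared_deviance_residual(n, mu):
    """Squared binomial deviance residual for 2 trials.

    d²(n, mu) = 2 [ n ln(n/mu) + (2-n) ln((2-n)/(2-mu)) ],  0·ln 0 = 0.

    Vectorized over ``n`` and ``mu``; nonnegative, zero iff n == mu.
    """
    n = np.asarray(n, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    if (mu <= 0).any() or (mu >= 2).any():
        raise ValueError("predicted dosage mu must lie in the open interval (0, 2)")
    d2 = 2.0 * (xlogy(n, n / mu) + xlogy(2.0 - n, (2.0 - n) / (2.0 - mu)))
    out = np.maximum(d2, 0.0)  # guard tiny negative rounding at n == mu
    return float(out) if out.ndim == 0 else out
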