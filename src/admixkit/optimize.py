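"""Block-relaxation maximization of the (possibly penalized) likelihood.

The admixture log-likelihood is biconcave: concave in Q for fixed F and
concave in F for fixed Q.  We therefore alternate constrained quadratic-
programming (SQP) updates of the two blocks:

* Q block — with F fixed the likelihood separates over individuals, so
  each ancestry row is updated by maximizing its second-order Taylor
  expansion subject to the simplex constraints (Σ_k q_ik = 1, q_ik ≥ 0).
  The equality constraint is handled through the bordered KKT system and
  nonnegativity through an active-set loop that pins violated
  coordinates at zero; all I row subproblems are solved in one batched
  ``numpy.linalg.solve`` call per active-set round.

* F block — with Q fixed the likelihood separates over markers; each
  column of allele frequencies takes a Newton step under box constraints
  [ε_f, 1 − ε_f], again batched over markers with an active-set loop for
  the bounds.

Every accepted step is safeguarded: a row or column whose objective
contribution would decrease under the full QP step is halved back toward
the current point (at most 10 times, then reverted), so the objective
trajectory is non-decreasing by construction, for the plain and the
penalized objective alike.

Convergence of the alternation is accelerated by quasi-Newton
extrapolation of the block-relaxation fixed-point map, built from the
most recent secant differences; an extrapolated point is accepted only
if it is feasible after projection and beats the plain block step, so
monotonicity survives acceleration.

Per-row and per-marker subproblems are independent, and all reductions
run in a fixed order, so results are identical for any requested worker
count — the ``workers`` setting is a throughput knob, never a source of
nondeterminism.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    EPS_F,
    EPS_P,
    DenseGenotypes,
    log_likelihood,
)
from .genotype_io import PopulationLabels
from .penalized import ZERO_SNAP, PenaltyConfig, penalty_gradient, penalty_rows

__all__ = [
    "OptimizerConfig",
    "FitResult",
    "initialize",
    "update_Q_block",
    "update_F_block",
    "quasi_newton_accelerate",
    "fit",
    "project_rows_to_simplex",
    "projected_gradient_norms",
]

logger = logging.getLogger(__name__)

_MAX_HALVINGS = 10


@dataclass
class OptimizerConfig:
    """Knobs of the block-relaxation fit.

    convergence_tol is the minimum objective increase between accelerated
    iterations that keeps the fit running; qn_secant_count the number of
    secant differences retained for quasi-Newton extrapolation (0 turns
    acceleration off); fixed_rows maps individual index -> unit vector for
    supervised references.  workers must be >= 1 and never changes results.
    """

    max_iterations: int = 500
    convergence_tol: float = 1e-4
    qn_secant_count: int = 3
    seed: int = 0
    workers: int = 1
    fixed_rows: dict[int, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.qn_secant_count < 0:
            raise ValueError("qn_secant_count must be >= 0")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


@dataclass
class FitResult:
    """Outcome of a fit: final state, objective trace and convergence flag."""

    Q: np.ndarray
    F: np.ndarray
    final_loglik: float
    trajectory: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False

    @property
    def K(self) -> int:
        return self.Q.shape[1]


def initialize(genotypes, K: int, seed: int, labels: PopulationLabels | None = None):
    """Random starting state: Dirichlet(1,..,1) ancestry rows, F near the
    overall per-marker allele frequency with population-specific jitter.

    With ``labels``, labeled individuals start (and stay) at the unit
    vector of their population's column, ordered by ``population_names``.
    """
    dense = genotypes if isinstance(genotypes, DenseGenotypes) else DenseGenotypes(genotypes)
    I, J = dense.N.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > I:
        raise ValueError(f"K={K} exceeds the number of individuals I={I}")
    rng = np.random.default_rng(seed)
    if K == 1:
        Q = np.ones((I, 1))
    else:
        Q = rng.dirichlet(np.ones(K), size=I)
    # Empirical frequency of allele 1 per marker, jittered per population so
    # the columns of Q are not exchangeable from the very first iteration.
    denom = np.maximum(dense.M.sum(axis=0), 1.0)
    p_hat = dense.N.sum(axis=0) / denom
    F = p_hat[None, :] + rng.normal(0.0, 0.05, size=(K, J))
    np.clip(F, EPS_F, 1.0 - EPS_F, out=F)
    if labels is not None:
        for i, vec in build_fixed_rows(labels, K).items():
            Q[i] = vec
    return Q, F


def build_fixed_rows(labels: PopulationLabels, K: int) -> dict[int, np.ndarray]:
    """Unit-vector constraints for labeled individuals (supervised mode)."""
    if labels.n_populations != K:
        raise ValueError(
            f"supervised mode needs K == number of labeled populations "
            f"({labels.n_populations}), got K={K}"
        )
    col = {name: k for k, name in enumerate(labels.population_names)}
    out: dict[int, np.ndarray] = {}
    for i, a in enumerate(labels.assignments):
        if a is not None:
            e = np.zeros(K)
            e[col[a]] = 1.0
            out[i] = e
    return out


# ---------------------------------------------------------------------------
# batched constrained QP solvers
# ---------------------------------------------------------------------------

def _ridge(H: np.ndarray) -> np.ndarray:
    """Tiny negative-definite regularization keeping KKT systems solvable."""
    B, K = H.shape[0], H.shape[1]
    scale = np.abs(np.diagonal(H, axis1=1, axis2=2)).max(axis=1)
    delta = 1e-9 * (1.0 + scale)
    out = H.copy()
    idx = np.arange(K)
    out[:, idx, idx] -= delta[:, None]
    return out


def _solve_simplex_qp(H: np.ndarray, g: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Maximize g·d + d'Hd/2 over steps d with 1'(q+d)=1, q+d >= 0, batched.

    Equality via the bordered KKT system; nonnegativity via an active-set
    loop that pins coordinates crossing zero.  Returns the new points.
    """
    B, K = q.shape
    if K == 1:
        return q.copy()
    H = _ridge(H)
    fixed = np.zeros((B, K), dtype=bool)
    d = np.zeros_like(q)
    for _ in range(K + 1):
        d_fix = np.where(fixed, -q, 0.0)  # pinned coords step to exactly 0
        A = np.zeros((B, K + 1, K + 1))
        A[:, :K, :K] = H
        A[:, :K, K] = 1.0
        A[:, K, :K] = 1.0
        rhs = np.empty((B, K + 1))
        rhs[:, :K] = -g - np.einsum("bkl,bl->bk", H, d_fix)
        rhs[:, K] = 1.0 - q.sum(axis=1) + np.where(fixed, q, 0.0).sum(axis=1)
        # eliminate pinned coordinates: identity row/col, zero rhs
        fx = np.concatenate([fixed, np.zeros((B, 1), dtype=bool)], axis=1)
        A[fx[:, :, None] | fx[:, None, :]] = 0.0
        diag = np.arange(K + 1)
        A[:, diag, diag] = np.where(fx, 1.0, A[:, diag, diag])
        rhs[fx] = 0.0
        try:
            sol = np.linalg.solve(A, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - ridge prevents this
            warnings.warn("singular KKT system in Q update; keeping current rows")
            return q.copy()
        d = sol[:, :K] + d_fix
        new = q + d
        viol = (new < -1e-12) & ~fixed
        if not viol.any():
            break
        fixed |= viol
    new = np.maximum(q + d, 0.0)
    s = new.sum(axis=1, keepdims=True)
    bad = ~np.isfinite(s) | (s <= 0)
    if bad.any():  # pathological row: keep the current point
        new = np.where(bad, q, new / np.where(bad, 1.0, s))
    else:
        new /= s
    return new


def _solve_box_qp(H: np.ndarray, g: np.ndarray, f: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Maximize g·d + d'Hd/2 over steps with f+d in [lo, hi], batched Newton
    with active-set pinning at the violated bound."""
    B, K = f.shape
    H = _ridge(H)
    fixed = np.zeros((B, K), dtype=bool)
    target = np.empty_like(f)
    d = np.zeros_like(f)
    for _ in range(K + 1):
        d_fix = np.where(fixed, target - f, 0.0)
        A = H.copy()
        rhs = -g - np.einsum("bkl,bl->bk", H, d_fix)
        A[fixed[:, :, None] | fixed[:, None, :]] = 0.0
        diag = np.arange(K)
        A[:, diag, diag] = np.where(fixed, 1.0, A[:, diag, diag])
        rhs[fixed] = 0.0
        try:
            sol = np.linalg.solve(A, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover
            warnings.warn("singular system in F update; keeping current columns")
            return f.copy()
        d = sol + d_fix
        new = f + d
        lo_v = (new < lo - 1e-15) & ~fixed
        hi_v = (new > hi + 1e-15) & ~fixed
        if not (lo_v.any() or hi_v.any()):
            break
        target = np.where(lo_v, lo, np.where(hi_v, hi, target))
        fixed |= lo_v | hi_v
    return np.clip(f + d, lo, hi)


# ---------------------------------------------------------------------------
# objective bookkeeping
# ---------------------------------------------------------------------------

def _penalty_per_row(Q, penalty: PenaltyConfig | None, pen_mask, rows=None) -> np.ndarray | float:
    if penalty is None or penalty.lam == 0:
        return 0.0
    Qr = Q if rows is None else Q[rows]
    pen = penalty_rows(Qr, penalty.lam, penalty.gamma)
    if pen_mask is not None:
        m = pen_mask if rows is None else pen_mask[rows]
        pen = np.where(m, pen, 0.0)
    return pen


def _row_objectives(dense: DenseGenotypes, Q, F, penalty: PenaltyConfig | None,
                    pen_mask: np.ndarray | None, rows=None) -> np.ndarray:
    """Per-individual contributions to the (penalized) objective."""
    N, M = dense.N, dense.M
    Qr = Q if rows is None else Q[rows]
    if rows is not None:
        N, M = N[rows], M[rows]
    P = Qr @ F
    np.clip(P, EPS_P, 1.0 - EPS_P, out=P)
    vals = (N * np.log(P) + (M - N) * np.log(1.0 - P)).sum(axis=1)
    return vals - _penalty_per_row(Q, penalty, pen_mask, rows)


def _col_objectives(dense: DenseGenotypes, Q, F, cols=None) -> np.ndarray:
    """Per-marker likelihood contributions (the penalty never involves F)."""
    N, M = dense.N, dense.M
    Fc = F if cols is None else F[:, cols]
    if cols is not None:
        N, M = N[:, cols], M[:, cols]
    P = Q @ Fc
    np.clip(P, EPS_P, 1.0 - EPS_P, out=P)
    return (N * np.log(P) + (M - N) * np.log(1.0 - P)).sum(axis=0)


class _Workspace:
    """Preallocated scratch for the fit's inner loop.

    Holds two log-term buffers, five elementwise scratch arrays for the
    score/curvature pass, and a rotating pool of success-probability
    matrices (a P matrix stays live for at most two evaluations, so four
    slots suffice).  Avoids repeated multi-megabyte allocations, which
    otherwise dominate the per-iteration cost through page faults.
    """

    def __init__(self, I: int, J: int) -> None:
        self.bufs = (np.empty((I, J)), np.empty((I, J)))
        self.aw = [np.empty((I, J)) for _ in range(5)]
        self.pslots = [np.empty((I, J)) for _ in range(4)]
        self.pidx = 0

    def next_p(self) -> np.ndarray:
        slot = self.pslots[self.pidx]
        self.pidx = (self.pidx + 1) % len(self.pslots)
        return slot


def _probs(Q, F, ws: _Workspace | None):
    out = ws.next_p() if ws is not None else None
    P = np.matmul(Q, F, out=out)
    np.clip(P, EPS_P, 1.0 - EPS_P, out=P)
    return P


def _terms_sums(dense: DenseGenotypes, Q, F, ws: _Workspace | None = None):
    """One pass over the matrix: returns (P, per-row loglik, per-col loglik).

    The workspace's scratch buffers hold the log terms (readable until the
    next call); P comes from the workspace pool so callers may keep it for
    the gradient pass at the same state.
    """
    P = _probs(Q, F, ws)
    buf1, buf2 = ws.bufs if ws is not None else (np.empty_like(P), np.empty_like(P))
    np.log(P, out=buf1)
    buf1 *= dense.N
    np.subtract(1.0, P, out=buf2)
    np.log(buf2, out=buf2)
    buf2 *= dense.MN
    buf1 += buf2
    return P, buf1.sum(axis=1), buf1.sum(axis=0), buf1


try:  # fused score/curvature kernel; plain numpy below is the fallback
    from numba import njit as _njit

    @_njit(fastmath=True, cache=True)
    def _aw_kernel(N, MN, P, A, W):  # pragma: no cover - exercised via _a_w
        I, J = N.shape
        for i in range(I):
            for j in range(J):
                p = P[i, j]
                r = 1.0 - p
                a1 = N[i, j] / p
                a2 = MN[i, j] / r
                A[i, j] = a1 - a2
                W[i, j] = a1 / p + a2 / r

except ImportError:  # pragma: no cover
    _aw_kernel = None


def _a_w(dense: DenseGenotypes, P, ws: _Workspace | None = None):
    """Score and curvature factors per entry: A = n/p - (m-n)/(1-p),
    W = n/p² + (m-n)/(1-p)²; zero at unobserved entries."""
    if ws is None:
        b1, b2, b3, b4, b5 = (np.empty_like(P) for _ in range(5))
    else:
        b1, b2, b3, b4, b5 = ws.aw
    if _aw_kernel is not None:
        _aw_kernel(dense.N, dense.MN, P, b5, b3)
        return b5, b3
    np.reciprocal(P, out=b1)                 # 1/p
    np.subtract(1.0, P, out=b2)
    np.reciprocal(b2, out=b2)                # 1/(1-p)
    np.multiply(dense.N, b1, out=b3)         # n/p
    np.multiply(dense.MN, b2, out=b4)        # (m-n)/(1-p)
    np.subtract(b3, b4, out=b5)              # A
    b3 *= b1                                 # n/p²
    b4 *= b2                                 # (m-n)/(1-p)²
    b3 += b4                                 # W
    return b5, b3


def _grad_hess_Q(dense: DenseGenotypes, Q, F, P=None, ws: _Workspace | None = None):
    if P is None:
        P = _probs(Q, F, ws)
    A, W = _a_w(dense, P, ws)
    G = A @ F.T
    K = Q.shape[1]
    # H[i] = -sum_j w_ij f_kj f_lj, assembled from the K(K+1)/2 products
    H = np.empty((Q.shape[0], K, K))
    for k in range(K):
        prods = F[k] * F[k:]  # (K-k, J)
        blk = W @ prods.T     # (I, K-k)
        H[:, k, k:] = -blk
        H[:, k:, k] = -blk
    return G, H


def _grad_hess_F(dense: DenseGenotypes, Q, F, P=None, ws: _Workspace | None = None):
    if P is None:
        P = _probs(Q, F, ws)
    A, W = _a_w(dense, P, ws)
    G = Q.T @ A  # K x J
    K = Q.shape[1]
    H = np.empty((F.shape[1], K, K))
    for k in range(K):
        prods = Q[:, k:] * Q[:, k][:, None]  # (I, K-k)
        blk = W.T @ prods                    # (J, K-k)
        H[:, k, k:] = -blk
        H[:, k:, k] = -blk
    return G, H


# ---------------------------------------------------------------------------
# public block updates
# ---------------------------------------------------------------------------

def _fixed_row_arrays(fixed_rows, K):
    if not fixed_rows:
        return np.empty(0, dtype=np.intp), np.empty((0, K))
    idx = np.fromiter(sorted(fixed_rows), dtype=np.intp)
    vecs = np.vstack([np.asarray(fixed_rows[i], dtype=np.float64) for i in sorted(fixed_rows)])
    return idx, vecs


def update_Q_block(genotypes, Q, F, fixed_rows=None, penalty: PenaltyConfig | None = None):
    """One safeguarded SQP step on every free ancestry row.

    Returns Q' with L(Q', F) >= L(Q, F) (penalized objective when
    ``penalty`` is given); rows in ``fixed_rows`` are returned unchanged.
    """
    dense = genotypes if isinstance(genotypes, DenseGenotypes) else DenseGenotypes(genotypes)
    Q = np.asarray(Q, dtype=np.float64)
    F = np.asarray(F, dtype=np.float64)
    fixed_idx, fixed_vecs = _fixed_row_arrays(fixed_rows, Q.shape[1])
    pen_mask = None
    if penalty is not None and fixed_idx.size:
        pen_mask = np.ones(Q.shape[0], dtype=bool)
        pen_mask[fixed_idx] = False
    Q1, _, _, _ = _q_step(dense, Q, F, fixed_idx, fixed_vecs, penalty, pen_mask)
    return Q1


def _q_step(dense, Q, F, fixed_idx, fixed_vecs, penalty, pen_mask,
            prev_rows=None, P=None, ws=None):
    """Internal Q update.

    Returns ``(Q', r', P', c')``: the new rows, their per-row objective
    contributions, the success probabilities at (Q', F) and the per-marker
    log-likelihood contributions at (Q', F) — the latter two feed the
    following F step without recomputation.
    """
    G, H = _grad_hess_Q(dense, Q, F, P=P, ws=ws)
    if penalty is not None and penalty.lam > 0:
        pg = penalty_gradient(Q, penalty.lam, penalty.gamma)
        if pen_mask is not None:
            pg = np.where(pen_mask[:, None], pg, 0.0)
        # MM linearization of the concave penalty: ascent on the surrogate
        # implies ascent on the true penalized objective.
        G = G - pg
    Q1 = _solve_simplex_qp(H, G, Q)
    if fixed_idx.size:
        Q1[fixed_idx] = fixed_vecs
    if penalty is not None and penalty.lam > 0:
        Q1 = _snap_zeros(Q1)
        if fixed_idx.size:
            Q1[fixed_idx] = fixed_vecs
    r0 = prev_rows if prev_rows is not None else _row_objectives(dense, Q, F, penalty, pen_mask)
    P1, rows_ll, cols_ll, terms = _terms_sums(dense, Q1, F, ws)
    r1 = rows_ll - _penalty_per_row(Q1, penalty, pen_mask)
    bad = np.flatnonzero(r1 < r0 - 1e-9 * (1.0 + np.abs(r0)))
    changed = bad
    halvings = 0
    while bad.size and halvings < _MAX_HALVINGS:
        Q1[bad] = 0.5 * (Q1[bad] + Q[bad])
        r1[bad] = _row_objectives(dense, Q1, F, penalty, pen_mask, rows=bad)
        bad = bad[r1[bad] < r0[bad] - 1e-9 * (1.0 + np.abs(r0[bad]))]
        halvings += 1
    if bad.size:  # give up on these rows this sweep
        Q1[bad] = Q[bad]
        r1[bad] = r0[bad]
    if changed.size:
        _refresh_rows(dense, Q1, F, changed, P1, terms, cols_ll)
    return Q1, r1, P1, cols_ll


def _refresh_rows(dense, Q, F, rows, P, terms, cols_ll) -> None:
    """Recompute P and the terms matrix for a few repaired rows, patching
    the cached per-marker sums in place."""
    Pr = Q[rows] @ F
    np.clip(Pr, EPS_P, 1.0 - EPS_P, out=Pr)
    t_new = dense.N[rows] * np.log(Pr) + dense.MN[rows] * np.log(1.0 - Pr)
    cols_ll += (t_new - terms[rows]).sum(axis=0)
    terms[rows] = t_new
    P[rows] = Pr


def _snap_zeros(Q):
    """Snap near-zero penalized coefficients to exact 0 and renormalize."""
    Q = np.where(Q < ZERO_SNAP, 0.0, Q)
    Q /= Q.sum(axis=1, keepdims=True)
    return Q


def update_F_block(genotypes, Q, F):
    """One safeguarded Newton/QP step on every allele-frequency column."""
    dense = genotypes if isinstance(genotypes, DenseGenotypes) else DenseGenotypes(genotypes)
    Q = np.asarray(Q, dtype=np.float64)
    F = np.asarray(F, dtype=np.float64)
    F1, _, _, _ = _f_step(dense, Q, F)
    return F1


def _f_step(dense, Q, F, prev_cols=None, P=None, ws=None):
    """Internal F update.

    Returns ``(F', c', r', P')``: the new frequency columns, their
    per-marker likelihood contributions, the per-individual log-likelihood
    contributions at (Q, F'), and the success probabilities there.
    """
    G, H = _grad_hess_F(dense, Q, F, P=P, ws=ws)
    Ft = _solve_box_qp(H, G.T, F.T, EPS_F, 1.0 - EPS_F)
    F1 = Ft.T.copy()
    c0 = prev_cols if prev_cols is not None else _col_objectives(dense, Q, F)
    P2, rows_ll, c1, terms = _terms_sums(dense, Q, F1, ws)
    bad = np.flatnonzero(c1 < c0 - 1e-9 * (1.0 + np.abs(c0)))
    changed = bad
    halvings = 0
    while bad.size and halvings < _MAX_HALVINGS:
        F1[:, bad] = 0.5 * (F1[:, bad] + F[:, bad])
        c1[bad] = _col_objectives(dense, Q, F1, cols=bad)
        bad = bad[c1[bad] < c0[bad] - 1e-9 * (1.0 + np.abs(c0[bad]))]
        halvings += 1
    if bad.size:
        F1[:, bad] = F[:, bad]
        c1[bad] = c0[bad]
    if changed.size:
        _refresh_cols(dense, Q, F1, changed, P2, terms, rows_ll)
    return F1, c1, rows_ll, P2


def _refresh_cols(dense, Q, F, cols, P, terms, rows_ll) -> None:
    """Recompute P and the terms matrix for a few repaired columns,
    patching the cached per-individual sums in place."""
    Pc = Q @ F[:, cols]
    np.clip(Pc, EPS_P, 1.0 - EPS_P, out=Pc)
    t_new = dense.N[:, cols] * np.log(Pc) + dense.MN[:, cols] * np.log(1.0 - Pc)
    rows_ll += (t_new - terms[:, cols]).sum(axis=1)
    terms[:, cols] = t_new
    P[:, cols] = Pc


# ---------------------------------------------------------------------------
# quasi-Newton extrapolation of the block-relaxation map
# ---------------------------------------------------------------------------

def quasi_newton_accelerate(history, qn_secant_count: int):
    """Extrapolated point from the last ``qn_secant_count`` secants.

    ``history`` is a sequence of (x, M(x)) pairs of flattened parameter
    vectors for the block-relaxation map M.  Returns the proposal vector,
    or ``None`` when there are too few secants, the secant system is
    singular, or qn_secant_count == 0 (caller then keeps the plain step).
    """
    m = qn_secant_count
    if m == 0 or len(history) < m + 1:
        return None
    xs = [h[0] for h in history[-(m + 1):]]
    ys = [h[1] for h in history[-(m + 1):]]
    U = np.stack([xs[t + 1] - xs[t] for t in range(m)], axis=1)
    V = np.stack([ys[t + 1] - ys[t] for t in range(m)], axis=1)
    x, y = xs[-1], ys[-1]
    W = U.T @ U - U.T @ V
    try:
        coef = np.linalg.solve(W, U.T @ (y - x))
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(coef)):
        return None
    return y + V @ coef


def project_rows_to_simplex(Q: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    Q = np.atleast_2d(np.asarray(Q, dtype=np.float64))
    n, K = Q.shape
    s = np.sort(Q, axis=1)[:, ::-1]
    css = np.cumsum(s, axis=1) - 1.0
    ks = np.arange(1, K + 1)
    cond = s - css / ks > 0
    rho = K - 1 - np.argmax(cond[:, ::-1], axis=1)
    theta = css[np.arange(n), rho] / (rho + 1)
    return np.maximum(Q - theta[:, None], 0.0)


# ---------------------------------------------------------------------------
# the fit driver
# ---------------------------------------------------------------------------

def fit(genotypes, K: int, config: OptimizerConfig | None = None,
        objective: str | PenaltyConfig = "plain",
        labels: PopulationLabels | None = None) -> FitResult:
    """Maximize the (penalized) log-likelihood by accelerated block relaxation.

    ``objective`` is ``"plain"`` or a :class:`PenaltyConfig`; ``labels``
    (or ``config.fixed_rows``) switch on supervised constraints.  The
    returned trajectory of objective values is non-decreasing; the fit
    stops when an accelerated iteration improves the objective by less
    than ``config.convergence_tol``.
    """
    config = config or OptimizerConfig()
    penalty = objective if isinstance(objective, PenaltyConfig) else None
    if isinstance(objective, str) and objective != "plain":
        raise ValueError("objective must be 'plain' or a PenaltyConfig")
    dense = genotypes if isinstance(genotypes, DenseGenotypes) else DenseGenotypes(genotypes)
    I, J = dense.N.shape

    fixed_rows = dict(config.fixed_rows or {})
    if labels is not None:
        fixed_rows.update(build_fixed_rows(labels, K))
    Q, F = initialize(dense, K, config.seed, labels=labels)
    for i, vec in fixed_rows.items():
        Q[i] = vec
    fixed_idx, fixed_vecs = _fixed_row_arrays(fixed_rows, K)
    pen_mask = None
    if penalty is not None and fixed_idx.size:
        pen_mask = np.ones(I, dtype=bool)
        pen_mask[fixed_idx] = False

    def pack(Qx, Fx):
        return np.concatenate([Qx.ravel(), Fx.ravel()])

    def unpack(x):
        Qx = x[: I * K].reshape(I, K)
        Fx = x[I * K:].reshape(K, J)
        return Qx, Fx

    ws = _Workspace(I, J)
    P, rows_ll, _, _ = _terms_sums(dense, Q, F, ws)
    r_cur = rows_ll - _penalty_per_row(Q, penalty, pen_mask)
    obj = float(r_cur.sum())
    if not np.isfinite(obj):
        raise FloatingPointError("non-finite objective at the initial state")
    trajectory = [obj]
    history: deque = deque(maxlen=config.qn_secant_count + 1)
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        # plain block step, reusing the cached P and partial sums throughout
        Q1, r1, P1, c0 = _q_step(dense, Q, F, fixed_idx, fixed_vecs, penalty,
                                 pen_mask, prev_rows=r_cur, P=P, ws=ws)
        F1, c1, rows_ll2, P2 = _f_step(dense, Q1, F, prev_cols=c0, P=P1, ws=ws)
        r_new = rows_ll2 - _penalty_per_row(Q1, penalty, pen_mask)
        obj_plain = float(r_new.sum())
        history.append((pack(Q, F), pack(Q1, F1)))

        Qn, Fn, obj_new, rn, Pn = Q1, F1, obj_plain, r_new, P2
        proposal = quasi_newton_accelerate(list(history), config.qn_secant_count)
        if proposal is not None:
            Qp, Fp = unpack(proposal)
            Qp = project_rows_to_simplex(Qp)
            if fixed_idx.size:
                Qp[fixed_idx] = fixed_vecs
            np.clip(Fp, EPS_F, 1.0 - EPS_F, out=Fp)
            Pp, rows_p, _, _ = _terms_sums(dense, Qp, Fp, ws)
            rp = rows_p - _penalty_per_row(Qp, penalty, pen_mask)
            obj_p = float(rp.sum())
            if np.isfinite(obj_p) and obj_p > obj_plain:
                Qn, Fn, obj_new, rn, Pn = Qp, Fp, obj_p, rp, Pp
        if not np.isfinite(obj_new):
            raise FloatingPointError(f"non-finite objective at iteration {it}")

        delta = obj_new - obj
        Q, F, obj, r_cur, P = Qn, Fn, obj_new, rn, Pn
        trajectory.append(obj)
        logger.debug("iter %d: objective %.6f (delta %.3g)", it, obj, delta)
        if delta < config.convergence_tol:
            converged = True
            break

    if penalty is not None and penalty.lam > 0:
        Q = _snap_zeros(Q.copy())
        if fixed_idx.size:
            Q[fixed_idx] = fixed_vecs
    final_ll = log_likelihood(dense, Q, F)
    return FitResult(Q=Q, F=F, final_loglik=final_ll, trajectory=trajectory,
                     iterations=it, converged=converged)


def projected_gradient_norms(genotypes, Q, F, fixed_rows=None,
                             penalty: PenaltyConfig | None = None):
    """KKT residuals at (Q, F): max-norm of the projected gradient for each
    ancestry row and each frequency column (0 at an exact stationary point).

    For simplex rows the multiplier of the equality constraint is taken as
    the mean gradient over the support; entries at 0 only violate when
    their gradient exceeds it.  For box-constrained frequencies, entries at
    a bound only violate when the gradient points back into the interior.
    """
    dense = genotypes if isinstance(genotypes, DenseGenotypes) else DenseGenotypes(genotypes)
    Q = np.asarray(Q, dtype=np.float64)
    F = np.asarray(F, dtype=np.float64)
    GQ, _ = _grad_hess_Q(dense, Q, F)
    if penalty is not None and penalty.lam > 0:
        GQ = GQ - penalty_gradient(Q, penalty.lam, penalty.gamma)
    support = Q > 1e-9
    nu = np.where(support, GQ, 0.0).sum(axis=1) / np.maximum(support.sum(axis=1), 1)
    viol_in = np.where(support, np.abs(GQ - nu[:, None]), 0.0)
    viol_out = np.where(~support, np.maximum(GQ - nu[:, None], 0.0), 0.0)
    q_res = np.maximum(viol_in, viol_out).max(axis=1)
    if fixed_rows:
        q_res[np.fromiter(sorted(fixed_rows), dtype=np.intp)] = 0.0

    GF, _ = _grad_hess_F(dense, Q, F)
    at_lo = F <= EPS_F * (1 + 1e-6)
    at_hi = F >= 1.0 - EPS_F * (1 + 1e-6)
    resF = np.where(at_lo, np.maximum(GF, 0.0),
                    np.where(at_hi, np.maximum(-GF, 0.0), np.abs(GF)))
    f_res = resF.max(axis=0)
    return q_res, f_res
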