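"""Entry-masking cross-validation for choosing K or the penalty strength.

The observed genotype cells (individual, marker pairs — not whole
individuals or whole markers) are partitioned uniformly at random into v
roughly equal folds.  Each fold in turn is masked (treated as missing),
the model is refit on the remainder, and every masked count n_ij is
predicted by its fitted dosage μ̂_ij = 2 Σ_k q̂_ik f̂_kj.  Prediction
error is the mean squared binomial deviance residual over all masked
entries of all folds; minimizing it over a grid of K (or λ) values
selects the model, ties broken toward the smaller, more parsimonious
value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    EPS_P,
    DenseGenotypes,
    MaskedGenotypes,
    squared_deviance_residual,
)
from .genotype_io import PopulationLabels
from .optimize import OptimizerConfig, fit
from .penalized import PenaltyConfig

__all__ = ["FoldAssignment", "CVResult", "make_folds", "cv_error", "select_K", "select_lambda"]

logger = logging.getLogger(__name__)


@dataclass
class FoldAssignment:
    """Balanced random partition of the observed (i, j) entries into v folds."""

    v: int
    rows: np.ndarray        # observed entry coordinates, one per entry
    cols: np.ndarray
    fold_of: np.ndarray     # fold index in 0..v-1, aligned with rows/cols
    seed: int

    def fold_entries(self, fold: int):
        sel = self.fold_of == fold
        return self.rows[sel], self.cols[sel]

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.fold_of, minlength=self.v)

    @property
    def n_entries(self) -> int:
        return self.rows.size


@dataclass
class CVResult:
    """Per-grid-value prediction errors and the minimizing value."""

    grid: list
    errors: list[float]
    selected: object = None
    failures: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.selected is None and self.errors:
            ok = [(e, g) for g, e in zip(self.grid, self.errors) if np.isfinite(e)]
            if not ok:
                raise ValueError("every grid point failed")
            best = min(e for e, _ in ok)
            # ties toward the smaller parameter value (grid is ascending)
            self.selected = next(g for e, g in ok if e == best)


def make_folds(genotypes, v: int, seed: int) -> FoldAssignment:
    """Uniformly random balanced partition of observed entries, reproducible
    from ``seed``.  Fold sizes differ by at most one entry."""
    if v < 2:
        raise ValueError("need at least v=2 folds")
    obs = genotypes.observed_mask()
    rows, cols = np.nonzero(obs)
    n = rows.size
    if v > n:
        raise ValueError(f"v={v} exceeds the {n} observed entries")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=np.int64)
    fold_of[order] = np.arange(n) % v
    return FoldAssignment(v=v, rows=rows, cols=cols, fold_of=fold_of, seed=seed)


def _fold_seed(seed: int, rows: np.ndarray, cols: np.ndarray, n_markers: int) -> int:
    """Deterministic per-fold seed below 2^31.

    Derived from the fold's content (its smallest flattened entry index)
    rather than its label, so permuting fold labels changes nothing.
    """
    anchor = int((rows.astype(np.int64) * n_markers + cols).min())
    return int(np.random.default_rng([seed, anchor]).integers(0, 2**31 - 1))


def cv_error(genotypes, K: int, folds: FoldAssignment,
             config: OptimizerConfig | None = None,
             objective: str | PenaltyConfig = "plain",
             labels: PopulationLabels | None = None) -> float:
    """Mean squared deviance residual of masked-entry predictions over all folds.

    Each fold's fit starts from a fold-specific deterministic seed derived
    from the master seed, so folds are reproducible yet uncoupled.
    """
    config = config or OptimizerConfig()
    dense = genotypes if isinstance(genotypes, DenseGenotypes) else DenseGenotypes(genotypes)
    total = 0.0
    count = 0
    for fold in range(folds.v):
        r, c = folds.fold_entries(fold)
        base = genotypes.base if isinstance(genotypes, MaskedGenotypes) else genotypes
        masked = MaskedGenotypes(base, (r, c))
        _warn_if_unidentifiable(masked, r, c)
        fold_cfg = OptimizerConfig(
            max_iterations=config.max_iterations,
            convergence_tol=config.convergence_tol,
            qn_secant_count=config.qn_secant_count,
            seed=_fold_seed(config.seed, r, c, base.n_markers),
            workers=config.workers,
            fixed_rows=config.fixed_rows,
        )
        res = fit(masked, K, config=fold_cfg, objective=objective, labels=labels)
        mu = 2.0 * np.einsum("ek,ke->e", res.Q[r], res.F[:, c])
        np.clip(mu, 2.0 * EPS_P, 2.0 - 2.0 * EPS_P, out=mu)
        n = dense.N[r, c]
        total += float(squared_deviance_residual(n, mu).sum())
        count += r.size
    return total / count


def _warn_if_unidentifiable(masked: MaskedGenotypes, r, c) -> None:
    obs = masked.observed_mask()
    if (~obs.any(axis=1))[np.unique(r)].any():
        warnings.warn("a fold masks every observed entry of some individual; "
                      "its ancestry is unidentifiable in that fold")
    if (~obs.any(axis=0))[np.unique(c)].any():
        warnings.warn("a fold masks every observed entry of some marker; "
                      "its frequencies are unidentifiable in that fold")


def select_K(genotypes, K_grid, v: int = 5,
             config: OptimizerConfig | None = None) -> CVResult:
    """Cross-validated choice of the number of ancestral populations."""
    return _select(genotypes, list(K_grid), v, config,
                   lambda K: (K, "plain"))


def select_lambda(genotypes, K: int, lambda_grid, gamma: float = 0.1,
                  v: int = 5, config: OptimizerConfig | None = None) -> CVResult:
    """Cross-validated choice of the penalty strength λ at fixed γ."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    return _select(genotypes, list(lambda_grid), v, config,
                   lambda lam: (K, PenaltyConfig(lam, gamma) if lam > 0 else "plain"))


def _select(genotypes, grid, v, config, point) -> CVResult:
    if not grid:
        raise ValueError("grid must be nonempty")
    if sorted(grid) != grid:
        raise ValueError("grid must be ascending")
    config = config or OptimizerConfig()
    folds = make_folds(genotypes, v, config.seed)
    errors: list[float] = []
    failures: dict = {}
    for g in grid:
        K, objective = point(g)
        try:
            err = cv_error(genotypes, K, folds, config=config, objective=objective)
        except Exception as exc:  # record the failed point, keep the grid going
            logger.warning("CV grid point %r failed: %s", g, exc)
            failures[g] = str(exc)
            err = np.inf
        errors.append(err)
        logger.info("CV error at %r: %s", g, err)
    return CVResult(grid=grid, errors=errors, failures=failures)
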