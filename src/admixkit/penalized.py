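"""Approximate-ℓ0 penalized estimation of ancestry fractions.

Small admixture coefficients are often estimation noise: with closely
related source populations and modest marker counts, maximum-likelihood
fits ascribe spurious admixture to essentially unadmixed individuals.
Penalizing the objective with a bounded concave approximation to the ℓ0
"norm" of each ancestry row shrinks such coefficients and drives the
smallest ones exactly to zero:

    pen(Q) = λ Σ_{i,k} ln(1 + q_ik/γ) / ln(1 + 1/γ).

The normalization by ln(1 + 1/γ) anchors the scale: a coefficient of 1
costs exactly λ, a coefficient of 0 costs nothing, so as γ → 0 the
penalty counts λ × (number of nonzero entries of Q).  λ ≥ 0 sets the
strength; smaller γ > 0 makes the penalty a sharper ℓ0 surrogate.  The
penalty applies to Q only — allele frequencies are never shrunk — and
the fitted objective is  log-likelihood − pen(Q).

Unlike a Dirichlet log-prior with concentration below 1, this penalty is
bounded on the simplex, so the penalized objective always has a finite
maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import log_likelihood

__all__ = [
    "PenaltyConfig",
    "penalty_value",
    "penalty_rows",
    "penalty_gradient",
    "penalized_objective",
]

#: Entries the optimizer has driven below this are snapped to exact zero.
ZERO_SNAP: float = 1e-10


@dataclass(frozen=True)
class PenaltyConfig:
    """Tuning constants of the approximate-ℓ0 penalty.

    lam : penalty strength λ ≥ 0 (λ = 0 recovers the plain likelihood).
    gamma : scale γ > 0 of the log barrier; the Figure-3-style default
        used throughout is γ = 0.1.
    """

    lam: float
    gamma: float = 0.1

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("penalty strength lam must be >= 0")
        if self.gamma <= 0:
            raise ValueError("penalty scale gamma must be > 0")

    @property
    def norm(self) -> float:
        """ln(1 + 1/γ), the normalizer making a unit coefficient cost λ."""
        return float(np.log1p(1.0 / self.gamma))


def penalty_rows(Q: np.ndarray, lam: float, gamma: float) -> np.ndarray:
    """Per-individual penalty contributions (length I vector)."""
    cfg = PenaltyConfig(lam, gamma)
    Q = np.atleast_2d(np.asarray(Q, dtype=np.float64))
    if lam == 0.0:
        return np.zeros(Q.shape[0])
    return cfg.lam * np.log1p(Q / cfg.gamma).sum(axis=1) / cfg.norm


def penalty_value(Q: np.ndarray, lam: float, gamma: float) -> float:
    """pen(Q) = λ Σ ln(1 + q_ik/γ) / ln(1 + 1/γ); zero iff λ = 0 for stochastic Q."""
    return float(penalty_rows(Q, lam, gamma).sum())


def penalty_gradient(Q: np.ndarray, lam: float, gamma: float) -> np.ndarray:
    """∂pen/∂q_ik = λ / (ln(1 + 1/γ) (γ + q_ik)), elementwise over Q."""
    cfg = PenaltyConfig(lam, gamma)
    Q = np.atleast_2d(np.asarray(Q, dtype=np.float64))
    if lam == 0.0:
        return np.zeros_like(Q)
    return cfg.lam / (cfg.norm * (cfg.gamma + Q))


def penalized_objective(genotypes, Q: np.ndarray, F: np.ndarray, cfg: PenaltyConfig) -> float:
    """log-likelihood minus the approximate-ℓ0 penalty on Q."""
    return log_likelihood(genotypes, Q, F) - penalty_value(Q, cfg.lam, cfg.gamma)


def penalized_update_Q_block(genotypes, Q, F, cfg: PenaltyConfig, fixed_rows=None):
    """One safeguarded penalized QP step on every free row of Q.

    Thin wrapper over the optimizer's Q-block update with the penalty
    attached; rows listed in ``fixed_rows`` (supervised references) are
    returned unchanged and excluded from the penalty.
    """
    from .optimize import update_Q_block

    return update_Q_block(genotypes, Q, F, fixed_rows=fixed_rows, penalty=cfg)
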