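"""Replicated benchmark studies on Balding-Nichols cohorts.

These drivers reproduce, at desk scale, the evaluation experiments the
simulator is designed for: repeated two-population cohorts (J = 10,000
markers, F_ST = .01, 100 reference individuals per population plus 200
grid-admixed individuals), fit unsupervised and supervised, scored by
allele-frequency RMSE and the Wright-style F_ST estimate; penalty-
strength selection by 5-fold cross-validation on a single cohort; and
the number-of-populations choice on one- and two-population stand-ins.

Every function takes a single master seed and derives all simulation and
fitting seeds from it, so whole studies are reproducible end to end.
"""

from __future__ import annotations

import logging

import numpy as np

from .crossval import select_K, select_lambda
from .optimize import OptimizerConfig, fit
from .penalized import PenaltyConfig
from .simulate import (
    SimulationDesign,
    align_populations,
    estimate_fst,
    mean_absolute_q_bias,
    reference_labels,
    rmse_frequencies,
    simulate_dataset,
)
from .supervised import supervised_fit

__all__ = ["frequency_recovery_study", "lambda_cv_study", "k_selection_study"]

logger = logging.getLogger(__name__)

#: The benchmark cohort: two closely related populations, 10,000 markers.
BENCH_DESIGN = dict(J=10_000, K=2, fst=0.01, n_ref_per_pop=100, n_admixed=200)


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def frequency_recovery_study(n_replicates: int = 10, seed: int = 0,
                             design_kw: dict | None = None,
                             config_kw: dict | None = None) -> dict:
    """Unsupervised vs supervised recovery of allele frequencies.

    For each replicate: simulate a cohort, fit both modes at K=2, resolve
    label switching by minimal frequency RMSE, and record the RMSE of the
    population-1 frequency vector, the estimated F_ST between the two
    fitted frequency vectors, and the mean absolute error of the admixed
    individuals' ancestry fractions.
    """
    dk = {**BENCH_DESIGN, **(design_kw or {})}
    ck = config_kw or {}
    seeds = _spawn_seeds(seed, 2 * n_replicates)
    out: dict[str, list] = {k: [] for k in (
        "rmse_unsup", "rmse_sup", "fst_unsup", "fst_sup",
        "qbias_unsup", "qbias_sup", "iters_unsup", "iters_sup")}
    for rep in range(n_replicates):
        design = SimulationDesign(**dk, seed=int(seeds[2 * rep]))
        genotypes, truth = simulate_dataset(design)
        labels = reference_labels(design)
        cfg = OptimizerConfig(seed=int(seeds[2 * rep + 1]), **ck)

        unsup = fit(genotypes, design.K, cfg)
        perm = align_populations(unsup.F, truth.F_true)
        out["rmse_unsup"].append(rmse_frequencies(unsup.F, truth.F_true, 0))
        out["fst_unsup"].append(estimate_fst(unsup.F[perm]))
        out["qbias_unsup"].append(mean_absolute_q_bias(unsup.Q, truth.Q_true))
        out["iters_unsup"].append(unsup.iterations)

        sup = supervised_fit(genotypes, labels, cfg)
        out["rmse_sup"].append(rmse_frequencies(sup.F, truth.F_true, 0))
        out["fst_sup"].append(estimate_fst(sup.F))
        out["qbias_sup"].append(mean_absolute_q_bias(sup.Q, truth.Q_true))
        out["iters_sup"].append(sup.iterations)
        logger.info("replicate %d: rmse %.4f/%.4f, fst %.4f/%.4f",
                    rep, out["rmse_unsup"][-1], out["rmse_sup"][-1],
                    out["fst_unsup"][-1], out["fst_sup"][-1])
    return out


def lambda_cv_study(seed: int = 0, grid=(0, 1, 2, 5, 10, 20, 50, 100),
                    gamma: float = 0.1, v: int = 5,
                    design_kw: dict | None = None,
                    config_kw: dict | None = None) -> dict:
    """Penalty-strength selection by cross-validation on one cohort.

    Runs v-fold entry-masking CV over the λ grid at fixed γ, then refits
    the full data at λ=0 and at the selected λ to compare ancestry-
    fraction bias.
    """
    dk = {**BENCH_DESIGN, **(design_kw or {})}
    ck = config_kw or {}
    s = _spawn_seeds(seed, 3)
    design = SimulationDesign(**dk, seed=int(s[0]))
    genotypes, truth = simulate_dataset(design)
    cfg = OptimizerConfig(seed=int(s[1]), **ck)
    cv = select_lambda(genotypes, design.K, list(grid), gamma=gamma, v=v, config=cfg)

    fit_cfg = OptimizerConfig(seed=int(s[2]), **ck)
    plain = fit(genotypes, design.K, fit_cfg)
    pen = fit(genotypes, design.K, fit_cfg,
              objective=PenaltyConfig(cv.selected, gamma) if cv.selected > 0 else "plain")
    return {
        "grid": list(cv.grid),
        "errors": list(cv.errors),
        "selected_lambda": cv.selected,
        "qbias_plain": mean_absolute_q_bias(plain.Q, truth.Q_true),
        "qbias_selected": mean_absolute_q_bias(pen.Q, truth.Q_true),
    }


def k_selection_study(seed: int = 0, J: int = 800, n_ref_per_pop: int = 60,
                      n_admixed: int = 60, config_kw: dict | None = None) -> dict:
    """Cross-validated K on one- and two-population synthetic stand-ins.

    A single Balding-Nichols population should select K=1; two populations
    at F_ST=.1 plus grid-admixed individuals should select K=2.
    """
    ck = config_kw or {}
    s = _spawn_seeds(seed, 4)
    one = SimulationDesign(J=J, K=1, fst=0.5, n_ref_per_pop=n_ref_per_pop,
                           n_admixed=0, seed=int(s[0]))
    g1, _ = simulate_dataset(one)
    cv1 = select_K(g1, [1, 2, 3], v=5, config=OptimizerConfig(seed=int(s[1]), **ck))

    two = SimulationDesign(J=J, K=2, fst=0.1, n_ref_per_pop=n_ref_per_pop,
                           n_admixed=n_admixed, seed=int(s[2]))
    g2, _ = simulate_dataset(two)
    cv2 = select_K(g2, [1, 2, 3], v=5, config=OptimizerConfig(seed=int(s[3]), **ck))
    return {
        "one_pop_selected": cv1.selected, "one_pop_errors": list(cv1.errors),
        "two_pop_selected": cv2.selected, "two_pop_errors": list(cv2.errors),
    }
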