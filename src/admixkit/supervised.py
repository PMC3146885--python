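"""Supervised ancestry estimation with reference individuals.

When the contributing populations are known and reference individuals
from each are available, their ancestry rows can be fixed to the unit
vector of their population, leaving only the unlabeled individuals'
ancestries and all allele frequencies to estimate.  With fewer free
parameters the allele frequencies are pinned down more precisely, which
in turn removes most of the bias toward 0.5 that unsupervised estimates
of weakly differentiated cohorts exhibit.

Supervised mode is only appropriate when references can be assigned to
fairly homogeneous ancestral populations with certainty; no automated
homogeneity check is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import PopulationLabels
from .optimize import FitResult, OptimizerConfig, build_fixed_rows, fit
from .penalized import PenaltyConfig

__all__ = ["SupervisedSpec", "build_constraints", "supervised_fit"]


@dataclass
class SupervisedSpec:
    """Labels plus the population-name → column mapping used by the fit."""

    labels: PopulationLabels

    @property
    def population_order(self) -> dict[str, int]:
        return {name: k for k, name in enumerate(self.labels.population_names)}

    @property
    def K(self) -> int:
        return self.labels.n_populations


def build_constraints(labels: PopulationLabels, K: int) -> dict[int, np.ndarray]:
    """Fixed-row constraints: labeled individual i -> unit vector of its
    population's column.  Errors unless the labels name exactly K populations."""
    return build_fixed_rows(labels, K)


def supervised_fit(genotypes, labels: PopulationLabels,
                   config: OptimizerConfig | None = None,
                   objective: str | PenaltyConfig = "plain") -> FitResult:
    """Fit with reference rows clamped to their populations' unit vectors.

    K is the number of labeled populations.  Fixed rows are bit-exact unit
    vectors in the result and are excluded from any penalty term.
    """
    K = labels.n_populations
    return fit(genotypes, K, config=config, objective=objective, labels=labels)
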