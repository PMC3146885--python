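"""Likelihood, derivatives and deviance residuals of the admixture model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admixkit.core_model import (
    MaskedGenotypes,
    block_gradients_and_hessians,
    log_likelihood,
    predicted_dosage,
    squared_deviance_residual,
    success_probability,
)
from admixkit.genotype_io import MISSING, GenotypeMatrix

from .conftest import random_genotypes


def loop_log_likelihood(counts, Q, F):
    """Scalar-loop oracle for the log-likelihood, independent of the
    vectorized implementation."""
    total = 0.0
    I, J = counts.shape
    for i in range(I):
        for j in range(J):
            n = counts[i, j]
            if n == MISSING:
                continue
            p = sum(Q[i, k] * F[k, j] for k in range(Q.shape[1]))
            total += n * math.log(p) + (2 - n) * math.log(1 - p)
    return total


def random_state(rng, I, K, J):
    Q = rng.dirichlet(np.ones(K), size=I)
    F = rng.uniform(0.05, 0.95, size=(K, J))
    return Q, F


class TestSuccessProbability:
    @pytest.mark.parametrize(
        "q, f, expected",
        [
            ([[1.0]], [[0.3]], 0.3),
            ([[0.5, 0.5]], [[0.2], [0.8]], 0.5),
            ([[0.25, 0.75]], [[0.1], [0.9]], 0.25 * 0.1 + 0.75 * 0.9),
        ],
    )
    def test_convex_combination(self, q, f, expected):
        assert success_probability(np.array(q), np.array(f), 0, 0) == pytest.approx(expected)


class TestLogLikelihood:
    def test_single_entry_analytic(self):
        g = GenotypeMatrix(np.array([[1]], dtype=np.int8), ["i"], ["m"])
        val = log_likelihood(g, np.array([[1.0]]), np.array([[0.5]]))
        assert val == pytest.approx(2 * math.log(0.5), abs=1e-12)

    def test_all_missing_gives_zero(self):
        g = GenotypeMatrix(np.full((3, 4), MISSING, dtype=np.int8),
                           list("abc"), list("wxyz"))
        Q = np.full((3, 2), 0.5)
        F = np.full((2, 4), 0.3)
        assert log_likelihood(g, Q, F) == 0.0

    @given(seed=st.integers(0, 500), I=st.integers(2, 20), J=st.integers(2, 50),
           K=st.integers(1, 4))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_scalar_loop_oracle(self, seed, I, J, K):
        rng = np.random.default_rng(seed)
        g = random_genotypes(rng, I, J, missing_frac=0.15)
        Q, F = random_state(rng, I, K, J)
        vec = log_likelihood(g, Q, F)
        ref = loop_log_likelihood(g.counts, Q, F)
        assert vec == pytest.approx(ref, rel=1e-10, abs=1e-10)

    def test_invariant_under_population_permutation(self, rng):
        g = random_genotypes(rng, 6, 9)
        Q, F = random_state(rng, 6, 3, 9)
        perm = [2, 0, 1]
        assert log_likelihood(g, Q, F) == pytest.approx(
            log_likelihood(g, Q[:, perm], F[perm]), rel=1e-12)

    def test_biconcave_along_segments(self, rng):
        # second differences of L along any line in one block are <= 0
        g = random_genotypes(rng, 6, 10)
        Q0, F = random_state(rng, 6, 3, 10)
        Q1, F1 = random_state(rng, 6, 3, 10)
        ts = np.linspace(0, 1, 9)
        for block in ("Q", "F"):
            vals = []
            for t in ts:
                if block == "Q":
                    vals.append(log_likelihood(g, (1 - t) * Q0 + t * Q1, F))
                else:
                    vals.append(log_likelihood(g, Q0, (1 - t) * F + t * F1))
            second = np.diff(vals, 2)
            assert (second <= 1e-9 * (1 + np.abs(vals).max())).all()


class TestBlockDerivatives:
    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(77)
        g = random_genotypes(rng, 4, 6, missing_frac=0.1)
        Q, F = random_state(rng, 4, 3, 6)
        h = 1e-6
        GQ, HQ = block_gradients_and_hessians(g, Q, F, "Q")
        for i in range(4):
            for k in range(3):
                Qp, Qm = Q.copy(), Q.copy()
                Qp[i, k] += h
                Qm[i, k] -= h
                fd = (log_likelihood(g, Qp, F) - log_likelihood(g, Qm, F)) / (2 * h)
                assert GQ[i, k] == pytest.approx(fd, rel=1e-5, abs=1e-5)
        GF, HF = block_gradients_and_hessians(g, Q, F, "F")
        for k in range(3):
            for j in range(6):
                Fp, Fm = F.copy(), F.copy()
                Fp[k, j] += h
                Fm[k, j] -= h
                fd = (log_likelihood(g, Q, Fp) - log_likelihood(g, Q, Fm)) / (2 * h)
                assert GF[k, j] == pytest.approx(fd, rel=1e-5, abs=1e-5)

    def test_hessians_negative_semidefinite(self, rng):
        g = random_genotypes(rng, 5, 8)
        Q, F = random_state(rng, 5, 3, 8)
        _, HQ = block_gradients_and_hessians(g, Q, F, "Q")
        _, HF = block_gradients_and_hessians(g, Q, F, "F")
        for H in (*HQ, *HF):
            assert np.linalg.eigvalsh(H).max() <= 1e-9

    def test_saturated_fit_pushes_frequencies_up(self):
        # all n=2 with f just below 1: the gradient wrt every f is positive
        counts = np.full((3, 4), 2, dtype=np.int8)
        g = GenotypeMatrix(counts, list("abc"), list("wxyz"))
        Q = np.array([[0.2, 0.8], [0.5, 0.5], [0.9, 0.1]])
        F = np.full((2, 4), 1 - 1e-6)
        GF, _ = block_gradients_and_hessians(g, Q, F, "F")
        assert (GF > 0).all()


class TestPredictedDosage:
    @pytest.mark.parametrize(
        "q, f, expected",
        [
            ([[1.0, 0.0]], [[0.5], [0.9]], 1.0),
            ([[1.0]], [[1e-6]], 2e-6),
            ([[0.3, 0.7]], [[0.2], [0.6]], 0.96),
        ],
    )
    def test_doubles_success_probability(self, q, f, expected):
        assert predicted_dosage(np.array(q), np.array(f), 0, 0) == pytest.approx(expected)


class TestDevianceResidual:
    def test_perfect_prediction_is_zero(self):
        assert squared_deviance_residual(1, 1.0) == 0.0

    def test_known_values(self):
        assert squared_deviance_residual(0, 1.0) == pytest.approx(4 * math.log(2))
        assert squared_deviance_residual(2, 0.5) == pytest.approx(4 * math.log(4))

    @pytest.mark.parametrize("mu", [0.0, 2.0, -0.1, 2.5])
    def test_domain_error(self, mu):
        with pytest.raises(ValueError):
            squared_deviance_residual(1, mu)

    @pytest.mark.parametrize("n", [0, 1, 2])
    def test_convex_and_minimized_at_n(self, n):
        mus = np.linspace(0.05, 1.95, 191)
        d2 = squared_deviance_residual(np.full_like(mus, n, dtype=float), mus)
        assert (d2 >= 0).all()
        assert (np.diff(d2, 2) >= -1e-9).all()
        if 0 < n < 2:
            assert mus[np.argmin(d2)] == pytest.approx(n, abs=0.011)
        else:
            # boundary counts: minimized at the feasible end of the grid
            assert np.argmin(d2) in (0, mus.size - 1)


class TestMaskedGenotypes:
    def test_masking_excludes_entries_from_likelihood(self, rng):
        g = random_genotypes(rng, 5, 7)
        Q, F = random_state(rng, 5, 2, 7)
        masked = MaskedGenotypes(g, [(0, 0), (2, 3), (4, 6)])
        counts = g.counts.copy()
        counts[0, 0] = counts[2, 3] = counts[4, 6] = MISSING
        assert log_likelihood(masked, Q, F) == pytest.approx(
            loop_log_likelihood(counts, Q, F), rel=1e-10)

    def test_mask_must_cover_observed_entries(self, rng):
        g = random_genotypes(rng, 3, 3)
        g.counts[1, 1] = MISSING
        with pytest.raises(ValueError):
            MaskedGenotypes(g, [(1, 1)])

    def test_observed_mask_reports_masked_as_missing(self, rng):
        g = random_genotypes(rng, 3, 3)
        masked = MaskedGenotypes(g, [(0, 1)])
        assert not masked.observed_mask()[0, 1]
        assert masked.n_masked == 1
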