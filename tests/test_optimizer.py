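"""Block-relaxation optimizer: ascent, convergence, determinism, KKT."""

import itertools

import numpy as np
import pytest

from admixkit.core_model import log_likelihood
from admixkit.genotype_io import GenotypeMatrix
from admixkit.optimize import (
    OptimizerConfig,
    fit,
    initialize,
    project_rows_to_simplex,
    projected_gradient_norms,
    quasi_newton_accelerate,
    update_F_block,
    update_Q_block,
)
from admixkit.simulate import SimulationDesign, simulate_dataset

from .conftest import random_genotypes


class TestInitialize:
    def test_k1_is_all_ones(self, small_genotypes):
        Q, _ = initialize(small_genotypes, 1, seed=0)
        np.testing.assert_array_equal(Q, 1.0)

    def test_same_seed_same_state(self, small_genotypes):
        Q1, F1 = initialize(small_genotypes, 3, seed=9)
        Q2, F2 = initialize(small_genotypes, 3, seed=9)
        np.testing.assert_array_equal(Q1, Q2)
        np.testing.assert_array_equal(F1, F2)

    def test_rows_on_simplex(self, small_genotypes):
        Q, F = initialize(small_genotypes, 3, seed=4)
        np.testing.assert_allclose(Q.sum(axis=1), 1.0, atol=1e-12)
        assert (Q >= 0).all()
        assert (F > 0).all() and (F < 1).all()

    def test_k_bounds(self, small_genotypes):
        with pytest.raises(ValueError):
            initialize(small_genotypes, 0, seed=0)
        with pytest.raises(ValueError):
            initialize(small_genotypes, 100, seed=0)


class TestBlockUpdates:
    def test_k1_q_update_is_identity(self, small_genotypes):
        Q, F = initialize(small_genotypes, 1, seed=0)
        np.testing.assert_array_equal(update_Q_block(small_genotypes, Q, F), Q)

    def test_q_update_drives_to_vertex(self):
        # one individual, two markers favouring population 1 overwhelmingly
        g = GenotypeMatrix(np.array([[2, 2]], dtype=np.int8), ["i"], ["a", "b"])
        F = np.array([[0.9, 0.9], [0.1, 0.1]])
        Q = np.array([[0.5, 0.5]])
        for _ in range(50):
            Q = update_Q_block(g, Q, F)
        # grid-search oracle over the 1-simplex
        ts = np.linspace(0, 1, 2001)
        lls = [log_likelihood(g, np.array([[t, 1 - t]]), F) for t in ts]
        t_star = ts[int(np.argmax(lls))]
        assert Q[0, 0] == pytest.approx(t_star, abs=1e-3)
        assert Q[0, 0] > 0.999

    def test_q_update_never_decreases_likelihood(self, rng):
        g = random_genotypes(rng, 10, 15, missing_frac=0.1)
        Q, F = initialize(g, 3, seed=2)
        for _ in range(5):
            Q1 = update_Q_block(g, Q, F)
            assert log_likelihood(g, Q1, F) >= log_likelihood(g, Q, F) - 1e-9
            Q = Q1

    def test_f_update_reaches_empirical_frequency_at_k1(self, rng):
        g = random_genotypes(rng, 12, 8)
        Q, F = initialize(g, 1, seed=3)
        for _ in range(30):
            F = update_F_block(g, Q, F)
        emp = g.counts.mean(axis=0) / 2
        np.testing.assert_allclose(F[0], emp, atol=1e-6)

    def test_f_update_separates_by_population(self, rng):
        # unadmixed individuals: each population converges to its own
        # empirical frequency
        counts = rng.integers(0, 3, size=(10, 6)).astype(np.int8)
        g = GenotypeMatrix(counts, [f"i{i}" for i in range(10)],
                           [f"m{j}" for j in range(6)])
        Q = np.repeat(np.eye(2), 5, axis=0)
        F = np.full((2, 6), 0.5)
        for _ in range(40):
            F = update_F_block(g, Q, F)
        np.testing.assert_allclose(F[0], counts[:5].mean(axis=0) / 2, atol=1e-6)
        np.testing.assert_allclose(F[1], counts[5:].mean(axis=0) / 2, atol=1e-6)

    def test_f_update_never_decreases_likelihood(self, rng):
        g = random_genotypes(rng, 10, 15, missing_frac=0.1)
        Q, F = initialize(g, 3, seed=5)
        for _ in range(5):
            F1 = update_F_block(g, Q, F)
            assert log_likelihood(g, Q, F1) >= log_likelihood(g, Q, F) - 1e-9
            F = F1


class TestQuasiNewton:
    def test_zero_secants_returns_none(self):
        x = np.arange(4.0)
        assert quasi_newton_accelerate([(x, x)], 0) is None

    def test_too_short_history_returns_none(self):
        x = np.arange(4.0)
        assert quasi_newton_accelerate([(x, x + 1)], 3) is None

    def test_acceleration_does_not_slow_convergence(self, rng):
        design = SimulationDesign(J=400, K=2, fst=0.1, n_ref_per_pop=20,
                                  n_admixed=20, seed=8)
        g, _ = simulate_dataset(design)
        plain = fit(g, 2, OptimizerConfig(seed=6, qn_secant_count=0))
        accel = fit(g, 2, OptimizerConfig(seed=6, qn_secant_count=3))
        assert accel.iterations <= plain.iterations
        assert accel.final_loglik >= plain.final_loglik - 1e-4

    def test_exact_on_linear_fixed_point_map(self):
        # for an affine map M(x) = Ax + b the secant extrapolation jumps
        # straight to the fixed point once enough secants are collected
        rng = np.random.default_rng(0)
        A = 0.5 * rng.random((3, 3))
        b = rng.random(3)
        x_star = np.linalg.solve(np.eye(3) - A, b)
        xs = [rng.random(3)]
        hist = []
        for _ in range(4):
            y = A @ xs[-1] + b
            hist.append((xs[-1], y))
            xs.append(y)
        prop = quasi_newton_accelerate(hist, 3)
        np.testing.assert_allclose(prop, x_star, atol=1e-8)


class TestSimplexProjection:
    def test_projects_onto_simplex(self, rng):
        Q = rng.normal(size=(50, 4))
        P = project_rows_to_simplex(Q)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert (P >= 0).all()

    def test_identity_on_feasible_points(self, rng):
        Q = rng.dirichlet(np.ones(3), size=20)
        np.testing.assert_allclose(project_rows_to_simplex(Q), Q, atol=1e-12)


class TestFit:
    def test_k1_closed_form(self, rng):
        g = random_genotypes(rng, 20, 30)
        res = fit(g, 1, OptimizerConfig(seed=1, convergence_tol=1e-8))
        np.testing.assert_allclose(res.F[0], g.counts.mean(axis=0) / 2, atol=1e-6)

    def test_recovers_well_separated_populations(self):
        design = SimulationDesign(J=2_000, K=2, fst=0.2, n_ref_per_pop=30,
                                  n_admixed=0, seed=6)
        g, truth = simulate_dataset(design)
        res = fit(g, 2, OptimizerConfig(seed=7))
        best = min(
            np.abs(res.Q[:, list(p)] - truth.Q_true).max()
            for p in itertools.permutations(range(2))
        )
        assert best < 0.05

    def test_trajectory_monotone(self, rng):
        g = random_genotypes(rng, 15, 25, missing_frac=0.1)
        res = fit(g, 3, OptimizerConfig(seed=9))
        diffs = np.diff(res.trajectory)
        assert (diffs >= -1e-8 * (1 + np.abs(res.trajectory[0]))).all()

    def test_seed_determinism_and_worker_invariance(self, rng):
        g = random_genotypes(rng, 12, 20)
        a = fit(g, 2, OptimizerConfig(seed=3, workers=1))
        b = fit(g, 2, OptimizerConfig(seed=3, workers=4))
        np.testing.assert_array_equal(a.Q, b.Q)
        np.testing.assert_array_equal(a.F, b.F)
        assert a.trajectory == b.trajectory

    def test_kkt_stationarity_at_convergence(self):
        design = SimulationDesign(J=60, K=2, fst=0.2, n_ref_per_pop=12,
                                  n_admixed=10, seed=5)
        g, _ = simulate_dataset(design)
        res = fit(g, 2, OptimizerConfig(seed=3, convergence_tol=1e-10,
                                        max_iterations=3000))
        q_res, f_res = projected_gradient_norms(g, res.Q, res.F)
        assert q_res.max() <= 1e-4
        assert f_res.max() <= 1e-4

    def test_label_switching_equivalence(self):
        design = SimulationDesign(J=2_000, K=2, fst=0.2, n_ref_per_pop=30,
                                  n_admixed=0, seed=6)
        g, _ = simulate_dataset(design)
        a = fit(g, 2, OptimizerConfig(seed=7))
        b = fit(g, 2, OptimizerConfig(seed=8))
        assert abs(a.final_loglik - b.final_loglik) < 1e-3 * (1 + abs(a.final_loglik))
        best = min(
            np.abs(a.Q - b.Q[:, list(p)]).max()
            for p in itertools.permutations(range(2))
        )
        assert best < 1e-2

    def test_invalid_objective_rejected(self, small_genotypes):
        with pytest.raises(ValueError):
            fit(small_genotypes, 2, OptimizerConfig(seed=0), objective="banana")


class TestOptimizerConfigValidation:
    @pytest.mark.parametrize(
        "kw", [dict(convergence_tol=0.0), dict(qn_secant_count=-1), dict(workers=0)]
    )
    def test_bad_settings_rejected(self, kw):
        with pytest.raises(ValueError):
            OptimizerConfig(**kw)
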