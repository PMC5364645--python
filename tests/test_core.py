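"""Unit and property tests for the pairwise partial-correlation estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from espace import (
    ExpressionMatrix,
    FitConfig,
    HubSet,
    edges_from_solution,
    fit,
    kkt_residuals,
    lambda_max,
    objective,
    pair_gram,
    pair_index,
    preprocess,
    soft_threshold,
)
from espace.core import _solve_rho, penalty_vector

from oracles import espace_fixed_omega, stacked_design


def _centered(rng, n, p):
    X = rng.standard_normal((n, p))
    return X - X.mean(axis=0)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "x, t, expected",
        [(5, 2, 3), (-1, 2, 0), (-5, 2, -3), (0, 0, 0), (2, 0, 2), (1.5, 1.5, 0)],
    )
    def test_examples(self, x, t, expected):
        assert soft_threshold(x, t) == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)

    @given(x=st.floats(-100, 100), t=st.floats(0, 100))
    @settings(max_examples=200, derandomize=True)
    def test_shrinks_toward_zero_preserving_sign(self, x, t):
        y = soft_threshold(x, t)
        assert abs(y) <= abs(x)
        assert y == 0 or np.sign(y) == np.sign(x)
        assert abs(y) == max(abs(x) - t, 0)


class TestPairGram:
    @pytest.mark.parametrize(
        "Xi, Xj, wii, wjj, cross, norm_sq",
        [
            ([1, 1], [1, 1], 1, 1, 4, 4),
            ([1, 0], [0, 1], 1, 1, 0, 2),
            ([1, 0], [0, 1], 2, 5, 0, None),
            ([1, 2], [3, 1], 1, 4, 12.5, 41.25),
        ],
    )
    def test_examples(self, Xi, Xj, wii, wjj, cross, norm_sq):
        c, ns = pair_gram(np.array(Xi, float), np.array(Xj, float), wii, wjj)
        assert c == pytest.approx(cross)
        if norm_sq is not None:
            assert ns == pytest.approx(norm_sq)

    def test_matches_explicit_stacked_vectors(self):
        """The O(n) identity must equal the naive stacked construction."""
        rng = np.random.default_rng(7)
        Xc = _centered(rng, 12, 3)
        omega = np.array([0.7, 1.9, 1.2])
        Y, A = stacked_design(Xc, omega)
        k = 0
        for i in range(2):
            for j in range(i + 1, 3):
                cross, norm_sq = pair_gram(Xc[:, i], Xc[:, j], omega[i], omega[j])
                assert cross == pytest.approx(float(Y @ A[:, k]), abs=1e-12)
                assert norm_sq == pytest.approx(float(A[:, k] @ A[:, k]), abs=1e-12)
                k += 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pair_gram(np.array([]), np.array([]), 1.0, 1.0)


class TestObjective:
    def test_zero_rho_is_weighted_loss_only(self):
        rng = np.random.default_rng(1)
        Xc = _centered(rng, 20, 4)
        X = ExpressionMatrix.from_array(Xc)
        w = np.array([1.0, 2.0, 0.5, 1.5])
        val = objective(X, np.zeros(6), np.ones(4), HubSet(), 3.0, 1.0, w)
        assert val == pytest.approx(0.5 * float(w @ (Xc**2).sum(axis=0)))

    def test_alpha_irrelevant_without_hubs(self):
        rng = np.random.default_rng(2)
        X = ExpressionMatrix.from_array(_centered(rng, 15, 3))
        rho = np.array([0.2, -0.1, 0.05])
        a = objective(X, rho, np.ones(3), HubSet(), 1.0, 1.0)
        b = objective(X, rho, np.ones(3), HubSet(), 1.0, 0.5)
        assert a == b

    def test_matches_term_by_term_summation(self):
        """Direct per-gene, per-sample evaluation of the penalized loss."""
        rng = np.random.default_rng(3)
        Xc = _centered(rng, 10, 3)
        X = ExpressionMatrix.from_array(Xc)
        rho = np.array([0.3, -0.2, 0.1])  # pairs (0,1), (0,2), (1,2)
        omega = np.array([1.5, 0.8, 1.1])
        hubs = HubSet(frozenset({0}))
        lam, alpha = 2.0, 0.6
        rho_m = {(0, 1): 0.3, (0, 2): -0.2, (1, 2): 0.1}
        loss = 0.0
        for i in range(3):
            for k in range(10):
                pred = sum(
                    rho_m[(min(i, j), max(i, j))] * np.sqrt(omega[j] / omega[i]) * Xc[k, j]
                    for j in range(3) if j != i
                )
                loss += 0.5 * (Xc[k, i] - pred) ** 2
        pen = alpha * lam * (abs(0.3) + abs(-0.2)) + lam * abs(0.1)
        assert objective(X, rho, omega, hubs, lam, alpha) == pytest.approx(loss + pen)

    def test_nonpositive_omega_rejected(self):
        X = ExpressionMatrix.from_array(_centered(np.random.default_rng(0), 5, 2))
        with pytest.raises(ValueError):
            objective(X, np.zeros(1), np.array([1.0, 0.0]), HubSet(), 1.0, 1.0)


class TestFit:
    def test_total_shrinkage_at_large_lambda(self):
        rng = np.random.default_rng(4)
        Xc = _centered(rng, 30, 5)
        X = ExpressionMatrix.from_array(Xc)
        lam = 2 * lambda_max(X)
        sol = fit(X, HubSet(), FitConfig(lam=lam))
        assert np.all(sol.rho == 0)
        np.testing.assert_allclose(sol.omega_diag, 30 / (Xc**2).sum(axis=0), rtol=1e-12)
        assert sol.converged

    def test_two_gene_closed_form_iteration(self):
        """p = 2: the estimate is the iterated single-pair soft threshold."""
        rng = np.random.default_rng(5)
        Xc = _centered(rng, 50, 2)
        X = ExpressionMatrix.from_array(Xc)
        lam = 0.1 * lambda_max(X)
        sol = fit(X, HubSet(), FitConfig(lam=lam, tol=1e-10))
        # independent scalar fixed-point iteration
        w = np.ones(2)
        for _ in range(200):
            cross, norm_sq = pair_gram(Xc[:, 0], Xc[:, 1], w[0], w[1])
            r = soft_threshold(cross, lam) / norm_sq
            resid0 = Xc[:, 0] - r * np.sqrt(w[1] / w[0]) * Xc[:, 1]
            resid1 = Xc[:, 1] - r * np.sqrt(w[0] / w[1]) * Xc[:, 0]
            w_new = np.array([50 / (resid0 @ resid0), 50 / (resid1 @ resid1)])
            if np.max(np.abs(w_new - w) / w) < 1e-12:
                break
            w = w_new
        assert sol.rho[0] == pytest.approx(r, abs=1e-6)
        assert np.allclose(sol.omega_diag, w, rtol=1e-5)

    @pytest.mark.parametrize("hubs, alpha", [(frozenset(), 1.0), (frozenset({0}), 0.5)])
    def test_fixed_omega_solution_matches_convex_solver(self, hubs, alpha):
        rng = np.random.default_rng(6)
        Xc = _centered(rng, 40, 4)
        omega = np.array([1.0, 1.4, 0.7, 1.1])
        lam = 3.0
        pen_vec = penalty_vector(4, HubSet(hubs), lam, alpha)
        iu, ju = np.triu_indices(4, 1)
        pen = np.zeros((4, 4))
        pen[iu, ju] = pen_vec
        pen[ju, iu] = pen_vec
        rho, *_ = _solve_rho(np.ascontiguousarray(Xc.T), omega, np.ones(4), pen,
                             1e-9, 1000, 200)
        ref = espace_fixed_omega(Xc, omega, set(hubs), lam, alpha)
        assert np.max(np.abs(rho[iu, ju] - ref)) < 1e-5

    def test_reduction_to_plain_estimator(self, small_dataset):
        """α = 1 with hubs and any α with no hubs give identical output."""
        net, _, Xc = small_dataset
        lam = 0.4 * lambda_max(Xc)
        sol_a = fit(Xc, net.hubs, FitConfig(lam=lam, alpha=1.0))
        sol_b = fit(Xc, HubSet(), FitConfig(lam=lam, alpha=0.5))
        sol_c = fit(Xc, HubSet(), FitConfig(lam=lam, alpha=1.0))
        assert np.max(np.abs(sol_a.rho - sol_b.rho)) == 0
        assert np.max(np.abs(sol_a.omega_diag - sol_b.omega_diag)) == 0
        assert np.max(np.abs(sol_a.rho - sol_c.rho)) == 0

    def test_monotone_descent_at_fixed_omega(self):
        """Each coordinate update can only decrease the penalized objective."""
        rng = np.random.default_rng(8)
        Xc = _centered(rng, 25, 5)
        X = ExpressionMatrix.from_array(Xc)
        omega = np.ones(5)
        hubs = HubSet(frozenset({1}))
        lam, alpha = 2.0, 0.7
        iu, ju = np.triu_indices(5, 1)
        pen_vec = penalty_vector(5, hubs, lam, alpha)
        # replay coordinate descent in pure python, tracking the objective
        rho = np.zeros(len(pen_vec))
        vals = [objective(X, rho, omega, hubs, lam, alpha)]
        for _cycle in range(3):
            for k in range(len(pen_vec)):
                i, j = iu[k], ju[k]
                resid = Xc.copy()
                rho_m = np.zeros((5, 5))
                rho_m[iu, ju] = rho
                rho_m[ju, iu] = rho
                rho_m[i, j] = rho_m[j, i] = 0.0
                for a in range(5):
                    pred = sum(rho_m[a, b] * Xc[:, b] for b in range(5) if b != a)
                    resid[:, a] = Xc[:, a] - pred
                c = float(Xc[:, j] @ resid[:, i] + Xc[:, i] @ resid[:, j])
                ns = float(Xc[:, j] @ Xc[:, j] + Xc[:, i] @ Xc[:, i])
                rho[k] = soft_threshold(c, pen_vec[k]) / ns
                vals.append(objective(X, rho, omega, hubs, lam, alpha))
        assert all(b <= a + 1e-10 for a, b in zip(vals, vals[1:]))

    def test_initialization_shrinks_less_on_hub_pairs_as_alpha_drops(self):
        """|initial hub-adjacent estimate| is non-increasing in α at fixed λ."""
        rng = np.random.default_rng(9)
        Xc = _centered(rng, 30, 4)
        lam = 1.0
        omega = np.ones(4)
        iu, ju = np.triu_indices(4, 1)
        prev = None
        for alpha in (0.2, 0.5, 0.8, 1.0):
            pen_vec = penalty_vector(4, HubSet(frozenset({0})), lam, alpha)
            init = []
            for k in range(len(pen_vec)):
                cross, ns = pair_gram(Xc[:, iu[k]], Xc[:, ju[k]], omega[iu[k]], omega[ju[k]])
                init.append(abs(soft_threshold(cross, pen_vec[k]) / ns))
            hub_adj = [k for k in range(len(pen_vec)) if 0 in (iu[k], ju[k])]
            cur = [init[k] for k in hub_adj]
            if prev is not None:
                assert all(c <= p + 1e-15 for c, p in zip(cur, prev))
            prev = cur

    def test_kkt_certificate_on_converged_fits(self, small_dataset):
        net, _, Xc = small_dataset
        for frac, alpha in ((0.8, 0.6), (0.4, 0.8), (0.2, 1.0)):
            lam = frac * lambda_max(Xc)
            cfg = FitConfig(lam=lam, alpha=alpha)
            sol = fit(Xc, net.hubs, cfg)
            if not sol.converged:
                continue
            res = kkt_residuals(Xc, sol.rho, sol.omega_diag, net.hubs, lam, alpha)
            assert res.max() <= 10 * cfg.tol

    def test_omega_loop_stabilizes_quickly(self, small_dataset):
        """On a well-conditioned instance the ω loop settles within 10 rounds."""
        net, _, Xc = small_dataset
        sol = fit(Xc, net.hubs, FitConfig(lam=0.5 * lambda_max(Xc), alpha=0.8))
        assert sol.converged
        assert sol.n_omega_iters <= 10

    def test_incremental_residuals_match_full_recomputation(self):
        rng = np.random.default_rng(10)
        Xc = _centered(rng, 20, 6)
        omega = rng.uniform(0.5, 2.0, 6)
        iu, ju = np.triu_indices(6, 1)
        pen_vec = np.full(len(iu), 1.0)
        pen = np.zeros((6, 6))
        pen[iu, ju] = pen_vec
        pen[ju, iu] = pen_vec
        rho, R, *_ = _solve_rho(np.ascontiguousarray(Xc.T), omega, np.ones(6), pen,
                                1e-8, 1000, 100)
        sw = np.sqrt(omega)
        B = rho * (sw[None, :] / sw[:, None])
        np.fill_diagonal(B, 0.0)
        R_full = Xc.T - B @ Xc.T
        assert np.max(np.abs(R - R_full)) < 1e-10

    def test_objective_value_field_consistent(self, small_dataset):
        net, _, Xc = small_dataset
        lam = 0.5 * lambda_max(Xc)
        sol = fit(Xc, net.hubs, FitConfig(lam=lam, alpha=0.7))
        recomputed = objective(Xc, sol.rho, sol.omega_diag, net.hubs, lam, 0.7)
        assert sol.objective_value == pytest.approx(recomputed, abs=1e-8)

    def test_uncentered_input_rejected(self):
        X = ExpressionMatrix.from_array(np.random.default_rng(0).standard_normal((10, 3)) + 5)
        with pytest.raises(ValueError, match="centered"):
            fit(X, HubSet(), FitConfig(lam=1.0))

    def test_lambda_zero_needs_more_samples_than_genes(self):
        rng = np.random.default_rng(11)
        X = preprocess(ExpressionMatrix.from_array(rng.standard_normal((4, 6))), scale=False)
        with pytest.raises(ValueError, match="n > p"):
            fit(X, HubSet(), FitConfig(lam=0.0))


class TestEdges:
    def test_zero_solution_gives_empty_edge_list(self):
        from espace.data import PartialCorrSolution
        sol = PartialCorrSolution(np.zeros(6), np.ones(4), 1, 1, True, 0.0)
        assert edges_from_solution(sol, ["a", "b", "c", "d"]) == []

    def test_count_and_roundtrip(self):
        from espace.data import PartialCorrSolution
        rho = np.array([0.5, 0.0, -0.3, 0.0, 0.0, 0.2])
        sol = PartialCorrSolution(rho, np.ones(4), 1, 1, True, 0.0)
        genes = ["g0", "g1", "g2", "g3"]
        edges = edges_from_solution(sol, genes, HubSet(frozenset({0})))
        assert len(edges) == 3
        # reassemble the sparse vector from the edge records
        rebuilt = np.zeros(6)
        gidx = {g: k for k, g in enumerate(genes)}
        for e in edges:
            rebuilt[pair_index(gidx[e.gene_a], gidx[e.gene_b], 4)] = e.rho
        np.testing.assert_array_equal(rebuilt, rho)
        assert [e.hub_adjacent for e in edges] == [True, True, False]


class TestWeightedLoss:
    def test_weights_shift_the_optimum(self):
        """Non-unit loss weights are honored by solver and objective alike."""
        rng = np.random.default_rng(12)
        Xc = _centered(rng, 30, 3)
        X = ExpressionMatrix.from_array(Xc)
        w = np.array([2.0, 1.0, 0.5])
        cfg = FitConfig(lam=1.0, weights=w, tol=1e-8)
        sol = fit(X, HubSet(), cfg)
        # perturbing each nonzero coordinate must not lower the objective
        base = objective(X, sol.rho, sol.omega_diag, HubSet(), 1.0, 1.0, w)
        for k in range(3):
            for d in (1e-4, -1e-4):
                pert = sol.rho.copy()
                pert[k] += d
                assert objective(X, pert, sol.omega_diag, HubSet(), 1.0, 1.0, w) >= base - 1e-9
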