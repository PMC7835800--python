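"""The co-regularized objective, its multiplicative updates and the fit loop."""

from dataclasses import replace

import numpy as np
import pytest

from conftest import make_association, make_network, random_network

from crnmf import (
    CrnmfConfig,
    LatentFactors,
    ValidationError,
    build_normalized_laplacian,
    exact_rank_instance,
    fit,
    kkt_residual,
    objective,
    path_target,
    predict,
)
from crnmf.factorization import update_B, update_F


def objective_loop_oracle(x, b, f, lap_matrix, t, alpha, beta):
    """Element-wise re-coding of the objective, no linear algebra shortcuts."""
    n, m = len(x), len(x[0])
    r = len(b[0])
    bf = [[sum(b[i][k] * f[k][j] for k in range(r)) for j in range(m)]
          for i in range(n)]
    val = 0.5 * sum((x[i][j] - bf[i][j]) ** 2 for i in range(n) for j in range(m))
    if lap_matrix is not None:
        lb = [[sum(lap_matrix[i][p] * b[p][k] for p in range(n))
               for k in range(r)] for i in range(n)]
        val += alpha * sum(b[i][k] * lb[i][k] for i in range(n) for k in range(r))
    if t is not None:
        val += 0.5 * beta * sum((bf[i][j] - t[i][j]) ** 2
                                for i in range(n) for j in range(m))
    return val


def _random_state(seed, n=6, m=4, r=2, n_genes=5):
    rng = np.random.default_rng(seed)
    x = make_association((rng.random((n, m)) < 0.4).astype(float))
    lnet = random_network(n, seed + 1, kind="lincRNA")
    lap = build_normalized_laplacian(lnet)
    z = make_association((rng.random((n_genes, n)) < 0.5).astype(float),
                         "gene", "lincRNA", row_prefix="g", col_prefix="l")
    gnet = random_network(n_genes, seed + 2, kind="gene")
    y = make_association((rng.random((n_genes, m)) < 0.5).astype(float),
                         "gene", "disease")
    target = path_target(z, gnet, y)
    return x, lap, target, (z, gnet, y)


class TestPathTarget:
    def test_two_gene_hand_expansion(self):
        # all-ones z (2 genes x 1 lincRNA) and y (2 genes x 1 disease),
        # single gene-gene edge of weight w: every path sum is 2w
        w = 0.3
        z = make_association(np.ones((2, 1)), "gene", "lincRNA",
                             row_prefix="g", col_prefix="l")
        y = make_association(np.ones((2, 1)), "gene", "disease")
        gnet = make_network([[0, w], [w, 0]])
        t = path_target(z, gnet, y)
        assert t.values[0, 0] == pytest.approx(2 * w)

    def test_zero_network_annihilates(self):
        z = make_association(np.ones((3, 2)), "gene", "lincRNA",
                             row_prefix="g", col_prefix="l")
        y = make_association(np.ones((3, 2)), "gene", "disease")
        t = path_target(z, make_network(np.zeros((3, 3))), y)
        assert np.all(t.values == 0)

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(40)
        z = make_association((rng.random((4, 3)) < 0.5).astype(float),
                             "gene", "lincRNA", row_prefix="g", col_prefix="l")
        gnet = random_network(4, 41, kind="gene")
        y = make_association((rng.random((4, 2)) < 0.5).astype(float),
                             "gene", "disease")
        t = path_target(z, gnet, y)
        for l in range(3):
            for d in range(2):
                want = sum(z.values[k, l] * gnet.weights[k, m] * y.values[m, d]
                           for k in range(4) for m in range(4))
                assert t.values[l, d] == pytest.approx(want, abs=1e-10)


class TestObjective:
    def test_exact_factorization_is_zero(self):
        b = np.array([[1.0], [2.0]])
        f = np.array([[0.5, 1.0]])
        x = make_association(b @ f)
        factors = LatentFactors(b, f)
        cfg = CrnmfConfig(r=1, alpha=0, beta=0)
        assert objective(x, factors, None, None, cfg) == 0.0

    def test_single_entry_frobenius(self):
        x = make_association([[1.0]])
        factors = LatentFactors(np.array([[1.0]]), np.array([[0.0]]))
        cfg = CrnmfConfig(r=1, alpha=0, beta=0)
        assert objective(x, factors, None, None, cfg) == pytest.approx(0.5)

    def test_matches_elementwise_loop_oracle(self):
        x, lap, target, _ = _random_state(50, n=5, m=4, r=2)
        rng = np.random.default_rng(51)
        factors = LatentFactors(rng.random((5, 2)), rng.random((2, 4)))
        cfg = CrnmfConfig(r=2, alpha=0.3, beta=0.7)
        got = objective(x, factors, lap, target, cfg)
        want = objective_loop_oracle(
            x.values.tolist(), factors.B.tolist(), factors.F.tolist(),
            lap.matrix.tolist(), target.values.tolist(), 0.3, 0.7)
        assert got == pytest.approx(want, rel=1e-12)


class TestUpdates:
    def test_fixed_point_at_exact_factorization(self):
        # at BF = X̂ with alpha = beta = 0, numerator equals denominator
        rng = np.random.default_rng(60)
        b = rng.random((6, 2)) + 0.1
        f = rng.random((2, 4)) + 0.1
        x = b @ f
        b2 = update_B(b, f, x, None, None, None, 0.0, 0.0)
        f2 = update_F(b2, f, x, None, 0.0)
        np.testing.assert_allclose(b2, b, atol=1e-9)
        np.testing.assert_allclose(f2, f, atol=1e-9)

    def test_reduces_to_lee_seung_rule(self):
        rng = np.random.default_rng(61)
        b = rng.random((6, 3)) + 0.05
        f = rng.random((3, 4)) + 0.05
        x = rng.random((6, 4))
        eps = 1e-12
        want_b = b * (x @ f.T) / (b @ (f @ f.T) + eps)
        np.testing.assert_array_equal(
            update_B(b, f, x, None, None, None, 0.0, 0.0, eps), want_b)
        want_f = f * (b.T @ x) / (b.T @ b @ f + eps)
        np.testing.assert_array_equal(
            update_F(b, f, x, None, 0.0, eps), want_f)

    @pytest.mark.parametrize("alpha,beta", [(0.0, 0.0), (0.5, 0.5), (0.0, 2.0)])
    def test_single_step_never_increases_objective(self, alpha, beta):
        x, lap, target, _ = _random_state(62, n=8, m=5, r=2)
        cfg = CrnmfConfig(r=2, alpha=alpha, beta=beta)
        rng = np.random.default_rng(63)
        b, f = rng.random((8, 2)), rng.random((2, 5))
        before = objective(x, LatentFactors(b, f), lap, target, cfg)
        b = update_B(b, f, x.values, lap.identity_part, lap.adjacency_part,
                     target.values, alpha, beta)
        f = update_F(b, f, x.values, target.values, beta)
        after = objective(x, LatentFactors(b, f), lap, target, cfg)
        assert after <= before + 1e-9

    def test_nonnegativity_preserved(self):
        x, lap, target, _ = _random_state(64, n=7, m=5, r=3)
        rng = np.random.default_rng(65)
        b, f = rng.random((7, 3)), rng.random((3, 5))
        for _ in range(20):
            b = update_B(b, f, x.values, lap.identity_part, lap.adjacency_part,
                         target.values, 1.0, 1.0)
            f = update_F(b, f, x.values, target.values, 1.0)
        assert np.all(b >= 0) and np.all(f >= 0)


class TestFit:
    def test_trajectory_monotone_and_converges(self):
        x, lap, target, _ = _random_state(70, n=10, m=6, r=2)
        res = fit(x, lap, target, CrnmfConfig(r=2, max_iter=2000, seed=4))
        diffs = np.diff(res.objective)
        assert np.all(diffs <= 1e-9)
        assert res.converged
        assert res.iterations <= 2000

    def test_zero_iteration_budget(self):
        x, lap, target, _ = _random_state(71)
        res = fit(x, lap, target, CrnmfConfig(r=2, max_iter=0))
        assert len(res.objective) == 1
        assert res.iterations == 0
        assert not res.converged

    def test_same_seed_bit_identical(self):
        x, lap, target, _ = _random_state(72)
        cfg = CrnmfConfig(r=2, max_iter=50, seed=9)
        a, b = fit(x, lap, target, cfg), fit(x, lap, target, cfg)
        np.testing.assert_array_equal(a.factors.B, b.factors.B)
        np.testing.assert_array_equal(a.factors.F, b.factors.F)
        assert a.objective == b.objective

    def test_exact_rank_recovery(self):
        x, b_true, f_true = exact_rank_instance(seed=5)
        cfg = CrnmfConfig(r=3, alpha=0, beta=0, max_iter=500, tol=1e-14, seed=5)
        res = fit(x, config=cfg)
        rel = (np.linalg.norm(x.values - res.factors.B @ res.factors.F)
               / np.linalg.norm(x.values))
        assert rel < 1e-3

    def test_missing_regularizer_inputs_rejected(self):
        x, lap, target, _ = _random_state(73)
        with pytest.raises(ValidationError):
            fit(x, None, target, CrnmfConfig(alpha=1.0, beta=0.0, r=2))
        with pytest.raises(ValidationError):
            fit(x, lap, None, CrnmfConfig(alpha=0.0, beta=1.0, r=2))

    def test_overparameterized_r_warns(self):
        x, lap, target, _ = _random_state(74, n=5, m=4)
        with pytest.warns(UserWarning, match="over-parameterized"):
            fit(x, lap, target, CrnmfConfig(r=5, max_iter=2))

    def test_kkt_residual_small_at_convergence(self):
        rng = np.random.default_rng(75)
        x = make_association(rng.random((6, 4)))
        cfg = CrnmfConfig(r=2, alpha=0, beta=0, max_iter=5000, tol=1e-15, seed=1)
        res = fit(x, config=cfg)
        res_b, res_f = kkt_residual(x, res.factors, None, None, cfg)
        assert res_b < 1e-3 and res_f < 1e-3

    def test_kkt_residual_reported_with_regularizers(self):
        x, lap, target, _ = _random_state(76, n=8, m=5, r=2)
        cfg = CrnmfConfig(r=2, alpha=0.1, beta=0.1, max_iter=3000, tol=1e-14, seed=2)
        res = fit(x, lap, target, cfg)
        res_b, res_f = kkt_residual(x, res.factors, lap, target, cfg)
        # entries decaying to zero leave a slowly vanishing residual; it must
        # still be tiny relative to the objective scale
        assert res_b < 0.05 and res_f < 0.05

    def test_alpha_zero_objective_scales_quadratically(self):
        x, lap, target, _ = _random_state(77)
        cfg = CrnmfConfig(r=2, alpha=0.0, beta=0.8)
        rng = np.random.default_rng(78)
        factors = LatentFactors(rng.random(x.shape[:1] + (2,)),
                                rng.random((2, x.shape[1])))
        base = objective(x, factors, None, target, cfg)
        c = 3.0
        x_scaled = make_association(c * x.values)
        t_scaled = make_association(c * target.values,
                                    row_kind="lincRNA", col_kind="disease")
        scaled_factors = LatentFactors(np.sqrt(c) * factors.B,
                                       np.sqrt(c) * factors.F)
        scaled = objective(x_scaled, scaled_factors, None, t_scaled, cfg)
        assert scaled == pytest.approx(c ** 2 * base, rel=1e-10)


class TestPredict:
    def test_matrix_product_with_labels(self):
        b = np.array([[1.0], [0.0]])
        f = np.array([[1.0, 0.0]])
        x = make_association([[1, 0], [0, 0]])
        factors = LatentFactors(b, f, rows=x.rows, cols=x.cols)
        scores = predict(factors)
        np.testing.assert_array_equal(scores.values, [[1, 0], [0, 0]])
        assert scores.rows.ids == x.rows.ids

    def test_clip_contract(self):
        rng = np.random.default_rng(80)
        factors = LatentFactors(rng.random((5, 2)) * 3, rng.random((2, 4)) * 3)
        scores = predict(factors)
        assert scores.values.min() >= 0 and scores.values.max() <= 1

    def test_unclipped_equals_matrix_product(self):
        rng = np.random.default_rng(81)
        b, f = rng.random((5, 2)), rng.random((2, 4))
        scores = predict(LatentFactors(b, f), clip=False)
        np.testing.assert_allclose(scores.values, b @ f, atol=1e-12)
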