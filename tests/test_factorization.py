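import numpy as np
import pytest

from dscmf import (
    AssociationMatrix,
    DscmfConfig,
    FactorPair,
    fit,
    gip_kernel,
    objective,
    predict,
    rank_candidates,
    svd_init,
    update_A,
    update_B,
)
from dscmf.factorization import row_reweights
from conftest import random_association
from oracles import objective_bruteforce, update_A_oracle


def _instance(seed, n_l=6, n_d=5, k=2):
    rng = np.random.default_rng(seed)
    Y = rng.random((n_l, n_d))
    Kl = rng.random((n_l, n_l))
    Kl = (Kl + Kl.T) / 2
    Kd = rng.random((n_d, n_d))
    Kd = (Kd + Kd.T) / 2
    A = rng.standard_normal((n_l, k))
    B = rng.standard_normal((n_d, k))
    return Y, Kl, Kd, A, B


class TestObjective:
    def test_zero_factors_leave_only_data_terms(self):
        Y, Kl, Kd, A, B = _instance(0)
        cfg = DscmfConfig(k=2, lambda_h=1.0, lambda_l=0.3, lambda_d=0.2)
        factors = FactorPair(np.zeros_like(A), np.zeros_like(B))
        expected = (
            np.linalg.norm(Y, "fro") ** 2
            + 0.3 * np.linalg.norm(Kl, "fro") ** 2
            + 0.2 * np.linalg.norm(Kd, "fro") ** 2
        )
        assert objective(Y, Kl, Kd, factors, cfg) == pytest.approx(expected)

    def test_exact_factors_with_zero_lambdas(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((6, 2))
        B = rng.standard_normal((5, 2))
        Y = A @ B.T
        cfg = DscmfConfig(k=2, lambda_h=0.0, lambda_l=0.0, lambda_d=0.0)
        val = objective(Y, None, None, FactorPair(A, B), cfg, variant="cmf")
        assert val == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("variant", ["dscmf", "cmf"])
    def test_matches_termwise_oracle(self, variant):
        for seed in range(10):
            Y, Kl, Kd, A, B = _instance(seed)
            cfg = DscmfConfig(k=2, lambda_h=0.7, lambda_l=0.05, lambda_d=0.02)
            got = objective(Y, Kl, Kd, FactorPair(A, B), cfg, variant)
            want = objective_bruteforce(Y, Kl, Kd, A, B, 0.7, 0.05, 0.02, variant)
            assert got == pytest.approx(want, rel=1e-10)

    def test_nonfinite_factors_rejected(self):
        Y, Kl, Kd, A, B = _instance(2)
        factors = FactorPair(A, B)
        factors.A = factors.A.copy()
        factors.A[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            objective(Y, Kl, Kd, factors, DscmfConfig(k=2))


class TestSvdInit:
    def test_exact_low_rank_is_reproduced(self):
        rng = np.random.default_rng(3)
        Y = rng.standard_normal((7, 2)) @ rng.standard_normal((2, 5))
        fp = svd_init(Y, 3)
        assert np.linalg.norm(Y - fp.A @ fp.B.T, "fro") < 1e-8

    def test_diagonal_top_triplet(self):
        fp = svd_init(np.diag([3.0, 1.0]), 1)
        np.testing.assert_allclose(fp.A @ fp.B.T, [[3, 0], [0, 0]], atol=1e-12)

    def test_equals_truncated_svd(self, rng):
        Y = rng.standard_normal((8, 6))
        k = 3
        fp = svd_init(Y, k)
        U, s, Vt = np.linalg.svd(Y)
        trunc = (U[:, :k] * s[:k]) @ Vt[:k]
        assert np.linalg.norm(fp.A @ fp.B.T - trunc, "fro") < 1e-8

    def test_rank_beyond_min_dimension_rejected(self, rng):
        with pytest.raises(ValueError, match="rank"):
            svd_init(rng.standard_normal((4, 3)), 4)


class TestUpdates:
    def test_unregularized_update_is_least_squares(self):
        Y, Kl, Kd, A, B = _instance(4)
        cfg = DscmfConfig(k=2, lambda_h=0.0, lambda_l=0.0, lambda_d=0.0)
        factors = FactorPair(A, B)
        A_new = update_A(Y, None, factors, cfg)
        # residual orthogonal to the column space of B (normal equations)
        assert np.linalg.norm((Y - A_new @ B.T) @ B) < 1e-8

    @pytest.mark.parametrize("mode", ["exact", "scalar"])
    def test_matches_assembled_system_oracle(self, mode):
        for seed in range(10):
            Y, Kl, Kd, A, B = _instance(seed, 8, 6, 3)
            cfg = DscmfConfig(k=3, lambda_h=0.8, lambda_l=0.05, lambda_d=0.05,
                              l21_exact=(mode == "exact"))
            factors = FactorPair(A, B)
            got = update_A(Y, Kl, factors, cfg)
            want = update_A_oracle(Y, Kl, A, B, 0.8, 0.05, factors.D1, mode)
            np.testing.assert_allclose(got, want, atol=1e-10)
            got_b = update_B(Y, Kd, factors, cfg)
            want_b = update_A_oracle(Y.T, Kd, B, A, 0.8, 0.05, factors.D2, mode)
            np.testing.assert_allclose(got_b, want_b, atol=1e-10)

    def test_fixed_point_is_invariant(self):
        # drive the A-update (with B held fixed) to its fixed point, then one
        # further application must leave A essentially unchanged
        Y, Kl, Kd, A, B = _instance(5, 8, 6, 2)
        cfg = DscmfConfig(k=2, lambda_h=0.5, lambda_l=0.0, lambda_d=0.0)
        factors = FactorPair(A, B)
        for _ in range(5000):
            factors.refresh_reweights()
            A_new = update_A(Y, None, factors, cfg)
            delta = np.abs(A_new - factors.A).max()
            factors.A = A_new
            if delta < 1e-13:
                break
        factors.refresh_reweights()
        A_next = update_A(Y, None, factors, cfg)
        assert np.abs(A_next - factors.A).max() <= 1e-10

    def test_least_squares_solution_is_exact_fixed_point(self):
        # with no regularization the stationarity system is the normal
        # equations, whose solution maps to itself
        Y, _, _, A, B = _instance(9, 8, 6, 2)
        cfg = DscmfConfig(k=2, lambda_h=0.0, lambda_l=0.0, lambda_d=0.0)
        factors = FactorPair(Y @ B @ np.linalg.inv(B.T @ B), B)
        A_next = update_A(Y, None, factors, cfg)
        assert np.abs(A_next - factors.A).max() <= 1e-10


class TestFit:
    def test_low_rank_instance_converges(self):
        rng = np.random.default_rng(6)
        Y = np.clip(rng.random((10, 8)) * (rng.random((10, 1)) > 0.5), 0, 1)
        Ya = AssociationMatrix([f"l{i}" for i in range(10)],
                               [f"d{j}" for j in range(8)], (Y > 0.5).astype(float))
        if Ya.values.sum() == 0:
            Ya.values[0, 0] = 1.0
        Kl = gip_kernel(Ya, "lncrna")
        Kd = gip_kernel(Ya, "disease")
        res = fit(Ya, Kl, Kd, DscmfConfig(k=2, tol=1e-6))
        assert res.converged and res.iterations_run <= 100

    def test_single_iteration_contract(self, small_assoc, small_kernels):
        Kl, Kd = small_kernels
        res = fit(small_assoc, Kl, Kd, DscmfConfig(k=2, max_iter=1))
        assert res.iterations_run == 1
        assert len(res.objective_trace) == 2
        assert not res.converged

    def test_objective_trace_nonincreasing_without_side_terms(self):
        # the IRLS majorization guarantees descent of the reweighted scheme;
        # it covers the residual, Tikhonov and L2,1 terms (lambda_l=lambda_d=0)
        for seed in range(8):
            rng = np.random.default_rng(seed)
            Y = random_association(rng, 12, 10, 0.3)
            res = fit(Y, None, None,
                      DscmfConfig(k=3, tol=1e-8, lambda_l=0.0, lambda_d=0.0))
            tr = np.asarray(res.objective_trace)
            rel = np.diff(tr) / np.abs(tr[:-1])
            assert rel.max() <= 1e-9

    def test_objective_trace_near_monotone_with_side_terms(self):
        # the collaborative terms make the update a fixed-point scheme rather
        # than exact minimization; drift stays far below the objective scale
        for seed in range(8):
            rng = np.random.default_rng(seed)
            Y = random_association(rng, 12, 10, 0.3)
            Kl = gip_kernel(Y, "lncrna")
            Kd = gip_kernel(Y, "disease")
            res = fit(Y, Kl, Kd, DscmfConfig(k=3, tol=1e-8))
            tr = np.asarray(res.objective_trace)
            rel = np.diff(tr) / np.abs(tr[:-1])
            assert rel.max() <= 1e-4

    def test_l21_penalty_yields_sparser_rows_than_cmf(self):
        from dscmf import PlantedModel, generate_association

        Y, _ = generate_association(PlantedModel(seed=3))
        Kl = gip_kernel(Y, "lncrna")
        Kd = gip_kernel(Y, "disease")
        cfg = DscmfConfig(k=10, lambda_h=1.0)

        def n_null_rows(res):
            return int(
                (np.linalg.norm(res.factors.A, axis=1) < 1e-3).sum()
                + (np.linalg.norm(res.factors.B, axis=1) < 1e-3).sum()
            )

        sparse = n_null_rows(fit(Y, Kl, Kd, cfg, "dscmf"))
        dense = n_null_rows(fit(Y, Kl, Kd, cfg, "cmf"))
        assert sparse > dense

    def test_noiseless_masked_recovery(self):
        rng = np.random.default_rng(0)
        truth = rng.standard_normal((40, 3)) @ rng.standard_normal((3, 30))
        M = truth.copy()
        masked = rng.choice(M.size, size=int(0.05 * M.size), replace=False)
        M.flat[masked] = 0.0
        cfg = DscmfConfig(k=3, lambda_h=1e-3, lambda_l=0.0, lambda_d=0.0,
                          tol=1e-10)
        scores = predict(fit(M, None, None, cfg).factors)
        corr = np.corrcoef(scores.flat[masked], truth.flat[masked])[0, 1]
        assert corr > 0.95


class TestPredictAndRanking:
    def test_identity_factors(self):
        fp = FactorPair(np.eye(2), np.eye(2))
        np.testing.assert_array_equal(predict(fp), np.eye(2))

    def test_scalar_product(self):
        fp = FactorPair(np.array([[2.0]]), np.array([[3.0]]))
        assert predict(fp)[0, 0] == 6.0

    def test_ranking_order_and_ties(self):
        Y = AssociationMatrix(["l1", "l2", "l3"], ["d1"], np.zeros((3, 1)))
        ranked = rank_candidates(np.array([[0.2], [0.9], [0.5]]), Y, "d1")
        assert [r[0] for r in ranked] == ["l2", "l3", "l1"]
        tied = rank_candidates(np.array([[0.5], [0.5], [0.1]]), Y, "d1")
        assert [r[0] for r in tied[:2]] == ["l1", "l2"]

    def test_top_20_of_gold_standard_scale(self, rng):
        Y = AssociationMatrix(
            [f"L{i:03d}" for i in range(115)],
            [f"D{j:03d}" for j in range(178)],
            np.zeros((115, 178)),
        )
        scores = rng.random((115, 178))
        assert len(rank_candidates(scores, Y, "D000")[:20]) == 20

    def test_exclude_known_drops_positives(self):
        Y = AssociationMatrix(["l1", "l2"], ["d1"], np.array([[1.0], [0.0]]))
        ranked = rank_candidates(np.array([[0.9], [0.1]]), Y, "d1",
                                 include_known=False)
        assert [r[0] for r in ranked] == ["l2"]

    def test_unknown_disease_rejected(self, small_assoc):
        with pytest.raises(KeyError):
            rank_candidates(np.zeros(small_assoc.shape), small_assoc, "nope")


def test_reweights_guard_against_zero_rows():
    M = np.array([[0.0, 0.0], [3.0, 4.0]])
    d = row_reweights(M, epsilon=1e-8)
    assert d[0] == pytest.approx(1 / (2e-8))
    assert d[1] == pytest.approx(0.1)
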