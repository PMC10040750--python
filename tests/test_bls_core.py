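import numpy as np
import pytest

from bladnet import bls_core as bc
from bladnet.bls_core import ValidationError


class TestRandomWeights:
    def test_seeded_and_supported(self):
        a = bc.random_feature_weights(5, 7, seed=3)
        b = bc.random_feature_weights(5, 7, seed=3)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (6, 7)  # bias row included
        assert np.all(np.abs(a) <= 1.0)

    def test_different_seeds_differ(self):
        a = bc.random_feature_weights(5, 7, seed=3)
        b = bc.random_feature_weights(5, 7, seed=4)
        assert not np.array_equal(a, b)

    def test_rejects_nonpositive_dims(self):
        with pytest.raises(ValidationError):
            bc.random_feature_weights(0, 3)


class TestSparseRefine:
    def _fixture(self, seed=0, n=20, d=5, k=4):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, d))
        W0 = bc.random_feature_weights(d, k, seed=seed + 1)
        return X, W0

    def test_zero_penalty_matches_least_squares_oracle(self):
        X, W0 = self._fixture()
        Xa = np.hstack([X, np.ones((len(X), 1))])
        W_oracle = np.linalg.solve(Xa.T @ Xa, Xa.T @ (Xa @ W0))
        W = bc.sparse_refine_weights(X, W0, lam_sae=0.0, iters=200)
        obj = bc.sae_objective(X, W, W0, 0.0)
        obj_oracle = bc.sae_objective(X, W_oracle, W0, 0.0)
        assert abs(obj - obj_oracle) < 1e-6

    def test_objective_nonincreasing(self):
        X, W0 = self._fixture(seed=5)
        objs = [
            bc.sae_objective(X, bc.sparse_refine_weights(X, W0, 0.5, iters=i), W0, 0.5)
            for i in range(0, 25, 5)
        ]
        assert all(a >= b - 1e-10 for a, b in zip(objs, objs[1:]))

    def test_zero_iters_returns_least_squares_init(self):
        X, W0 = self._fixture(seed=2)
        W = bc.sparse_refine_weights(X, W0, lam_sae=1.0, iters=0)
        Xa = np.hstack([X, np.ones((len(X), 1))])
        np.testing.assert_allclose(W, np.linalg.lstsq(Xa, Xa @ W0, rcond=None)[0], atol=1e-10)

    def test_nonfinite_input_rejected(self):
        X, W0 = self._fixture()
        X[0, 0] = np.nan
        with pytest.raises(ValidationError):
            bc.sparse_refine_weights(X, W0)

    def test_penalty_induces_sparsity(self):
        X, W0 = self._fixture(seed=7)
        dense = bc.sparse_refine_weights(X, W0, lam_sae=0.0, iters=50)
        sparse = bc.sparse_refine_weights(X, W0, lam_sae=50.0, iters=50)
        assert np.sum(sparse == 0.0) > np.sum(dense == 0.0)


class TestNodeMaps:
    def _block(self, d_in=6, nf=8, ne=5, seed=0):
        return bc.make_block(d_in, nf, ne, seed=seed)

    def test_feature_nodes_zero_input_gives_bias_response(self):
        blk = self._block()
        Z = bc.map_feature_nodes(np.zeros((3, 6)), blk)
        np.testing.assert_allclose(Z, np.tile(blk.Wf[-1], (3, 1)))

    def test_feature_nodes_shape_and_determinism(self):
        blk = self._block()
        X = np.random.default_rng(1).normal(size=(10, 6))
        Z1, Z2 = bc.map_feature_nodes(X, blk), bc.map_feature_nodes(X, blk)
        assert Z1.shape == (10, 8)
        np.testing.assert_array_equal(Z1, Z2)

    def test_enhancement_nodes_bounded_by_tanh(self):
        blk = self._block()
        rng = np.random.default_rng(2)
        H = bc.map_enhancement_nodes(rng.normal(size=(10, 8)), blk)
        assert np.all(np.abs(H) < 1.0)
        # extreme inputs saturate but never exceed the tanh range
        H_big = bc.map_enhancement_nodes(rng.normal(size=(10, 8)) * 1e6, blk)
        assert np.all(np.abs(H_big) <= 1.0)

    def test_enhancement_weights_orthonormal_vs_qr_oracle(self):
        blk = self._block(nf=8, ne=5)  # 5 columns in dimension 9: orthonormalizable
        G = blk.We.T @ blk.We
        np.testing.assert_allclose(G, np.eye(5), atol=1e-10)

    def test_enhancement_zero_features_is_activated_bias_row(self):
        blk = self._block()
        H = bc.map_enhancement_nodes(np.zeros((2, 8)), blk)
        expected = np.tanh(blk.shrink * blk.We[-1])
        np.testing.assert_allclose(H, np.tile(expected, (2, 1)))

    def test_shape_mismatch_rejected(self):
        blk = self._block()
        with pytest.raises(ValidationError):
            bc.map_feature_nodes(np.zeros((3, 4)), blk)


class TestRidgeSolve:
    def test_identity_system(self):
        sol = bc.ridge_solve(np.eye(3), np.eye(3), 0.0)
        np.testing.assert_allclose(sol.W, np.eye(3), atol=1e-12)

    def test_zero_target_gives_zero_weights(self):
        A = np.random.default_rng(0).normal(size=(10, 4))
        for lam in (0.0, 0.5):
            sol = bc.ridge_solve(A, np.zeros((10, 2)), lam)
            np.testing.assert_allclose(sol.W, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(20, 6))
        Y = rng.normal(size=(20, 3))
        lam = 0.1
        W = bc.ridge_solve(A, Y, lam).W
        W_oracle = np.linalg.solve(A.T @ A + lam * np.eye(6), A.T @ Y)
        assert np.abs(W - W_oracle).max() < 1e-8

    def test_rank_deficient_lam_zero_uses_minimum_norm(self):
        A = np.ones((5, 3))  # rank 1
        Y = np.ones((5, 1))
        sol = bc.ridge_solve(A, Y, 0.0)
        W_oracle = np.linalg.pinv(A) @ Y
        np.testing.assert_allclose(sol.W, W_oracle, atol=1e-12)

    def test_local_optimality_of_objective(self):
        rng = np.random.default_rng(3)
        A, Y, lam = rng.normal(size=(15, 5)), rng.normal(size=(15, 2)), 0.3
        W = bc.ridge_solve(A, Y, lam).W
        obj = lambda w: np.sum((A @ w - Y) ** 2) + lam * np.sum(w**2)
        base = obj(W)
        for _ in range(10):
            delta = rng.normal(size=W.shape) * 1e-4
            assert obj(W + delta) >= base

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            bc.ridge_solve(np.ones((4, 2)), np.ones((5, 1)), 0.1)


class TestPseudoInverse:
    def test_identity_and_zero(self):
        np.testing.assert_allclose(bc.pseudo_inverse(np.eye(4)), np.eye(4), atol=1e-12)
        np.testing.assert_array_equal(bc.pseudo_inverse(np.zeros((3, 2))), np.zeros((2, 3)))

    def test_matches_svd_oracle_and_mp_conditions(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(7, 4))
        Ap = bc.pseudo_inverse(A)
        # independent SVD-based construction
        U, s, Vt = np.linalg.svd(A, full_matrices=False)
        Ap_oracle = Vt.T @ np.diag(1.0 / s) @ U.T
        np.testing.assert_allclose(Ap, Ap_oracle, atol=1e-10)
        assert bc.mp_violation(A, Ap) < 1e-8


class TestIncrementalColumns:
    def _state(self, n=30, m=8, c=3, seed=0):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(n, m))
        Y = rng.normal(size=(n, c))
        return bc.build_state(A, Y), A, Y, rng

    def test_matches_batch_retrain_oracle(self):
        st, A, Y, rng = self._state()
        H = rng.normal(size=(30, 4))
        st2 = bc.incremental_add_columns(st, H, Y)
        W_batch = bc.ridge_solve(np.hstack([A, H]), Y, 0.0).W
        assert np.abs(st2.W - W_batch).max() < 1e-8
        assert bc.mp_violation(np.hstack([A, H]), st2.A_pinv) < 1e-8
        assert st2.col_spans == [(0, 8), (8, 12)]

    def test_duplicate_column_leaves_fit_unchanged(self):
        st, A, Y, _ = self._state()
        st2 = bc.incremental_add_columns(st, A[:, [2]], Y)
        np.testing.assert_allclose(st2.A @ st2.W, A @ st.W, atol=1e-8)

    def test_zero_column_gives_zero_weight_row(self):
        st, A, Y, _ = self._state()
        st2 = bc.incremental_add_columns(st, np.zeros((30, 1)), Y)
        np.testing.assert_allclose(st2.W[-1], 0.0, atol=1e-12)
        np.testing.assert_allclose(st2.A @ st2.W, A @ st.W, atol=1e-10)

    def test_residual_nonincreasing_as_columns_grow(self):
        st, A, Y, rng = self._state()
        res = [np.linalg.norm(st.A @ st.W - Y)]
        for _ in range(3):
            st = bc.incremental_add_columns(st, rng.normal(size=(30, 2)), Y)
            res.append(np.linalg.norm(st.A @ st.W - Y))
        assert all(a >= b - 1e-10 for a, b in zip(res, res[1:]))

    def test_row_mismatch_rejected(self):
        st, _, Y, _ = self._state()
        with pytest.raises(ValidationError):
            bc.incremental_add_columns(st, np.ones((29, 2)), Y)


class TestIncrementalRows:
    def _state(self, seed=0):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(30, 8))
        Y = rng.normal(size=(30, 3))
        return bc.build_state(A, Y), A, Y, rng

    def test_matches_batch_oracle(self):
        st, A, Y, rng = self._state()
        Ax, Yx = rng.normal(size=(5, 8)), rng.normal(size=(5, 3))
        st2 = bc.incremental_add_rows(st, Ax, Yx)
        W_batch = bc.ridge_solve(np.vstack([A, Ax]), np.vstack([Y, Yx]), 0.0).W
        assert np.abs(st2.W - W_batch).max() < 1e-8
        assert bc.mp_violation(np.vstack([A, Ax]), st2.A_pinv) < 1e-8

    def test_duplicated_rows_keep_old_fits(self):
        st, A, Y, _ = self._state()
        st2 = bc.incremental_add_rows(st, A[:4], Y[:4])
        W_batch = bc.ridge_solve(np.vstack([A, A[:4]]), np.vstack([Y, Y[:4]]), 0.0).W
        assert np.abs(st2.W - W_batch).max() < 1e-8
        np.testing.assert_allclose(A @ st2.W, A @ W_batch, atol=1e-8)

    def test_empty_addition_is_noop(self):
        st, _, _, _ = self._state()
        st2 = bc.incremental_add_rows(st, np.empty((0, 8)), np.empty((0, 3)))
        assert st2 is st

    def test_column_mismatch_rejected(self):
        st, _, _, _ = self._state()
        with pytest.raises(ValidationError):
            bc.incremental_add_rows(st, np.ones((2, 7)), np.ones((2, 3)))


class TestMixedSequences:
    @pytest.mark.parametrize("seed", range(5))
    def test_any_mix_of_column_and_row_additions_matches_batch(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(25, 6))
        Y = rng.normal(size=(25, 2))
        st = bc.build_state(A, Y)
        ops = rng.permutation(["cols", "rows", "cols", "rows"])
        for op in ops:
            if op == "cols":
                H = rng.normal(size=(st.n_samples, 3))
                A = np.hstack([A, H])
                st = bc.incremental_add_columns(st, H, Y)
            else:
                Ax = rng.normal(size=(4, st.n_columns))
                Yx = rng.normal(size=(4, 2))
                A = np.vstack([A, Ax])
                Y = np.vstack([Y, Yx])
                st = bc.incremental_add_rows(st, Ax, Yx)
        W_batch = bc.ridge_solve(A, Y, 0.0).W
        assert np.abs(st.W - W_batch).max() < 1e-6
        assert bc.mp_violation(A, st.A_pinv) < 1e-8
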