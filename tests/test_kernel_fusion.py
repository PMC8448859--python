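import numpy as np
import pytest
from scipy.linalg import solve

from pdsubtype import (
    FusionConfig,
    bistochastize,
    fit_weights,
    gaussian_kernel,
    mbbs_fuse,
    project_doubly_stochastic_affine,
)
from pdsubtype.kernel_fusion import ConvergenceError, SimilarityMatrix

from conftest import affine_projection_oracle, sinkhorn_oracle, two_view_cohort_kernels


class TestGaussianKernel:
    def test_identical_rows_have_unit_similarity(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [4.0, 6.0]])
        K = gaussian_kernel(X, 1.0)
        assert K.values[0, 1] == pytest.approx(1.0)

    def test_closed_form_at_sigma_sqrt2(self):
        X = np.array([[0.0], [1.0], [3.0]])
        K = gaussian_kernel(X, 1.0)
        sigma = K.bandwidth  # median of pairwise distances {1, 2, 3} = 2
        assert sigma == pytest.approx(2.0)
        d01 = 1.0
        assert K.values[0, 1] == pytest.approx(np.exp(-d01**2 / (2 * sigma**2)))

    def test_matches_elementwise_brute_force(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, 4))
        K = gaussian_kernel(X, 1.3)
        d = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        sigma = 1.3 * np.median(d[~np.eye(3, dtype=bool)])
        expected = np.exp(-(d**2) / (2 * sigma**2))
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(K.values, expected, atol=1e-12)

    def test_all_identical_rows_rejected(self):
        with pytest.raises(ValueError, match="median"):
            gaussian_kernel(np.ones((4, 2)), 1.0)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kernel(np.eye(3), 0.0)


class TestAffineProjection:
    def test_doubly_stochastic_input_is_fixed_point(self):
        S = np.full((4, 4), 0.25)
        np.testing.assert_allclose(project_doubly_stochastic_affine(S), S, atol=1e-12)

    def test_two_by_two_zero_matrix(self):
        got = project_doubly_stochastic_affine(np.zeros((2, 2)))
        np.testing.assert_allclose(got, np.full((2, 2), 0.5), atol=1e-12)

    def test_matches_generic_kkt_solver(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            A = rng.normal(size=(5, 5))
            K = (A + A.T) / 2
            got = project_doubly_stochastic_affine(K)
            np.testing.assert_allclose(got, affine_projection_oracle(K), atol=1e-8)
            np.testing.assert_allclose(got.sum(axis=0), 1.0, atol=1e-10)
            np.testing.assert_allclose(got.sum(axis=1), 1.0, atol=1e-10)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            project_doubly_stochastic_affine(np.ones((2, 3)))


class TestBistochastize:
    def test_identity_is_fixed_point_frobenius(self):
        out = bistochastize(np.eye(5), "frobenius")
        np.testing.assert_allclose(out.values, np.eye(5), atol=1e-8)

    def test_constant_matrix_kl_gives_uniform(self):
        out = bistochastize(np.full((6, 6), 3.7), "kl")
        np.testing.assert_allclose(out.values, np.full((6, 6), 1 / 6), atol=1e-8)

    @pytest.mark.parametrize("divergence", ["frobenius", "kl"])
    def test_row_and_column_sums(self, divergence):
        rng = np.random.default_rng(2)
        A = rng.uniform(0.05, 1.0, size=(6, 6))
        K = (A + A.T) / 2
        out = bistochastize(K, divergence)
        np.testing.assert_allclose(out.values.sum(axis=0), 1.0, atol=1e-8)
        np.testing.assert_allclose(out.values.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(out.values >= -1e-12)
        np.testing.assert_allclose(out.values, out.values.T, atol=1e-8)

    def test_kl_matches_independent_sinkhorn(self):
        rng = np.random.default_rng(3)
        A = rng.uniform(0.1, 1.0, size=(7, 7))
        K = (A + A.T) / 2
        out = bistochastize(K, "kl", tol=1e-12)
        np.testing.assert_allclose(out.values, sinkhorn_oracle(K), atol=1e-8)

    def test_frobenius_matches_birkhoff_projection_qp(self):
        import warnings

        from scipy.optimize import LinearConstraint, minimize

        rng = np.random.default_rng(4)
        A = rng.uniform(0.0, 1.0, size=(5, 5))
        K = (A + A.T) / 2
        got = bistochastize(K, "frobenius", tol=1e-10).values

        n = 5
        I = np.eye(n)
        Aeq = np.vstack(
            [np.kron(I, np.ones((1, n))), np.kron(np.ones((1, n)), I)]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # redundant equality rows
            res = minimize(
                lambda x: np.sum((x - K.ravel()) ** 2),
                np.full(n * n, 1.0 / n),
                jac=lambda x: 2 * (x - K.ravel()),
                bounds=[(0, None)] * (n * n),
                constraints=[LinearConstraint(Aeq, 1.0, 1.0)],
                method="trust-constr",
                options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 3000},
            )
        np.testing.assert_allclose(got, res.x.reshape(n, n), atol=1e-6)

    def test_kl_requires_positive_entries(self):
        with pytest.raises(ValueError, match="positive"):
            bistochastize(np.eye(3), "kl")

    def test_convergence_error_carries_residual(self):
        rng = np.random.default_rng(5)
        A = rng.uniform(0.1, 1.0, size=(8, 8))
        with pytest.raises(ConvergenceError) as exc:
            bistochastize((A + A.T) / 2, "kl", tol=1e-14, max_iter=2)
        assert exc.value.residual > 0


def grid_search_oracle(S, K1, K2, step=0.001):
    ws = np.arange(0.0, 1.0 + step / 2, step)
    objs = [np.sum((w * K1 + (1 - w) * K2 - S) ** 2) for w in ws]
    i = int(np.argmin(objs))
    return ws[i], objs[i]


class TestFitWeights:
    def test_exact_representation_recovers_corner(self):
        rng = np.random.default_rng(6)
        A = rng.uniform(0.1, 1, size=(6, 6))
        K1 = (A + A.T) / 2
        B = rng.uniform(0.1, 1, size=(6, 6))
        K2 = (B + B.T) / 2
        w = fit_weights(K1, [K1, K2])
        assert w[0] == pytest.approx(1.0, abs=1e-8)

    def test_identical_kernels_tie_to_uniform(self):
        K = np.full((4, 4), 0.5)
        S = np.full((4, 4), 0.25)
        np.testing.assert_allclose(fit_weights(S, [K, K.copy()]), [0.5, 0.5])

    def test_matches_fine_grid_search(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            A = rng.uniform(0, 1, size=(6, 6))
            B = rng.uniform(0, 1, size=(6, 6))
            T = rng.uniform(0, 1, size=(6, 6))
            K1, K2, S = (A + A.T) / 2, (B + B.T) / 2, (T + T.T) / 2
            w = fit_weights(S, [K1, K2])
            obj = np.sum((w[0] * K1 + w[1] * K2 - S) ** 2)
            _, grid_obj = grid_search_oracle(S, K1, K2)
            assert obj <= grid_obj + 1e-6

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            fit_weights(np.eye(3), [np.eye(3), np.eye(4)])

    def test_fewer_than_two_kernels_rejected(self):
        with pytest.raises(ValueError):
            fit_weights(np.eye(3), [np.eye(3)])


class TestMbbsFuse:
    def test_identical_kernels_fuse_to_bistochastication(self):
        rng = np.random.default_rng(8)
        A = rng.uniform(0.2, 1.0, size=(8, 8))
        K = SimilarityMatrix((A + A.T) / 2, "v1")
        K2 = SimilarityMatrix(K.values.copy(), "v2")
        result = mbbs_fuse([K, K2])
        np.testing.assert_allclose(result.weights, [0.5, 0.5])
        expected = bistochastize(K.values, "kl").values
        np.testing.assert_allclose(result.fused.values, expected, atol=1e-7)

    @pytest.mark.parametrize("divergence", ["kl", "frobenius"])
    def test_fused_matrix_contract(self, divergence):
        K_inf, K_noise, _ = two_view_cohort_kernels(seed=0, n=40)
        result = mbbs_fuse([K_inf, K_noise], FusionConfig(divergence=divergence))
        S = result.fused.values
        np.testing.assert_allclose(S.sum(axis=0), 1.0, atol=1e-8)
        np.testing.assert_allclose(S.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(S >= -1e-12)
        assert abs(result.weights.sum() - 1.0) < 1e-12
        assert np.all(result.weights >= 0)
        trace = result.objective_trace
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_informative_view_outweighs_noise(self):
        wins = 0
        for seed in range(5):
            K_inf, K_noise, _ = two_view_cohort_kernels(seed=seed)
            result = mbbs_fuse([K_inf, K_noise])
            wins += result.weights[0] > result.weights[1]
        assert wins >= 4

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError, match="patient set"):
            mbbs_fuse(
                [
                    SimilarityMatrix(np.full((3, 3), 0.5)),
                    SimilarityMatrix(np.full((4, 4), 0.5)),
                ]
            )
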