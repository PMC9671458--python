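import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from patgwas.covariance import (
    CovarianceModel,
    build_sigma_e,
    build_sigma_g_z,
    enumerate_configurations,
    masked_sigma_g,
    mvn_logpdf,
    repair_psd,
)

from conftest import mvn_logpdf_dense


class TestBuildSigmaE:
    def test_zero_overlap_is_identity_for_any_rho(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            A = rng.uniform(-0.9, 0.9, size=(4, 4))
            rho = np.clip(0.5 * (A + A.T), -0.99, 0.99)
            np.fill_diagonal(rho, 1.0)
            sigma = build_sigma_e(rho, np.array([1e4] * 4), np.diag([1e4] * 4))
            np.testing.assert_allclose(sigma, np.eye(4), atol=1e-12)

    def test_overlap_weighting_arithmetic(self):
        # n1=100, n2=400, 100 shared, rho=0.5 -> 0.5 * 100/200 = 0.25
        sigma = build_sigma_e(
            np.array([[1.0, 0.5], [0.5, 1.0]]),
            np.array([100, 400]),
            np.array([[100, 100], [100, 400]]),
        )
        assert sigma[0, 1] == pytest.approx(0.25)
        assert sigma[0, 0] == 1.0 and sigma[1, 1] == 1.0

    def test_full_overlap_equal_n_passes_rho_through(self):
        n = np.array([5000, 5000])
        sigma = build_sigma_e(
            np.array([[1.0, 0.67], [0.67, 1.0]]), n, np.full((2, 2), 5000)
        )
        assert sigma[0, 1] == pytest.approx(0.67)

    def test_indefinite_result_is_an_error(self):
        # 3 traits, full overlap, correlations 0.9/0.9/-0.9 are infeasible
        rho = np.array([[1, 0.9, 0.9], [0.9, 1, -0.9], [0.9, -0.9, 1]])
        n = np.array([1000] * 3)
        with pytest.raises(ValueError, match="positive semi-definite"):
            build_sigma_e(rho, n, np.full((3, 3), 1000))

    def test_overlap_cannot_exceed_sample_sizes(self):
        with pytest.raises(ValueError, match="exceed"):
            build_sigma_e(
                np.eye(2), np.array([100, 100]), np.full((2, 2), 500)
            )


class TestBuildSigmaGZ:
    def test_diagonal_scaling(self):
        # 25,000 x 4.9e-5 = 1.225 on the diagonal
        sg = np.array([[4.9e-5, 0.0], [0.0, 4.9e-5]])
        out = build_sigma_g_z(sg, np.array([25_000, 25_000]))
        np.testing.assert_allclose(np.diag(out), [1.225, 1.225])
        assert out[0, 1] == 0.0

    def test_zero_matrix_collapses_alternative_to_null(self):
        out = build_sigma_g_z(np.zeros((3, 3)), np.array([1e4, 2e4, 3e4]))
        np.testing.assert_array_equal(out, 0.0)

    def test_matches_outer_product_oracle(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(3, 3))
        sg = A @ A.T * 1e-6
        n = np.array([1e4, 4e4, 9e4])
        out = build_sigma_g_z(sg, n)
        oracle = np.empty((3, 3))
        for i in range(3):
            for k in range(3):
                oracle[i, k] = np.sqrt(n[i] * n[k]) * sg[i, k]
        np.testing.assert_allclose(out, oracle, rtol=1e-12)

    def test_negative_genetic_variance_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            build_sigma_g_z(np.array([[-1e-5]]), np.array([1000]))


class TestMaskedSigmaG:
    def test_all_two_trait_masks_by_hand(self):
        sg = np.array([[2.0, 1.0], [1.0, 3.0]])
        np.testing.assert_array_equal(masked_sigma_g(sg, [1, 1]), sg)
        np.testing.assert_array_equal(masked_sigma_g(sg, [0, 0]), np.zeros((2, 2)))
        np.testing.assert_array_equal(
            masked_sigma_g(sg, [1, 0]), np.array([[2.0, 0.0], [0.0, 0.0]])
        )
        np.testing.assert_array_equal(
            masked_sigma_g(sg, [0, 1]), np.array([[0.0, 0.0], [0.0, 3.0]])
        )

    def test_mask_sum_inclusion_exclusion_recovers_matrix(self):
        # summing entrywise indicators over all configs: entry (i,k) appears in
        # exactly 2^(T-2) configs for i != k and 2^(T-1) on the diagonal
        rng = np.random.default_rng(2)
        T = 4
        A = rng.normal(size=(T, T))
        sg = A @ A.T
        total = np.zeros((T, T))
        for c in enumerate_configurations(T):
            total += masked_sigma_g(sg, c.astype(float))
        expected = sg * (2 ** (T - 2)) * (1 + np.eye(T))
        np.testing.assert_allclose(total, expected, rtol=1e-10)


class TestEnumerateConfigurations:
    @pytest.mark.parametrize("T", [1, 2, 4])
    def test_covers_all_binary_vectors_exactly_once(self, T):
        configs = enumerate_configurations(T)
        assert configs.shape == (2**T, T)
        assert len({tuple(c) for c in configs}) == 2**T

    def test_guard_on_large_T(self):
        with pytest.raises(ValueError, match="guard"):
            enumerate_configurations(20)


class TestMvnLogpdf:
    def test_closed_forms(self):
        assert mvn_logpdf(np.zeros(2), np.eye(2)) == pytest.approx(
            -np.log(2 * np.pi)
        )
        assert mvn_logpdf(np.array([1.96]), np.eye(1)) == pytest.approx(
            norm.logpdf(1.96)
        )

    def test_matches_dense_inverse_oracle(self):
        rng = np.random.default_rng(3)
        for T in (2, 4, 6):
            A = rng.normal(size=(T, T))
            sigma = A @ A.T + T * np.eye(T)
            S = rng.normal(size=(5, T))
            np.testing.assert_allclose(
                mvn_logpdf(S, sigma), mvn_logpdf_dense(S, sigma), atol=1e-10
            )

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        T = 4
        A = rng.normal(size=(T, T))
        sigma = A @ A.T + T * np.eye(T)
        S = rng.normal(size=T)
        perm = rng.permutation(T)
        assert mvn_logpdf(S, sigma) == pytest.approx(
            mvn_logpdf(S[perm], sigma[np.ix_(perm, perm)]), rel=1e-10
        )


class TestRepairPsd:
    def test_tiny_negative_eigenvalue_clipped_with_warning(self):
        v = np.array([1.0, 1.0]) / np.sqrt(2)
        sigma = np.eye(2) - (1 + 1e-10) * np.outer(v, v)
        with pytest.warns(UserWarning, match="clipping"):
            out = repair_psd(sigma)
        assert np.linalg.eigvalsh(out)[0] >= 0

    def test_large_negative_eigenvalue_raises(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            repair_psd(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestCovarianceModel:
    def test_sigma_e_diagonal_forced_to_one(self, model4):
        np.testing.assert_allclose(np.diag(model4.sigma_e), 1.0)

    def test_fingerprint_tracks_sigma_e(self, model4, model1):
        assert model4.sigma_e_fingerprint() != model1.sigma_e_fingerprint()
        assert model4.sigma_e_fingerprint() == model4.sigma_e_fingerprint()

    def test_permuted_model_permutes_matrices(self, model4):
        perm = [2, 0, 3, 1]
        pm = model4.permuted(perm)
        np.testing.assert_allclose(
            pm.sigma_e, model4.sigma_e[np.ix_(perm, perm)]
        )
        np.testing.assert_allclose(
            pm.sigma_g_z, model4.sigma_g_z[np.ix_(perm, perm)]
        )
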