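"""Laplacian-kernel imputation, bicubic resizing, Gaussian smoothing and
matrix-exponential diffusion."""

import numpy as np
import pytest
from scipy.linalg import expm

from scuddo.imputation import (ImputationParams, common_dimension, diffuse,
                               gaussian_kernel_2d, gaussian_smooth,
                               impute_ensemble, impute_map,
                               neumann_laplacian_kernel,
                               regularized_laplacian_kernel,
                               symmetrize_resize)

from conftest import make_ensemble


def series_kernel_oracle(A, terms=200):
    """Independent oracle: the kernel as 1/2 * sum_k (P/2)^k, summed term by
    term from the definition of P."""
    A = np.asarray(A, float)
    Areg = A + np.eye(len(A))
    P = Areg / Areg.sum(axis=1, keepdims=True)
    acc = np.zeros_like(P)
    term = np.eye(len(A))
    for _ in range(terms):
        acc += term
        term = term @ (P / 2)
    return acc / 2


class TestLaplacianKernel:
    def test_scalar_map(self):
        assert regularized_laplacian_kernel(np.array([[0]])) == \
            pytest.approx(np.array([[1.0]]))

    def test_two_bin_exchange(self):
        K = regularized_laplacian_kernel(np.array([[0, 1], [1, 0]]))
        np.testing.assert_allclose(K, [[0.75, 0.25], [0.25, 0.75]],
                                   atol=1e-14)

    def test_rows_sum_to_one_and_match_series(self, random_symmetric_counts):
        A = random_symmetric_counts(8)
        K = regularized_laplacian_kernel(A)
        np.testing.assert_allclose(K.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(K, series_kernel_oracle(A), atol=1e-12)
        assert (K >= -1e-14).all()

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            regularized_laplacian_kernel(np.zeros((2, 3)))


class TestNeumannKernel:
    def test_order_zero_is_half_identity(self):
        K = neumann_laplacian_kernel(np.array([[0, 2], [2, 0]]), order=0)
        np.testing.assert_allclose(K, 0.5 * np.eye(2))

    def test_high_order_matches_exact(self, random_symmetric_counts):
        A = random_symmetric_counts(6)
        exact = regularized_laplacian_kernel(A)
        approx = neumann_laplacian_kernel(A, order=50)
        assert np.linalg.norm(exact - approx) < 1e-10

    def test_error_monotone_in_order(self, random_symmetric_counts):
        A = random_symmetric_counts(6)
        exact = regularized_laplacian_kernel(A)
        errs = [np.linalg.norm(exact - neumann_laplacian_kernel(A, k))
                for k in range(12)]
        assert all(e2 <= e1 + 1e-15 for e1, e2 in zip(errs, errs[1:]))


def bicubic_oracle(M, r, a=-0.5):
    """Direct dense evaluation of cubic-convolution resampling with
    clamp-to-edge taps and half-pixel-centered grids."""
    def w(x):
        x = abs(x)
        if x <= 1:
            return (a + 2) * x ** 3 - (a + 3) * x ** 2 + 1
        if x < 2:
            return a * (x ** 3 - 5 * x ** 2 + 8 * x - 4)
        return 0.0

    n = M.shape[0]
    out = np.zeros((r, r))
    scale = n / r
    for oi in range(r):
        for oj in range(r):
            x = (oi + 0.5) * scale - 0.5
            y = (oj + 0.5) * scale - 0.5
            acc = norm = 0.0
            for di in range(int(np.floor(x)) - 1, int(np.floor(x)) + 3):
                for dj in range(int(np.floor(y)) - 1, int(np.floor(y)) + 3):
                    wt = w(x - di) * w(y - dj)
                    acc += wt * M[min(max(di, 0), n - 1),
                                  min(max(dj, 0), n - 1)]
                    norm += wt
            out[oi, oj] = acc / norm
    return out


class TestSymmetrizeResize:
    def test_same_dimension_is_identity(self, rng):
        M = rng.normal(size=(6, 6))
        S = 0.5 * (M + M.T)
        np.testing.assert_allclose(symmetrize_resize(M, 6), S, atol=1e-9)

    @pytest.mark.parametrize("r", [3, 5, 9])
    def test_constant_matrix_reproduced(self, r):
        M = np.full((7, 7), 3.25)
        np.testing.assert_allclose(symmetrize_resize(M, r), 3.25, atol=1e-12)

    @pytest.mark.parametrize("r", [2, 3, 6])
    def test_matches_dense_oracle(self, rng, r):
        M = rng.normal(size=(4, 4))
        M = 0.5 * (M + M.T)
        expected = bicubic_oracle(M, r)
        expected = 0.5 * (expected + expected.T)
        np.testing.assert_allclose(symmetrize_resize(M, r), expected,
                                   atol=1e-10)

    def test_rejects_degenerate_target(self):
        with pytest.raises(ValueError):
            symmetrize_resize(np.eye(4), 1)


class TestGaussianSmooth:
    def test_kernel_weights_sigma_half(self):
        G = gaussian_kernel_2d(3, 0.5)
        assert G.sum() == pytest.approx(1.0, abs=1e-12)
        assert G[1, 1] == pytest.approx(0.6193, abs=2e-4)
        assert G[0, 1] == pytest.approx(0.0838, abs=2e-4)
        assert G[0, 0] == pytest.approx(0.0113, abs=2e-4)

    def test_constant_is_fixed_point(self):
        M = np.full((5, 5), 2.5)
        np.testing.assert_allclose(gaussian_smooth(M), 2.5, atol=1e-12)

    def test_corner_impulse_against_padded_oracle(self):
        M = np.zeros((5, 5))
        M[0, 0] = 1.0
        G = gaussian_kernel_2d(3, 0.5)
        padded = np.pad(M, 1, mode="edge")
        expected = np.zeros_like(M)
        for i in range(5):
            for j in range(5):
                expected[i, j] = (padded[i:i + 3, j:j + 3] * G[::-1, ::-1]).sum()
        np.testing.assert_allclose(gaussian_smooth(M), expected, atol=1e-12)
        # replicate padding re-weights the corner: total mass exceeds 1
        assert gaussian_smooth(M).sum() == pytest.approx(expected.sum())

    def test_symmetric_in_symmetric_out_and_range(self, rng):
        M = rng.normal(size=(7, 7))
        M = 0.5 * (M + M.T)
        out = gaussian_smooth(M)
        np.testing.assert_allclose(out, out.T, atol=1e-12)
        assert out.min() >= M.min() - 1e-12
        assert out.max() <= M.max() + 1e-12


class TestDiffuse:
    def test_zero_map_gives_identity(self):
        np.testing.assert_array_equal(diffuse(np.zeros((4, 4))), np.eye(4))

    def test_antidiagonal_closed_form(self):
        # expm(-M/2) for M = [[0,1],[1,0]]: cosh/sinh at 1/2
        B = diffuse(np.array([[0.0, 1.0], [1.0, 0.0]]))
        c, s = np.cosh(0.5), np.sinh(0.5)
        np.testing.assert_allclose(B, [[c, -s], [-s, c]], atol=1e-12)

    def test_taylor_matches_exact(self, rng):
        M = rng.random((10, 10))
        M = 0.5 * (M + M.T)
        exact = diffuse(M)
        fast = diffuse(M, ImputationParams(fast_mode=True, taylor_order=20))
        assert np.abs(exact - fast).max() < 1e-12
        np.testing.assert_allclose(exact, expm(-M / M.sum()), atol=1e-12)


class TestEnsembleDriver:
    def test_single_map_composes_stages(self, random_symmetric_counts):
        A = random_symmetric_counts(8, 5)
        ens = make_ensemble({("c0", "chr1"): A, ("c1", "chr1"): A})
        params = ImputationParams()
        out = impute_ensemble(ens, params)
        assert common_dimension(ens) == 8
        expected = diffuse(gaussian_smooth(symmetrize_resize(
            regularized_laplacian_kernel(A), 8), params), params)
        np.testing.assert_array_equal(out[("c0", "chr1")].matrix, expected)

    def test_all_dimensions_equal_r(self, small_ensemble):
        out = impute_ensemble(small_ensemble)
        r = common_dimension(small_ensemble)
        assert r == 7  # round((8 + 6) / 2)
        assert {m.r for m in out.values()} == {r}

    def test_zero_map_path_does_not_crash(self):
        zero = np.zeros((6, 6), dtype=np.int64)
        dense = np.ones((6, 6), dtype=np.int64)
        ens = make_ensemble({("c0", "chr1"): zero, ("c1", "chr1"): dense})
        out = impute_ensemble(ens)
        assert np.isfinite(out[("c0", "chr1")].matrix).all()

    def test_imputed_maps_symmetric(self, small_ensemble):
        out = impute_ensemble(small_ensemble)
        for m in out.values():
            np.testing.assert_allclose(m.matrix, m.matrix.T, atol=1e-10)

    def test_perturbation_continuity(self, random_symmetric_counts):
        A = random_symmetric_counts(50, 4)
        B1 = impute_map(A, 50, ImputationParams())
        A2 = A.copy()
        A2[3, 7] += 1
        A2[7, 3] += 1
        B2 = impute_map(A2, 50, ImputationParams())
        assert 0 < np.linalg.norm(B1 - B2) < 1.0
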