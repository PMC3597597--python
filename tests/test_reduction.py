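"""Regularized canonical variates and dimension reduction."""

import numpy as np
import pytest

from gsaa import (
    PairedGeneSetData,
    reduce_pair,
    regularized_cancor,
    select_lambdas,
    standardize_columns,
)


def _pair(rng, n, p, q):
    return PairedGeneSetData(rng.normal(size=(n, p)), rng.normal(size=(n, q)),
                             [f"s{i}" for i in range(n)])


class TestStandardize:
    def test_basic_column(self):
        out = standardize_columns(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out[:, 0], [-1, 0, 1])

    def test_idempotent(self, rng):
        M = standardize_columns(rng.normal(size=(10, 3)))
        np.testing.assert_allclose(standardize_columns(M), M, atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            standardize_columns(np.array([[1.0, 2.0], [1.0, 3.0]]))


def _grid_oracle_first_corr(X, Y, lx, ly, n_angles=2000):
    """Brute-force maximum of the regularized correlation over unit coefs.

    For p = q = 2 the coefficient vectors are parameterized by angles; the
    objective is a' Sxy b / sqrt(a'(Sxx+lx I)a * b'(Syy+ly I)b).
    """
    n = X.shape[0]
    Xc, Yc = X - X.mean(0), Y - Y.mean(0)
    Sxx = Xc.T @ Xc / (n - 1) + lx * np.eye(2)
    Syy = Yc.T @ Yc / (n - 1) + ly * np.eye(2)
    Sxy = Xc.T @ Yc / (n - 1)
    th = np.linspace(0, np.pi, n_angles, endpoint=False)
    A = np.stack([np.cos(th), np.sin(th)])  # 2 x n_angles
    num = np.abs(A.T @ Sxy @ A)  # angles_a x angles_b
    da = np.sqrt(np.einsum("ij,jk,ki->i", A.T, Sxx, A))
    db = np.sqrt(np.einsum("ij,jk,ki->i", A.T, Syy, A))
    return (num / np.outer(da, db)).max()


class TestRegularizedCancor:
    def test_self_correlation_is_one(self, rng):
        X = standardize_columns(rng.normal(size=(20, 3)))
        cv = regularized_cancor(X, X.copy())
        assert cv.correlations[0] == pytest.approx(1.0, abs=1e-8)

    def test_univariate_collapses_to_pearson(self, rng):
        x = rng.normal(size=(30, 1))
        y = 0.6 * x + rng.normal(size=(30, 1))
        cv = regularized_cancor(x, y)
        r = abs(np.corrcoef(x[:, 0], y[:, 0])[0, 1])
        assert cv.correlations[0] == pytest.approx(r, abs=1e-10)

    def test_matches_grid_search_oracle_on_small_instance(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(4, 2))
        Y = rng.normal(size=(4, 2))
        cv = regularized_cancor(X, Y, 0.1, 0.1)
        oracle = _grid_oracle_first_corr(X, Y, 0.1, 0.1)
        assert cv.correlations[0] == pytest.approx(oracle, abs=5e-4)

    def test_correlations_bounded_and_decreasing(self, rng):
        for _ in range(20):
            X = rng.normal(size=(15, 4))
            Y = rng.normal(size=(15, 3))
            cv = regularized_cancor(X, Y, 0.05, 0.05)
            c = cv.correlations
            assert (c >= -1e-12).all() and (c <= 1 + 1e-12).all()
            assert (np.diff(c) <= 1e-10).all()

    def test_ridge_never_increases_first_correlation(self, rng):
        X = standardize_columns(rng.normal(size=(40, 3)))
        Y = standardize_columns(X @ rng.normal(size=(3, 2))
                                + 0.5 * rng.normal(size=(40, 2)))
        r0 = regularized_cancor(X, Y, 0.0, 0.0).correlations[0]
        r1 = regularized_cancor(X, Y, 0.5, 0.5).correlations[0]
        assert r1 <= r0 + 1e-10

    def test_singular_case_well_posed_with_ridge(self, rng):
        # N < p makes the sample covariance singular; ridge regularizes it
        for _ in range(100):
            X = rng.normal(size=(8, 12))
            Y = rng.normal(size=(8, 11))
            cv = regularized_cancor(X, Y, 0.1, 0.1, m=3)
            assert np.isfinite(cv.correlations).all()

    def test_unit_regularized_variance_scores(self, rng):
        X = standardize_columns(rng.normal(size=(25, 4)))
        Y = standardize_columns(rng.normal(size=(25, 3)))
        lx, ly = 0.2, 0.3
        cv = regularized_cancor(X, Y, lx, ly)
        n = X.shape[0]
        Sxx = X.T @ X / (n - 1) + lx * np.eye(4)
        v = np.einsum("ij,ij->j", cv.a_coeffs, Sxx @ cv.a_coeffs)
        np.testing.assert_allclose(v, 1.0, atol=1e-10)

    def test_invalid_inputs(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            regularized_cancor(X, X, lambda_x=-0.1)
        bad = X.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            regularized_cancor(bad, X)


class TestSelectLambdas:
    def test_strong_linear_dependence_prefers_small_ridge(self, rng):
        X = rng.normal(size=(30, 2))
        Y = X @ np.array([[1.0, 0.2], [0.3, 1.0]]) + 0.05 * rng.normal(size=(30, 2))
        lx, ly = select_lambdas(standardize_columns(X), standardize_columns(Y),
                                grid=(1e-3, 1e-1, 1.0))
        assert lx <= 1e-1 and ly <= 1e-1

    def test_pure_noise_still_returns_a_cell(self, rng):
        X = rng.normal(size=(12, 2))
        Y = rng.normal(size=(12, 2))
        lx, ly = select_lambdas(X, Y, grid=(1e-2, 1e-1))
        assert (lx, ly) in {(a, b) for a in (1e-2, 1e-1) for b in (1e-2, 1e-1)}

    def test_singleton_grid(self, rng):
        X = rng.normal(size=(8, 2))
        Y = rng.normal(size=(8, 2))
        assert select_lambdas(X, Y, grid=(0.5,)) == (0.5, 0.5)


class TestReducePair:
    def test_high_dimensional_pair_reduced_to_three(self, rng):
        pair = _pair(rng, 30, 65, 43)
        red = reduce_pair(pair, lambdas=(0.1, 0.1))
        assert red.p == 3 and red.q == 3
        assert red.sample_ids == pair.sample_ids

    def test_low_dimensional_pair_unchanged(self, rng):
        pair = _pair(rng, 20, 5, 2)
        assert reduce_pair(pair) is pair

    def test_dimension_cap_uses_smaller_block(self, rng):
        pair = _pair(rng, 25, 12, 2)
        red = reduce_pair(pair, lambdas=(0.1, 0.1))
        assert red.p == 2 and red.q == 2
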