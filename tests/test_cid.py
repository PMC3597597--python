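"""The CID estimator: ecdfs, clustering-based subgrouping, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsaa import (
    PairedGeneSetData,
    SubgroupAssignment,
    cid,
    cid_given,
    cid_normalizer,
    conditional_ecdf,
    marginal_ecdf,
    subgroup_by_clustering,
    symmetric_cid,
)

# Conditional ecdf rows of the worked toy example: subgroup -> values at r1..r5
TOY_CONDITIONALS = {
    1: [0.5, 0.5, 0.0, 0.0, 0.5],  # (r1, r2)-group
    2: [1.0, 1.0, 1.0, 0.0, 1.0],  # r3-group
    3: [0.5, 0.5, 0.5, 0.5, 1.0],  # (r4, r5)-group
}


def _toy_assignment(X):
    return subgroup_by_clustering(X, 3)


class TestEcdfs:
    def test_marginal_matches_worked_example(self, toy_xy):
        _, Y = toy_xy
        expected = [0.6, 0.6, 0.4, 0.2, 0.8]
        got = [marginal_ecdf(Y, Y[i]) for i in range(5)]
        assert got == pytest.approx(expected)

    def test_marginal_extremes(self, rng):
        Y = rng.normal(size=(8, 3))
        assert marginal_ecdf(Y, Y.min(axis=0) - 1) == 0.0
        assert marginal_ecdf(Y, Y.max(axis=0)) == 1.0

    def test_marginal_dimension_mismatch(self, toy_xy):
        _, Y = toy_xy
        with pytest.raises(ValueError):
            marginal_ecdf(Y, np.zeros(3))

    def test_conditional_matches_worked_example(self, toy_xy):
        X, Y = toy_xy
        a = _toy_assignment(X)
        for s, row in TOY_CONDITIONALS.items():
            got = [conditional_ecdf(Y, a, s, Y[i]) for i in range(5)]
            assert got == pytest.approx(row), f"subgroup {s}"


class TestSubgrouping:
    def test_toy_partition_is_r12_r3_r45(self, toy_xy):
        X, _ = toy_xy
        a = _toy_assignment(X)
        assert a.labels[0] == a.labels[1]
        assert a.labels[3] == a.labels[4]
        assert len({a.labels[0], a.labels[2], a.labels[3]}) == 3

    def test_K_extremes(self, rng):
        X = rng.normal(size=(6, 2))
        assert subgroup_by_clustering(X, 1).sizes.tolist() == [6]
        assert subgroup_by_clustering(X, 6).sizes.tolist() == [1] * 6

    def test_K_out_of_range(self, rng):
        X = rng.normal(size=(4, 2))
        with pytest.raises(ValueError):
            subgroup_by_clustering(X, 5)
        with pytest.raises(ValueError):
            subgroup_by_clustering(X, 0)

    @pytest.mark.parametrize("method", ["hierarchical_complete", "kmeans", "som"])
    def test_two_separated_blobs_recovered(self, rng, method):
        # oracle: nearest true center classifies each point
        c = np.array([[0.0, 0.0], [10.0, 10.0]])
        X = np.vstack([rng.normal(c[0], 1.0, size=(20, 2)),
                       rng.normal(c[1], 1.0, size=(20, 2))])
        truth = (((X[:, None, :] - c[None]) ** 2).sum(-1)).argmin(1)
        a = subgroup_by_clustering(X, 2, method=method, seed=0)
        # same partition up to label swap
        same = (a.labels - 1 == truth).all() or (2 - a.labels == truth).all()
        assert same

    def test_deterministic_given_input(self, rng):
        X = rng.normal(size=(30, 4))
        a = subgroup_by_clustering(X, 4)
        b = subgroup_by_clustering(X, 4)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_assignment_invariants(self):
        with pytest.raises(ValueError):
            SubgroupAssignment(np.array([1, 1, 3]), 3)  # subgroup 2 empty


class TestNormalizer:
    def test_known_values(self):
        assert cid_normalizer(5) == pytest.approx(0.16)
        assert cid_normalizer(2) == pytest.approx(0.125)

    def test_limit_is_one_sixth(self):
        assert cid_normalizer(10**6) == pytest.approx(1 / 6, abs=1e-6)

    def test_rejects_small_N(self):
        with pytest.raises(ValueError):
            cid_normalizer(1)


class TestCid:
    def test_toy_value_and_decomposition(self, toy_xy):
        X, Y = toy_xy
        res = cid(Y, _toy_assignment(X))
        assert res.value == pytest.approx(0.425)
        assert res.per_sample == pytest.approx([0.04, 0.04, 0.14, 0.06, 0.06])
        assert res.normalizer == pytest.approx(0.16)
        assert res.per_subgroup_share.sum() == pytest.approx(1.0)

    def test_single_group_gives_zero(self, rng):
        Y = rng.normal(size=(12, 2))
        a = SubgroupAssignment(np.ones(12, dtype=int), 1)
        assert cid(Y, a).value == pytest.approx(0.0, abs=1e-15)

    def test_full_dependence_singletons_gives_one(self, rng):
        # q = 1, distinct values, K = N singleton subgroups
        for n in (3, 7, 20):
            y = rng.permutation(n).astype(float)[:, None]
            a = SubgroupAssignment(np.arange(1, n + 1), n)
            assert cid(y, a).value == pytest.approx(1.0)

    def test_length_mismatch(self, toy_xy):
        _, Y = toy_xy
        a = SubgroupAssignment(np.array([1, 1, 2]), 2)
        with pytest.raises(ValueError):
            cid(Y, a)

    def test_triple_loop_oracle_equivalence(self, rng):
        """Vectorized CID equals a naive loop over samples/subgroups/rows."""
        for _ in range(50):
            n = int(rng.integers(4, 31))
            q = int(rng.integers(1, 4))
            K = int(rng.integers(2, min(6, n)))
            Y = rng.normal(size=(n, q))
            labels = np.r_[np.arange(1, K + 1),
                           rng.integers(1, K + 1, size=n - K)]
            rng.shuffle(labels)
            a = SubgroupAssignment(labels, K)
            # naive evaluation
            total = 0.0
            for i in range(n):
                Gi = np.mean([(Y[j] <= Y[i]).all() for j in range(n)])
                Di = 0.0
                for s in range(1, K + 1):
                    rows = np.where(labels == s)[0]
                    Gs = np.mean([(Y[j] <= Y[i]).all() for j in rows])
                    Di += (len(rows) / n) * (Gs - Gi) ** 2
                total += Di
            naive = total / n / cid_normalizer(n)
            assert cid(Y, a).value == pytest.approx(naive, abs=1e-12)


class TestCidProperties:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(4, 25), st.integers(1, 3))
    def test_bounded_in_unit_interval(self, seed, n, q):
        # multivariate bound holds in the operating regime K <= N/2;
        # univariate (q = 1) holds for any K
        r = np.random.default_rng(seed)
        Y = r.normal(size=(n, q))
        K = int(r.integers(1, n + 1)) if q == 1 else int(r.integers(1, n // 2 + 1))
        X = r.normal(size=(n, 2))
        v = cid_given(X, Y, K).value
        assert 0.0 <= v <= 1.0 + 1e-12

    def test_univariate_bounded_even_with_singleton_subgroups(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 20))
            y = rng.normal(size=(n, 1))
            v = cid_given(rng.normal(size=(n, 2)), y, n).value
            assert 0.0 <= v <= 1.0 + 1e-12

    def test_monotone_transform_invariance(self, rng):
        X = rng.normal(size=(20, 3))
        Y = rng.normal(size=(20, 2))
        a = subgroup_by_clustering(X, 4)
        base = cid(Y, a).value
        Yt = np.column_stack([np.exp(Y[:, 0]), Y[:, 1] ** 3 + 5 * Y[:, 1]])
        assert cid(Yt, a).value == pytest.approx(base, abs=1e-14)

    def test_depends_on_X_only_through_partition(self, rng):
        X = rng.normal(size=(15, 2))
        Y = rng.normal(size=(15, 2))
        a = subgroup_by_clustering(X, 3)
        # any X' yielding the same partition yields the same CID
        assert cid(Y, a).value == cid_given(100 * X + 7, Y, 3).value

    def test_asymmetry_is_allowed(self, toy_xy):
        X, Y = toy_xy
        fwd = cid_given(X, Y, 3).value
        rev = cid_given(Y, X, 3).value
        assert fwd != pytest.approx(rev)


class TestSymmetricCid:
    def test_identical_blocks_equal_directed_value(self, rng):
        Z = rng.normal(size=(10, 2))
        pair = PairedGeneSetData(Z, Z.copy(), [f"s{i}" for i in range(10)])
        assert symmetric_cid(pair, 3) == pytest.approx(cid_given(Z, Z, 3).value)

    def test_mean_of_both_directions(self, toy_pair):
        X, Y = toy_pair.X, toy_pair.Y
        a = cid_given(X, Y, 3).value
        b = cid_given(Y, X, 3).value
        s = symmetric_cid(toy_pair, 3)
        assert s == pytest.approx((a + b) / 2)
        assert 0.0 <= s <= 1.0
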