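"""The coefficient of intrinsic dependence (CID).

The CID measures how strongly a multivariate target Y depends on a
multivariate predictor X.  The sample is partitioned into K subgroups by
clustering the predictor rows; the CID is the normalized, subgroup-size
weighted average squared discrepancy between the marginal empirical CDF of Y
and the conditional empirical CDFs of Y within each subgroup, evaluated at
every observed target row:

    D_i   = sum_s (n_s / N) * (G_s(y_i) - G(y_i))**2
    CID   = (1/N) * sum_i D_i / C(N),        C(N) = (N**2 - 1) / (6 N**2)

where G is the marginal ecdf, G_s the ecdf within subgroup s, and the
multivariate ecdf counts rows componentwise <= the evaluation point
(non-strict in every coordinate, including the point itself).  C(N) makes
CID = 1 exactly under full dependence (distinct univariate targets, singleton
subgroups) and CID = 0 when K = 1.

The CID is asymmetric: CID(Y|X) need not equal CID(X|Y).  It is invariant
under strictly increasing transformations applied per coordinate of Y, and
depends on X only through the subgroup partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .data import PairedGeneSetData

__all__ = [
    "SubgroupAssignment",
    "CidResult",
    "marginal_ecdf",
    "conditional_ecdf",
    "subgroup_by_clustering",
    "cid",
    "cid_normalizer",
    "symmetric_cid",
]


@dataclass
class SubgroupAssignment:
    """Partition of N samples into K nonempty subgroups labelled 1..K."""

    labels: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.K + 1)):
            raise ValueError(
                f"labels must cover 1..{self.K} with no empty subgroup; "
                f"got {present.tolist()}"
            )
        if self.K > len(self.labels):
            raise ValueError("more subgroups than samples")

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    @property
    def sizes(self) -> np.ndarray:
        """Subgroup sizes n_s, s = 1..K."""
        return np.bincount(self.labels, minlength=self.K + 1)[1:]

    def permuted(self, rng: np.random.Generator) -> "SubgroupAssignment":
        """Randomly permute labels across samples (subgroup sizes fixed)."""
        return SubgroupAssignment(rng.permutation(self.labels), self.K)


@dataclass
class CidResult:
    """CID value with its per-sample and per-subgroup decomposition."""

    value: float
    per_sample: np.ndarray  # weighted squared discrepancies D_i
    per_subgroup_share: np.ndarray  # fractional contribution of each subgroup
    normalizer: float  # C(N)


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters as 1..K in order of first appearance (deterministic)."""
    out = np.empty_like(raw)
    mapping: dict[int, int] = {}
    for i, v in enumerate(raw):
        if v not in mapping:
            mapping[v] = len(mapping) + 1
        out[i] = mapping[v]
    return out


def dominance_matrix(Y: np.ndarray) -> np.ndarray:
    """L[j, i] = 1 if row y_j <= row y_i componentwise (non-strict).

    Column means of L are the marginal ecdf values at each observed row;
    subgroup-restricted column means are the conditional ecdf values.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    return (Y[:, None, :] <= Y[None, :, :]).all(axis=-1).astype(float)


def marginal_ecdf(Y: np.ndarray, y: np.ndarray) -> float:
    """Fraction of rows of Y componentwise <= the point y."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != Y.shape[1]:
        raise ValueError(f"point has dimension {y.shape[0]}, Y has {Y.shape[1]}")
    if np.isnan(Y).any() or np.isnan(y).any():
        raise ValueError("missing values not allowed")
    return float((Y <= y).all(axis=1).mean())


def conditional_ecdf(
    Y: np.ndarray, assignment: SubgroupAssignment, s: int, y: np.ndarray
) -> float:
    """Fraction of subgroup-s rows of Y componentwise <= the point y."""
    if not 1 <= s <= assignment.K:
        raise ValueError(f"subgroup index {s} outside 1..{assignment.K}")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if len(assignment.labels) != Y.shape[0]:
        raise ValueError("assignment length does not match Y")
    return marginal_ecdf(Y[assignment.labels == s], y)


def _som_1d(X: np.ndarray, K: int, rng: np.random.Generator,
            n_iter: int = 50) -> np.ndarray:
    """Minimal 1-D batch self-organizing map with K units.

    Units live on a line; each batch step assigns samples to their nearest
    unit and moves units toward the neighbourhood-weighted mean with a
    shrinking Gaussian neighbourhood.  Returns raw unit indices (0-based).
    """
    n = X.shape[0]
    weights = X[rng.choice(n, size=K, replace=False)].astype(float)
    grid = np.arange(K, dtype=float)
    for it in range(n_iter):
        sigma = max(K / 2.0 * (1.0 - it / n_iter), 0.5)
        d2 = ((X[:, None, :] - weights[None, :, :]) ** 2).sum(-1)
        bmu = d2.argmin(axis=1)
        h = np.exp(-((grid[:, None] - grid[bmu][None, :]) ** 2) / (2 * sigma**2))
        denom = h.sum(axis=1, keepdims=True)
        np.divide(h, denom, out=h, where=denom > 0)
        weights = h @ X
    d2 = ((X[:, None, :] - weights[None, :, :]) ** 2).sum(-1)
    return d2.argmin(axis=1)


def subgroup_by_clustering(
    X: np.ndarray,
    K: int,
    method: str = "hierarchical_complete",
    seed: int | None = None,
) -> SubgroupAssignment:
    """Partition samples into K subgroups by clustering the predictor rows.

    The primary method is agglomerative hierarchical clustering with complete
    linkage on Euclidean distances, with the tree cut to K clusters; it is
    deterministic given the input order.  ``kmeans`` and ``som`` are optional
    seeded backends.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if not 1 <= K <= n:
        raise ValueError(f"K={K} outside 1..{n}")
    if K == 1:
        return SubgroupAssignment(np.ones(n, dtype=int), 1)
    if K == n:
        return SubgroupAssignment(np.arange(1, n + 1), n)
    if method == "hierarchical_complete":
        raw = fcluster(linkage(X, method="complete"), K, criterion="maxclust")
    elif method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=K, n_init=10, random_state=seed)
        raw = km.fit_predict(X) + 1
    elif method == "som":
        rng = np.random.default_rng(seed)
        raw = _som_1d(X, K, rng)
        # merge-free SOMs can leave dead units; split the largest cluster's
        # farthest points until K nonempty groups exist
        raw = _canonical_labels(raw)
        while len(np.unique(raw)) < K:
            vals, counts = np.unique(raw, return_counts=True)
            big = vals[counts.argmax()]
            members = np.where(raw == big)[0]
            centroid = X[members].mean(axis=0)
            far = members[((X[members] - centroid) ** 2).sum(-1).argmax()]
            raw[far] = raw.max() + 1
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    labels = _canonical_labels(np.asarray(raw))
    k_eff = len(np.unique(labels))
    if k_eff != K:
        raise RuntimeError(f"clustering produced {k_eff} groups, requested {K}")
    return SubgroupAssignment(labels, K)


def cid_normalizer(N: int) -> float:
    """C(N) = (N^2 - 1) / (6 N^2); the N -> inf limit is 1/6."""
    if N < 2:
        raise ValueError("need N >= 2")
    return (N * N - 1) / (6.0 * N * N)


def _cid_from_dominance(
    L: np.ndarray, labels: np.ndarray, K: int
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Core evaluation given a precomputed dominance matrix.

    Shared by :func:`cid` and the label-permutation null in the inference
    module, where L is fixed across permutations.
    """
    N = L.shape[0]
    C = cid_normalizer(N)
    G = L.mean(axis=0)
    onehot = (labels[None, :] == np.arange(1, K + 1)[:, None]).astype(float)
    ns = onehot.sum(axis=1)
    Gs = (onehot @ L) / ns[:, None]  # K x N conditional ecdfs
    contrib = (ns / N)[:, None] * (Gs - G) ** 2  # K x N
    per_sample = contrib.sum(axis=0)
    value = per_sample.mean() / C
    total = per_sample.sum()
    share = contrib.sum(axis=1) / total if total > 0 else np.zeros(K)
    return float(value), per_sample, share, C


def cid(Y: np.ndarray, assignment: SubgroupAssignment) -> CidResult:
    """CID of the target block Y given a subgroup assignment of the sample."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != assignment.n_samples:
        raise ValueError("assignment length does not match Y row count")
    if Y.shape[0] < 2:
        raise ValueError("need N >= 2")
    if np.isnan(Y).any():
        raise ValueError("missing values not allowed")
    L = dominance_matrix(Y)
    value, per_sample, share, C = _cid_from_dominance(
        L, assignment.labels, assignment.K
    )
    return CidResult(value=value, per_sample=per_sample,
                     per_subgroup_share=share, normalizer=C)


def cid_given(
    X: np.ndarray,
    Y: np.ndarray,
    K: int,
    method: str = "hierarchical_complete",
    seed: int | None = None,
) -> CidResult:
    """Convenience: cluster X into K subgroups, then evaluate CID(Y|X)."""
    return cid(Y, subgroup_by_clustering(X, K, method=method, seed=seed))


def symmetric_cid(
    pair: PairedGeneSetData,
    K: int,
    method: str = "hierarchical_complete",
    seed: int | None = None,
) -> float:
    """Mean of CID(Y|X) and CID(X|Y), each clustering its own predictor."""
    fwd = cid_given(pair.X, pair.Y, K, method=method, seed=seed)
    rev = cid_given(pair.Y, pair.X, K, method=method, seed=seed)
    return 0.5 * (fwd.value + rev.value)
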