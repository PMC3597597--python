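"""Permutation significance and the adjusted-CID outlier screen.

Two inferential devices accompany the association measures.  (1) A
permutation test: for the CID the subgroup labels are randomly reassigned
across samples (the observed partition sizes are kept and the clustering is
not re-run); for the rival measures the rows of X are permuted and the full
statistic, including re-clustering where it applies, is recomputed.  The
p-value is the fraction of the B null values that beat or tie the observed
statistic in the direction of stronger association.  (2) For all-pairs
screens, raw CID values are standardized per predictor column by median and
(unscaled) median absolute deviation; adjusted values above 3.5 are declared
significant, following the modified z-score outlier rule.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

from .cid import (
    SubgroupAssignment,
    _cid_from_dominance,
    dominance_matrix,
    subgroup_by_clustering,
)
from .data import PairedGeneSetData
from .rivals import cancor_score, hd_score, kld_score, ppr_score

logger = logging.getLogger("gsaa")

__all__ = [
    "PermutationResult",
    "AdjustedCidMatrix",
    "permutation_pvalue",
    "adjusted_cid",
]

#: Direction in which a larger ("greater") or smaller ("less") statistic
#: means stronger association.
_DIRECTIONS = {
    "cid": "greater",
    "cancor": "greater",
    "kld": "greater",
    "hd": "greater",
    "ppr": "less",
}


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null, and the resulting p-value."""

    observed: float
    null_values: np.ndarray
    p_value: float
    direction: str


def _pvalue(observed: float, null: np.ndarray, direction: str) -> float:
    """p = #{null beats-or-ties observed}/B; ties count against the observed."""
    if direction == "greater":
        return float((null >= observed).mean())
    elif direction == "less":
        return float((null <= observed).mean())
    raise ValueError(f"unknown direction {direction!r}")


def _cid_label_permutation(
    Y: np.ndarray,
    assignment: SubgroupAssignment,
    B: int,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray]:
    """CID null by label permutation, vectorized over all B permutations.

    The dominance matrix of Y is fixed, so each permutation only regroups its
    rows; all B conditional-ecdf blocks are evaluated in one einsum.
    """
    N = Y.shape[0]
    K = assignment.K
    L = dominance_matrix(Y)
    observed, *_ = _cid_from_dominance(L, assignment.labels, K)
    perms = np.stack([rng.permutation(assignment.labels) for _ in range(B)])
    onehot = (perms[:, None, :] == np.arange(1, K + 1)[None, :, None])
    onehot = onehot.astype(float)
    ns = onehot.sum(axis=-1)  # B x K (constant across rows by construction)
    G = L.mean(axis=0)
    Gs = np.einsum("bkn,ni->bki", onehot, L) / ns[:, :, None]
    per_sample = ((ns / N)[:, :, None] * (Gs - G) ** 2).sum(axis=1)
    C = (N * N - 1) / (6.0 * N * N)
    null = per_sample.mean(axis=1) / C
    return observed, null


def permutation_pvalue(
    measure,
    pair: PairedGeneSetData,
    K: int,
    B: int = 1000,
    seed: int | None = None,
    r: int = 3,
    terms: int = 2,
    clustering: str = "hierarchical_complete",
) -> PermutationResult:
    """Permutation p-value for one gene-set pair under a chosen measure.

    ``measure`` is one of ``'cid'``, ``'cancor'``, ``'kld'``, ``'hd'``,
    ``'ppr'``, or a callable ``f(X, Y) -> float`` (treated as
    direction-greater).  The RNG is fully determined by ``seed``.
    """
    if B < 1:
        raise ValueError("need B >= 1 permutations")
    rng = np.random.default_rng(seed)
    X, Y = pair.X, pair.Y
    n = pair.n_samples

    if measure == "cid":
        assignment = subgroup_by_clustering(X, K, method=clustering, seed=seed)
        observed, null = _cid_label_permutation(Y, assignment, B, rng)
        direction = "greater"
    else:
        if callable(measure):
            stat = measure
            direction = "greater"
        elif measure == "cancor":
            stat = lambda Xp, Yp: cancor_score(Xp, Yp)  # noqa: E731
            direction = "greater"
        elif measure == "kld":
            stat = lambda Xp, Yp: kld_score(Xp, Yp, K=K, r=r)  # noqa: E731
            direction = "greater"
        elif measure == "hd":
            stat = lambda Xp, Yp: hd_score(Xp, Yp, K=K, r=r)  # noqa: E731
            direction = "greater"
        elif measure == "ppr":
            stat = lambda Xp, Yp: ppr_score(Xp, Yp, terms=terms)  # noqa: E731
            direction = "less"
        else:
            raise ValueError(f"unknown measure {measure!r}")
        observed = float(stat(X, Y))
        null = np.empty(B)
        for b in range(B):
            null[b] = stat(X[rng.permutation(n)], Y)

    return PermutationResult(
        observed=float(observed),
        null_values=np.asarray(null, dtype=float),
        p_value=_pvalue(observed, np.asarray(null), direction),
        direction=direction,
    )


@dataclass
class AdjustedCidMatrix:
    """Per-predictor-column median/MAD standardization of a raw CID matrix.

    ``raw[i, j]`` is CID(target i | predictor j); the diagonal is undefined
    (NaN).  ``adjusted[i, j] = (raw[i, j] - m_j) / mad_j`` with m_j and mad_j
    the median and MAD of column j's off-diagonal entries.  ``significant``
    flags adjusted values above the cutoff; columns with zero MAD are marked
    degenerate and make no calls.
    """

    raw: np.ndarray
    adjusted: np.ndarray
    per_predictor_median: np.ndarray
    per_predictor_mad: np.ndarray
    significant: np.ndarray
    degenerate_columns: np.ndarray
    cutoff: float


def adjusted_cid(
    raw: np.ndarray,
    cutoff: float = 3.5,
    mad_scale: float = 1.0,
) -> AdjustedCidMatrix:
    """Screen a G x G raw CID matrix for per-predictor outliers.

    ``mad_scale`` divides the MAD before standardizing; the default 1.0 is the
    plain (unscaled) MAD.  Passing 0.6745 reproduces the modified z-score
    consistency convention.
    """
    raw = np.asarray(raw, dtype=float)
    G = raw.shape[0]
    if raw.shape != (G, G) or G < 3:
        raise ValueError("need a square matrix with G >= 3")
    off = ~np.eye(G, dtype=bool)
    med = np.empty(G)
    mad = np.empty(G)
    adjusted = np.full_like(raw, np.nan)
    degenerate = np.zeros(G, dtype=bool)
    for j in range(G):
        col = raw[off[:, j], j]
        med[j] = np.median(col)
        mad[j] = np.median(np.abs(col - med[j])) / mad_scale
        if mad[j] == 0:
            degenerate[j] = True
            logger.warning("adjusted CID: predictor column %d has zero MAD; "
                           "no significance calls made for it", j)
            continue
        adjusted[off[:, j], j] = (col - med[j]) / mad[j]
    significant = np.zeros_like(raw, dtype=bool)
    with np.errstate(invalid="ignore"):
        significant[off] = adjusted[off] > cutoff
    significant[:, degenerate] = False
    return AdjustedCidMatrix(
        raw=raw, adjusted=adjusted, per_predictor_median=med,
        per_predictor_mad=mad, significant=significant,
        degenerate_columns=degenerate, cutoff=cutoff,
    )
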