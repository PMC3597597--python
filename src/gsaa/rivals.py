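"""Rival association measures: canonical correlation, KLD, HD and PPR.

These are the comparison statistics benchmarked against the CID.  CanCor is
the largest classical canonical correlation.  KLD and HD compare the marginal
cell probabilities of a quantile-discretized target against the conditional
cell probabilities within predictor-derived subgroups, aggregated with
subgroup-size weights (the same conditioning device as the CID).  PPR is a
reduced-scope projection pursuit regression whose residual sum of squares is
a monotone proxy for fit quality, not a re-implementation of any particular
legacy smoother stack.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .cid import SubgroupAssignment, subgroup_by_clustering

__all__ = [
    "DiscretizedDistribution",
    "cancor_score",
    "quantile_discretize",
    "kld_score",
    "hd_score",
    "ppr_score",
]


def cancor_score(X: np.ndarray, Y: np.ndarray) -> float:
    """Largest classical (unregularized) canonical correlation of X and Y."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = X.shape[0]
    if n <= max(X.shape[1], Y.shape[1]):
        raise ValueError(
            "need N > max(p, q) for the unregularized solve; "
            "use the regularized canonical variates instead"
        )
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    qx, rx = np.linalg.qr(Xc)
    qy, ry = np.linalg.qr(Yc)
    if min(np.abs(np.diag(rx)).min(), np.abs(np.diag(ry)).min()) < 1e-10:
        raise np.linalg.LinAlgError(
            "singular within-block covariance; use the regularized path"
        )
    s = np.linalg.svd(qx.T @ qy, compute_uv=False)
    return float(np.clip(s[0], 0.0, 1.0))


@dataclass
class DiscretizedDistribution:
    """Joint cell probabilities of a quantile-binned target block.

    Each of the q dimensions is cut into r bins at its sample quantiles
    (k/r, k=1..r-1, type-7 interpolation); a joint cell is the tuple of
    per-dimension bins, flattened to a single index.
    """

    cell_probs: np.ndarray  # r**q
    r: int
    cell_index_of_sample: np.ndarray  # N ints in [0, r**q)


def quantile_discretize(Y: np.ndarray, r: int = 3) -> DiscretizedDistribution:
    """Bin each target dimension at its sample quantiles; ties go low."""
    if r < 2:
        raise ValueError("need r >= 2 bins")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, q = Y.shape
    if r**q > n:
        warnings.warn(
            f"{r}**{q} = {r**q} cells exceed N = {n}; estimates will be sparse",
            stacklevel=2,
        )
    cell = np.zeros(n, dtype=int)
    for d in range(q):
        cuts = np.quantile(Y[:, d], np.arange(1, r) / r)  # type-7 default
        # value equal to a cut point falls in the lower bin
        bins = np.searchsorted(cuts, Y[:, d], side="left")
        cell = cell * r + bins
    probs = np.bincount(cell, minlength=r**q) / n
    return DiscretizedDistribution(cell_probs=probs, r=r,
                                   cell_index_of_sample=cell)


def _conditional_cell_probs(
    disc: DiscretizedDistribution, assignment: SubgroupAssignment
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subgroup cell probabilities on the global marginal cells."""
    ncell = disc.cell_probs.shape[0]
    K = assignment.K
    out = np.zeros((K, ncell))
    ns = assignment.sizes
    for s in range(1, K + 1):
        members = disc.cell_index_of_sample[assignment.labels == s]
        out[s - 1] = np.bincount(members, minlength=ncell) / ns[s - 1]
    return out, ns


def kld_score(
    X: np.ndarray,
    Y: np.ndarray,
    K: int,
    r: int = 3,
    assignment: SubgroupAssignment | None = None,
) -> float:
    """Subgroup-size weighted Kullback-Leibler divergence (nats).

    score = sum_s (n_s/N) sum_cells p_cond ln(p_cond / p_marg), with
    0 ln(0/.) = 0.  Conditional cells are the global marginal cells, so any
    occupied conditional cell has positive marginal probability.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if assignment is None:
        assignment = subgroup_by_clustering(X, K)
    disc = quantile_discretize(Y, r=r)
    cond, ns = _conditional_cell_probs(disc, assignment)
    marg = disc.cell_probs
    n = Y.shape[0]
    total = 0.0
    for s in range(assignment.K):
        pc = cond[s]
        nz = pc > 0
        total += (ns[s] / n) * float(np.sum(pc[nz] * np.log(pc[nz] / marg[nz])))
    return total


def hd_score(
    X: np.ndarray,
    Y: np.ndarray,
    K: int,
    r: int = 3,
    assignment: SubgroupAssignment | None = None,
) -> float:
    """Subgroup-size weighted Hellinger distance, in [0, 1].

    H_s = sqrt(1 - sum_cells sqrt(p_cond * p_marg)); score = sum_s (n_s/N) H_s.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if assignment is None:
        assignment = subgroup_by_clustering(X, K)
    disc = quantile_discretize(Y, r=r)
    cond, ns = _conditional_cell_probs(disc, assignment)
    marg = disc.cell_probs
    n = Y.shape[0]
    total = 0.0
    for s in range(assignment.K):
        bc = float(np.sum(np.sqrt(cond[s] * marg)))
        total += (ns[s] / n) * np.sqrt(max(1.0 - bc, 0.0))
    return total


def _lowess_fit(z: np.ndarray, y: np.ndarray, frac: float = 0.6) -> np.ndarray:
    """Local-linear smoother of y on z, evaluated at the sample points."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    fitted = lowess(y, z, frac=frac, return_sorted=False)
    return np.asarray(fitted, dtype=float)


def ppr_score(
    X: np.ndarray,
    Y: np.ndarray,
    terms: int = 2,
    max_iter: int = 3,
    frac: float = 0.6,
) -> float:
    """Total residual sum of squares of a projection pursuit regression fit.

    Greedy forward fit: each term projects the current residual onto a
    direction initialized from the least-squares coefficient map, smooths the
    projection with a local-linear smoother, and regresses the residual
    columns on the smoothed ridge function.  A term is kept only if it lowers
    the RSS, so RSS is non-increasing in ``terms``.  Smaller RSS means
    stronger association; this is a monotone proxy for fit quality.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    Xc = X - X.mean(axis=0)
    R = Y - Y.mean(axis=0)  # residual after the intercept-only fit
    for _ in range(terms):
        # initialize direction and response weights from the linear map
        coef, *_ = np.linalg.lstsq(Xc, R, rcond=None)
        if not np.any(coef):
            break
        U, _, Vt = np.linalg.svd(coef, full_matrices=False)
        alpha, beta = U[:, 0], Vt[0]
        best_term = None
        for _ in range(max_iter):
            z = Xc @ alpha
            if np.ptp(z) == 0:
                break
            comb = R @ beta / max(beta @ beta, 1e-12)
            f = _lowess_fit(z, comb, frac=frac)
            fc = f - f.mean()
            denom = fc @ fc
            if denom <= 1e-12:
                break
            beta = (R.T @ fc) / denom  # q loadings on the ridge function
            cand = R - np.outer(fc, beta)
            if best_term is None or (cand**2).sum() < (best_term**2).sum():
                best_term = cand
            # refine the direction toward the current combined response
            coef1, *_ = np.linalg.lstsq(Xc, R @ beta, rcond=None)
            norm = np.linalg.norm(coef1)
            if norm <= 1e-12:
                break
            alpha = coef1 / norm
        if best_term is not None and (best_term**2).sum() < (R**2).sum():
            R = best_term
    return float((R**2).sum())
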