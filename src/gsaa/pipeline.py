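"""End-to-end gene set association analysis (GSAA) runners.

Unsupervised mode screens every ordered pair of gene sets in a collection:
for each (target i, predictor j) the blocks are extracted, reduced to
canonical variates when high-dimensional, the predictor block is clustered
into K subgroups, and CID(g_i | g_j) is computed — G(G-1) values for G sets.
Raw values are then standardized per predictor column (median/MAD) and
adjusted values above 3.5 are called significant.

Supervised mode tests one designated predictor set (e.g. transcription
factors) against one target set (a pathway or subnetwork) in a chosen sample
cohort, with K set to roughly one-tenth of the cohort size and significance
from the CID label-permutation test at p <= alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd

from .cid import cid, subgroup_by_clustering
from .data import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    PairedGeneSetData,
    extract_pair,
)
from .inference import AdjustedCidMatrix, PermutationResult, adjusted_cid, permutation_pvalue
from .reduction import reduce_pair

logger = logging.getLogger("gsaa")

__all__ = [
    "GsaaConfig",
    "supervised_k",
    "run_unsupervised_gsaa",
    "run_supervised_gsaa",
]


@dataclass
class GsaaConfig:
    """Tunable settings of the GSAA runners.

    Defaults follow the benchmark conditions: K=3 subgroups for the
    unsupervised all-pairs screen, K ~ N/10 for supervised tests, up to 3
    canonical variate pairs with reduction triggered at 10 genes, B=1000
    permutations, alpha=0.05, adjusted-CID cutoff 3.5.
    """

    mode: str = "unsupervised"
    K_rule: str = "fixed"  # 'fixed' or 'n_over_10'
    K_fixed: int = 3
    max_variate_pairs: int = 3
    reduction_threshold: int = 10
    B: int = 1000
    alpha: float = 0.05
    adjusted_cutoff: float = 3.5
    mad_scale: float = 1.0
    lambda_grid: tuple | None = None  # None -> reduction module default
    missing_policy: str = "drop_gene"
    clustering: str = "hierarchical_complete"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("unsupervised", "supervised"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.K_rule not in ("fixed", "n_over_10"):
            raise ValueError(f"unknown K rule {self.K_rule!r}")


def supervised_k(n: int) -> int:
    """K = round(N/10), at least 2: 60 -> 6, 48 -> 5, 152 -> 15."""
    return int(min(max(np.floor(n / 10 + 0.5), 2), n))


def _prepare_pair(
    expr: ExpressionMatrix,
    predictor: GeneSet,
    target: GeneSet,
    cfg: GsaaConfig,
) -> tuple[PairedGeneSetData, bool]:
    """Extract and (if high-dimensional) canonically reduce one pair."""
    pair = extract_pair(expr, predictor, target, missing_policy=cfg.missing_policy)
    reduced = pair.p >= cfg.reduction_threshold or pair.q >= cfg.reduction_threshold
    if reduced:
        kwargs = {} if cfg.lambda_grid is None else {"grid": cfg.lambda_grid}
        pair = reduce_pair(
            pair,
            max_pairs=cfg.max_variate_pairs,
            threshold_dim=cfg.reduction_threshold,
            **kwargs,
        )
    return pair, reduced


def run_unsupervised_gsaa(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    cfg: GsaaConfig | None = None,
) -> tuple[AdjustedCidMatrix, pd.DataFrame]:
    """All-pairs CID screen over a gene-set collection.

    Returns the adjusted CID matrix and a tidy association table with one row
    per ordered (target, predictor) pair — G(G-1) rows for G sets.  Pairs are
    processed in deterministic collection order.
    """
    cfg = cfg or GsaaConfig()
    G = len(sets)
    if G < 3:
        raise ValueError("need at least 3 gene sets")
    K = cfg.K_fixed
    names = sets.names
    raw = np.full((G, G), np.nan)
    reduced_flags = np.zeros((G, G), dtype=bool)
    for j, predictor in enumerate(sets):
        for i, target in enumerate(sets):
            if i == j:
                continue
            pair, reduced = _prepare_pair(expr, predictor, target, cfg)
            assignment = subgroup_by_clustering(
                pair.X, K, method=cfg.clustering, seed=cfg.seed
            )
            raw[i, j] = cid(pair.Y, assignment).value
            reduced_flags[i, j] = reduced
            logger.debug("CID(%s | %s) = %.4f (reduced=%s, K=%d)",
                         target.name, predictor.name, raw[i, j], reduced, K)
    screen = adjusted_cid(raw, cutoff=cfg.adjusted_cutoff, mad_scale=cfg.mad_scale)
    rows = []
    for j in range(G):
        for i in range(G):
            if i == j:
                continue
            rows.append({
                "pair_id": f"{names[i]}|{names[j]}",
                "target_set": names[i],
                "predictor_set": names[j],
                "statistic": "cid",
                "raw_value": raw[i, j],
                "adjusted_value": screen.adjusted[i, j],
                "significant": bool(screen.significant[i, j]),
                "reduced": bool(reduced_flags[i, j]),
                "K": K,
                "seed": cfg.seed,
            })
    return screen, pd.DataFrame(rows)


def run_supervised_gsaa(
    expr: ExpressionMatrix,
    set1: GeneSet,
    set2: GeneSet,
    cohort_samples: list[str] | None = None,
    cfg: GsaaConfig | None = None,
) -> PermutationResult:
    """Test predictor set1 (e.g. TFs) against target set2 in one cohort.

    K is round(N/10) clipped to [2, N] unless the config fixes it.  The
    result carries the observed CID, the label-permutation null and the
    p-value; significance is p <= cfg.alpha.
    """
    cfg = cfg or GsaaConfig(mode="supervised", K_rule="n_over_10")
    if cohort_samples is not None:
        missing = [s for s in cohort_samples if s not in expr.sample_ids]
        if missing:
            raise ValueError(f"cohort samples not in matrix: {missing}")
        idx = [expr.sample_ids.index(s) for s in cohort_samples]
        expr = ExpressionMatrix(
            expr.values[idx], sample_ids=list(cohort_samples),
            gene_ids=list(expr.gene_ids), mask=expr.mask[idx],
        )
    pair, _ = _prepare_pair(expr, set1, set2, cfg)
    n = pair.n_samples
    if n < 20:
        logger.warning("cohort of %d samples is small; K clipped to >= 2", n)
    K = supervised_k(n) if cfg.K_rule == "n_over_10" else cfg.K_fixed
    return permutation_pvalue(
        "cid", pair, K=K, B=cfg.B, seed=cfg.seed, clustering=cfg.clustering
    )
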