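"""Expression matrices, gene-set collections, and paired gene-set blocks.

Expression data are log-ratio values on N samples by G genes.  Gene sets are
named, ordered lists of gene identifiers read from GMT files.  The analysis
unit is a :class:`PairedGeneSetData`: the sample-aligned expression blocks of
a predictor gene set (X, N x p) and a target gene set (Y, N x q), with no
missing values.

Gene identifiers are opaque strings; callers must supply expression matrices
keyed by the same identifiers as their gene-set collections.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("gsaa")

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "PairedGeneSetData",
    "read_gmt",
    "write_gmt",
    "read_expression_matrix",
    "extract_pair",
]


@dataclass
class ExpressionMatrix:
    """N x G expression values with an explicit missing-value mask.

    ``values`` holds floats with NaN at masked positions; ``mask`` is True
    where the entry is missing.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        n, g = self.values.shape
        if n != len(self.sample_ids) or g != len(self.gene_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene ids")
        if self.mask is None:
            self.mask = np.isnan(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None


@dataclass
class GeneSet:
    """A named, ordered list of gene identifiers."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Ordered collection of gene sets with unique names."""

    sets: list[GeneSet]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set names: {dup}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


@dataclass
class PairedGeneSetData:
    """Sample-aligned predictor (X, N x p) and target (Y, N x q) blocks."""

    X: np.ndarray
    Y: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y row counts differ")
        if self.X.shape[0] != len(self.sample_ids):
            raise ValueError("sample id count does not match row count")
        if self.X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if self.X.shape[1] < 1 or self.Y.shape[1] < 1:
            raise ValueError("empty gene set block")
        if not (np.isfinite(self.X).all() and np.isfinite(self.Y).all()):
            raise ValueError("paired blocks must not contain missing values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Y.shape[1]

    def swapped(self) -> "PairedGeneSetData":
        """Swap predictor and target roles."""
        return PairedGeneSetData(self.Y, self.X, list(self.sample_ids))


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (tab-separated: name, description, genes...).

    The description field is discarded; gene order is preserved.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            genes = [g for g in fields[2:] if g]
            sets.append(GeneSet(name=name, genes=genes))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    """Write a collection in GMT format (round-trips with :func:`read_gmt`)."""
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, description, *s.genes]) + "\n")


def read_expression_matrix(
    path,
    delimiter: str = "\t",
    orientation: str = "genes_by_samples",
    missing_token: str = "NA",
) -> ExpressionMatrix:
    """Read a delimited expression text file.

    ``orientation='genes_by_samples'`` (default, microarray convention) means
    rows are genes and columns are samples; ``'samples_by_genes'`` the
    transpose.  The first row and column are headers.  Cells equal to
    ``missing_token`` are masked; any other non-numeric cell is an error.
    Ragged rows are rejected.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    if not rows:
        raise ValueError(f"{path}: empty file")
    width = len(rows[0])
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValueError(
                f"{path}: ragged row at line {lineno}: "
                f"{len(row)} fields, expected {width}"
            )
    header = [c.strip() for c in rows[0][1:]]
    row_ids = [r[0].strip() for r in rows[1:]]
    body = np.empty((len(row_ids), len(header)))
    for i, row in enumerate(rows[1:]):
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell == missing_token or cell == "":
                body[i, j] = np.nan
            else:
                try:
                    body[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at line {i + 2}, "
                        f"column {j + 2}"
                    ) from None
    if orientation == "genes_by_samples":
        return ExpressionMatrix(body.T, sample_ids=header, gene_ids=row_ids)
    elif orientation == "samples_by_genes":
        return ExpressionMatrix(body, sample_ids=row_ids, gene_ids=header)
    raise ValueError(f"unknown orientation {orientation!r}")


def _select_block(
    expr: ExpressionMatrix, gene_set: GeneSet
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Columns of ``expr`` for the genes of ``gene_set`` that are present."""
    present = [g for g in gene_set.genes if g in set(expr.gene_ids)]
    absent = [g for g in gene_set.genes if g not in set(expr.gene_ids)]
    if absent:
        logger.info(
            "gene set %s: %d gene(s) absent from matrix, dropped: %s",
            gene_set.name, len(absent), ",".join(absent),
        )
    idx = [expr.gene_ids.index(g) for g in present]
    return expr.values[:, idx], expr.mask[:, idx], present


def extract_pair(
    expr: ExpressionMatrix,
    predictor: GeneSet,
    target: GeneSet,
    missing_policy: str = "drop_gene",
) -> PairedGeneSetData:
    """Extract the aligned predictor/target blocks for one gene-set pair.

    ``missing_policy`` controls missing values: ``drop_gene`` removes any gene
    with a missing value (only probes with complete data are used),
    ``drop_sample`` removes samples with a missing value in either block, and
    ``reject`` raises on any missingness.  Genes absent from the matrix are
    dropped and logged under every policy.
    """
    xv, xm, xg = _select_block(expr, predictor)
    yv, ym, yg = _select_block(expr, target)
    keep_rows = np.ones(expr.n_samples, dtype=bool)
    if missing_policy == "drop_gene":
        xk = ~xm.any(axis=0)
        yk = ~ym.any(axis=0)
        dropped = [g for g, k in zip(xg + yg, np.r_[xk, yk]) if not k]
        if dropped:
            logger.info("dropped %d gene(s) with missing values: %s",
                        len(dropped), ",".join(dropped))
        xv, yv = xv[:, xk], yv[:, yk]
    elif missing_policy == "drop_sample":
        keep_rows = ~(xm.any(axis=1) | ym.any(axis=1))
        xv, yv = xv[keep_rows], yv[keep_rows]
    elif missing_policy == "reject":
        if xm.any() or ym.any():
            raise ValueError("missing values present and policy is 'reject'")
    else:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    if xv.shape[1] == 0 or yv.shape[1] == 0:
        raise ValueError(
            f"empty gene set block for pair ({predictor.name}, {target.name})"
        )
    sample_ids = [s for s, k in zip(expr.sample_ids, keep_rows) if k]
    return PairedGeneSetData(X=xv, Y=yv, sample_ids=sample_ids)
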