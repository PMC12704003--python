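"""Gene-gene optimal transport distances over the cell graph.

Each gene's expression vector is normalized into a probability distribution
over cells; the distance between two genes is the optimal-transport cost of
morphing one distribution into the other, with the geodesic cell-cell
distances as ground cost.  Zero-mass cells cannot receive or emit mass, so
each problem is restricted to the two genes' expressing-cell supports
without changing the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._emd import emd
from .containers import ExpressionMatrix, GeneSet

__all__ = [
    "GeneDistribution",
    "GeneDistanceMatrix",
    "gene_distribution",
    "ot_distance",
    "pairwise_ot",
]


@dataclass
class GeneDistribution:
    """A gene's expression as a probability distribution over cells."""

    gene_id: str
    support: np.ndarray  # cell indices with positive expression
    mass: np.ndarray  # positive, sums to 1

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=int)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.support.size != self.mass.size:
            raise ValueError("support and mass must align")
        if np.unique(self.support).size != self.support.size:
            raise ValueError("repeated cells in support")
        if np.any(self.mass <= 0):
            raise ValueError("mass must be positive on the support")
        if abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError("mass must sum to 1")


@dataclass
class GeneDistanceMatrix:
    """Symmetric gene x gene transport distance matrix."""

    D: np.ndarray
    gene_ids: list[str]
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise ValueError("D shape does not match gene_ids")

    def submatrix(self, gene_ids: list[str]) -> "GeneDistanceMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return GeneDistanceMatrix(
            self.D[np.ix_(idx, idx)], list(gene_ids), self.condition_label
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.gene_ids, columns=self.gene_ids)

    @classmethod
    def from_tsv(cls, path: str, condition_label: str = "") -> "GeneDistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), [str(g) for g in df.index], condition_label)

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t")


def gene_distribution(expr: ExpressionMatrix, gene_id: str) -> GeneDistribution:
    """Normalize one gene's expression into a distribution over cells."""
    row = expr.values[expr.gene_index(gene_id)]
    support = np.flatnonzero(row > 0)
    if support.size == 0:
        raise ValueError(f"gene {gene_id!r} has no expressing cells")
    mass = row[support]
    mass = mass / mass.sum()
    return GeneDistribution(gene_id, support, mass)


def ot_distance(gi: GeneDistribution, gj: GeneDistribution, C: np.ndarray) -> float:
    """Exact transport cost between two gene distributions.

    The problem is solved on the cost submatrix of the two supports; cells
    with zero mass are irrelevant to the optimum.
    """
    n = C.shape[0]
    if gi.support.max() >= n or gj.support.max() >= n:
        raise ValueError("gene supports index outside the cost matrix")
    sub = C[np.ix_(gi.support, gj.support)]
    return emd(gi.mass, gj.mass, sub)


def pairwise_ot(
    expr: ExpressionMatrix,
    genes: GeneSet | list[str],
    C: np.ndarray,
    n_workers: int = 1,
) -> GeneDistanceMatrix:
    """All pairwise gene transport distances.

    The result is independent of ``n_workers`` (pairs are chunked
    deterministically and reassembled in order).
    """
    gene_ids = list(genes)
    zero = [g for g in gene_ids if not np.any(expr.values[expr.gene_index(g)] > 0)]
    if zero:
        raise ValueError(f"genes with no expressing cells (drop them first): {zero}")
    dists = [gene_distribution(expr, g) for g in gene_ids]
    p = len(gene_ids)
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]

    def _solve_pair(i: int, j: int) -> float:
        return ot_distance(dists[i], dists[j], C)

    if n_workers > 1 and len(pairs) > 1:
        from joblib import Parallel, delayed

        chunks = np.array_split(np.arange(len(pairs)), n_workers * 4)
        results = Parallel(n_jobs=n_workers)(
            delayed(lambda idxs: [_solve_pair(*pairs[t]) for t in idxs])(chunk)
            for chunk in chunks
        )
        flat = [v for chunk in results for v in chunk]
    else:
        flat = [_solve_pair(i, j) for i, j in pairs]
    D = np.zeros((p, p))
    for (i, j), v in zip(pairs, flat):
        D[i, j] = D[j, i] = v
    return GeneDistanceMatrix(D, gene_ids, expr.condition_label)
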