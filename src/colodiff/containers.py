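"""Core in-memory containers for two-condition single-cell analysis.

Matrices are oriented genes x cells throughout the package.  The two
conditions are never merged cell-wise: each condition keeps its own
:class:`CountMatrix` / :class:`ExpressionMatrix`, and only gene identifiers
are joined across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} ID: {dup!r}")


@dataclass
class CountMatrix:
    """Raw UMI counts, genes x cells, with string identifiers.

    Parameters
    ----------
    values
        Non-negative integer matrix of shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Ordered unique identifiers for the rows / columns.
    condition_label
        Free-text label of the biological condition or batch.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.values.size == 0:
            raise ValueError("need at least 1 gene and 1 cell")
        if np.issubdtype(self.values.dtype, np.floating):
            if not np.all(self.values == np.floor(self.values)):
                raise ValueError("counts must be integral")
            self.values = self.values.astype(np.int64)
        if self.values.min() < 0:
            raise ValueError("counts must be non-negative")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not present") from None


@dataclass
class ExpressionMatrix:
    """Log-normalized expression, genes x cells.

    Entries are ``ln(1 + count / cell_total * scale_factor)``; an entry is
    zero iff the underlying count is zero.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    scale_factor: float = 1e4
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("shape does not match gene/cell IDs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.values.size and self.values.min() < 0:
            raise ValueError("log-normalized expression must be non-negative")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not present") from None

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in gene_ids]
        return ExpressionMatrix(
            self.values[idx],
            [self.gene_ids[i] for i in idx],
            self.cell_ids,
            self.scale_factor,
            self.condition_label,
        )


@dataclass
class GeneSet:
    """An ordered (lexicographic) set of gene IDs with filter provenance.

    ``provenance[g]`` records which condition(s) admitted gene ``g`` and
    which filters it passed there.
    """

    gene_ids: list[str]
    provenance: dict[str, dict[str, bool]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.gene_ids, "gene")
        self.gene_ids = sorted(self.gene_ids)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.gene_ids)
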