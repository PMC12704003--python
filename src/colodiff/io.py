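"""Reading, writing, normalization and gene filtering.

Supported on-disk layouts:

* 10x-style Matrix-Market triplet: ``matrix.mtx`` (1-based gene,cell,count
  triplets) next to ``features.tsv`` and ``barcodes.tsv``;
* dense TSV with gene rows, cell columns and a header row of cell IDs.

Gene filtering for the transport analysis follows the two-condition rule:
within each condition keep genes expressed in a bounded fraction of cells
(default 0.5%-50%) that also rank among that condition's top highly
variable genes; take the union across conditions; drop genes with zero
detected cells in either condition.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CountMatrix, ExpressionMatrix, GeneSet

__all__ = [
    "load_counts",
    "write_counts",
    "log_normalize",
    "hvg_ranking",
    "select_analysis_genes",
]


def _read_ids(path: str, what: str) -> list[str]:
    ids = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} IDs in {path}")
    return ids


def load_counts(path: str, fmt: str = "mtx_triplet", condition_label: str = "") -> CountMatrix:
    """Load a raw count matrix from ``path``.

    For ``mtx_triplet``, ``path`` is a directory containing ``matrix.mtx``,
    ``features.tsv`` and ``barcodes.tsv``.  For ``dense_tsv``, ``path`` is a
    TSV file with gene rows and a header row of cell IDs.
    """
    if fmt == "mtx_triplet":
        mtx = os.path.join(path, "matrix.mtx")
        try:
            mat = spio.mmread(mtx)
        except Exception as exc:  # noqa: BLE001 - surface the offending file
            raise ValueError(f"malformed Matrix-Market file {mtx}: {exc}") from exc
        coo = sparse.coo_matrix(mat)
        pairs = np.stack([coo.row, coo.col])
        uniq, counts = np.unique(pairs, axis=1, return_counts=True)
        if counts.max(initial=0) > 1:
            g, c = uniq[:, np.argmax(counts)]
            raise ValueError(
                f"duplicate triplet entry for (gene {g + 1}, cell {c + 1}) in {mtx}"
            )
        dense = np.asarray(coo.todense())
        if not np.all(dense == np.floor(dense)):
            bad = np.argwhere(dense != np.floor(dense))[0]
            raise ValueError(f"non-integer count at (gene {bad[0] + 1}, cell {bad[1] + 1})")
        genes = _read_ids(os.path.join(path, "features.tsv"), "gene")
        cells = _read_ids(os.path.join(path, "barcodes.tsv"), "cell")
        if dense.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {dense.shape} does not match "
                f"{len(genes)} features x {len(cells)} barcodes"
            )
        return CountMatrix(dense.astype(np.int64), genes, cells, condition_label)
    if fmt == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        vals = df.to_numpy()
        if not np.all(vals == np.floor(vals)):
            raise ValueError(f"non-integer count in {path}")
        return CountMatrix(
            vals.astype(np.int64),
            [str(g) for g in df.index],
            [str(c) for c in df.columns],
            condition_label,
        )
    raise ValueError(f"unknown format {fmt!r}; expected 'mtx_triplet' or 'dense_tsv'")


def write_counts(counts: CountMatrix, path: str, fmt: str = "mtx_triplet") -> None:
    """Write ``counts`` so that :func:`load_counts` round-trips exactly."""
    if fmt == "mtx_triplet":
        os.makedirs(path, exist_ok=True)
        spio.mmwrite(os.path.join(path, "matrix.mtx"), sparse.coo_matrix(counts.values))
        pd.Series(counts.gene_ids).to_csv(
            os.path.join(path, "features.tsv"), sep="\t", header=False, index=False
        )
        pd.Series(counts.cell_ids).to_csv(
            os.path.join(path, "barcodes.tsv"), sep="\t", header=False, index=False
        )
    elif fmt == "dense_tsv":
        pd.DataFrame(counts.values, index=counts.gene_ids, columns=counts.cell_ids).to_csv(
            path, sep="\t"
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def log_normalize(counts: CountMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """Library-size normalize and log-transform.

    entry = ln(1 + count / cell_total * scale_factor).  Cells with zero
    total count cannot be normalized and are rejected.
    """
    totals = counts.values.sum(axis=0)
    if np.any(totals == 0):
        bad = [counts.cell_ids[i] for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"cells with zero total count: {bad}")
    vals = np.log1p(counts.values / totals[None, :] * scale_factor)
    return ExpressionMatrix(
        vals, counts.gene_ids, counts.cell_ids, scale_factor, counts.condition_label
    )


def hvg_ranking(expr: ExpressionMatrix, n_bins: int = 20) -> pd.Series:
    """Rank genes by standardized dispersion (most variable first).

    The dispersion statistic is the variance/mean ratio of the de-logged
    expression, standardized (z-scored) within ``n_bins`` mean-expression
    bins, as in the classic Seurat variable-feature procedure.  Ties are
    broken by gene ID so the ranking is deterministic.

    Returns a Series mapping gene ID -> rank (0 = most variable).
    """
    x = np.expm1(expr.values)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1) if expr.n_cells > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    df = pd.DataFrame({"mean": mean, "disp": disp}, index=expr.gene_ids)
    # log-scale the dispersion before binning, as the reference procedure does
    df["disp"] = np.log(df["disp"].where(df["disp"] > 0, np.nan))
    df["mean"] = np.log1p(df["mean"])
    try:
        df["bin"] = pd.cut(df["mean"], bins=n_bins, duplicates="drop")
    except ValueError:
        df["bin"] = 0
    grouped = df.groupby("bin", observed=True)["disp"]
    mu = grouped.transform("mean")
    sd = grouped.transform("std")
    z = (df["disp"] - mu) / sd.replace(0.0, np.nan)
    z = z.fillna(0.0)
    order = sorted(expr.gene_ids, key=lambda g: (-z[g], g))
    return pd.Series({g: r for r, g in enumerate(order)})


def _per_condition_pass(
    expr: ExpressionMatrix, n_hvg: int, min_frac: float, max_frac: float
) -> dict[str, dict[str, bool]]:
    frac = (expr.values > 0).mean(axis=1)
    in_band = (frac >= min_frac) & (frac <= max_frac)
    ranks = hvg_ranking(expr)
    record: dict[str, dict[str, bool]] = {}
    for i, g in enumerate(expr.gene_ids):
        record[g] = {
            "frequency_band": bool(in_band[i]),
            "hvg": bool(ranks[g] < n_hvg),
            "detected": bool(frac[i] > 0),
        }
    return record


def select_analysis_genes(
    expr1: ExpressionMatrix,
    expr2: ExpressionMatrix,
    n_hvg: int = 500,
    min_frac: float = 0.005,
    max_frac: float = 0.5,
    extra_genes: list[str] | None = None,
) -> GeneSet:
    """Select the gene set used for transport analysis.

    Union of the per-condition sets {frequency in [min_frac, max_frac] and
    among the top ``n_hvg`` variable genes}, minus genes undetected in
    either condition.  ``extra_genes`` (e.g. genes perturbed by a benchmark
    simulation) are added to the union but still must be detected in both
    conditions.
    """
    shared = sorted(set(expr1.gene_ids) & set(expr2.gene_ids))
    if not shared:
        raise ValueError("the two conditions share no gene IDs")
    e1 = expr1.subset_genes(shared)
    e2 = expr2.subset_genes(shared)
    rec1 = _per_condition_pass(e1, n_hvg, min_frac, max_frac)
    rec2 = _per_condition_pass(e2, n_hvg, min_frac, max_frac)
    extra = set(extra_genes or []) & set(shared)
    selected = []
    provenance = {}
    for g in shared:
        p1 = rec1[g]["frequency_band"] and rec1[g]["hvg"]
        p2 = rec2[g]["frequency_band"] and rec2[g]["hvg"]
        detected = rec1[g]["detected"] and rec2[g]["detected"]
        if detected and (p1 or p2 or g in extra):
            selected.append(g)
            provenance[g] = {
                "condition1": p1,
                "condition2": p2,
                "extra": g in extra,
            }
    if not selected:
        raise ValueError(
            "no genes pass the filters; loosen min_frac/max_frac or raise n_hvg"
        )
    return GeneSet(selected, provenance)
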