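"""Grouping significant genes into co-localized modules.

Significant genes are clustered on their transport-distance submatrix by
average-linkage hierarchical clustering with an adaptive (dynamic) cut:
the dendrogram's merge heights are scanned inside a window set by the
``deep_split`` level, and the cut producing the most clusters of at least
``min_size`` genes is kept.  Within each module, genes whose mean
intra-module distance exceeds median + 3 x MAD are removed as outliers
(MAD with the 1.4826 normal-consistency constant, single pass), and
modules that fall below the minimum size are dropped.

Module importance weights each module by the spectral rank of its genes:
every gene is uniquely assigned to the highest-ranked eigenvector in which
it is significant, c_{m,l} is the fraction of module m assigned to
eigenvector l, and w_m = sum_l c_{m,l} * lambda_hat_l with eigenvalues
normalized to sum to one over the selected components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix
from .spectral import SpectralResult
from .transport import GeneDistanceMatrix

__all__ = ["GeneModule", "ModuleSet", "assemble_modules", "module_importance", "module_activity"]

MAD_CONSTANT = 1.4826


@dataclass
class GeneModule:
    module_id: str
    gene_ids: list[str]
    eigenvector_fractions: dict[int, float] = field(default_factory=dict)
    importance: float = float("nan")

    @property
    def size(self) -> int:
        return len(self.gene_ids)


@dataclass
class ModuleSet:
    modules: list[GeneModule]
    outlier_genes: list[str]
    direction: str = ""

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)


def _dynamic_cut(Z: np.ndarray, n: int, min_size: int, deep_split: int) -> np.ndarray:
    """Adaptive static-height cut of a linkage matrix.

    Scans candidate cut heights (the merge heights inside a window mapped
    from ``deep_split``: deeper splits scan lower heights) and keeps the
    cut with the most clusters of size >= min_size; ties prefer lower
    heights (finer splits) at deep_split >= 2 and higher heights otherwise.
    Genes in clusters below min_size get label 0 (unassigned).
    """
    heights = Z[:, 2]
    hi_q = 1.0 - 0.05 * deep_split  # deep_split 0..4 -> upper quantile 1.0..0.8
    lo_q = 0.05
    lo, hi = np.quantile(heights, [lo_q, hi_q])
    candidates = np.unique(heights[(heights >= lo) & (heights <= hi)])
    if candidates.size == 0:
        candidates = np.unique(heights)
    best_labels = None
    best_score = -1
    order = candidates if deep_split >= 2 else candidates[::-1]
    for h in order:
        labels = fcluster(Z, t=h * (1 + 1e-12), criterion="distance")
        sizes = np.bincount(labels)
        score = int(np.sum(sizes[1:] >= min_size))
        if score > best_score:
            best_score = score
            best_labels = labels
    assert best_labels is not None
    keep = {c for c in np.unique(best_labels) if np.sum(best_labels == c) >= min_size}
    out = np.zeros(n, dtype=int)
    relabel = {c: i + 1 for i, c in enumerate(sorted(keep))}
    for i, c in enumerate(best_labels):
        out[i] = relabel.get(c, 0)
    return out


def assemble_modules(
    significant_genes: list[str],
    D_sub: GeneDistanceMatrix,
    min_size: int = 5,
    outlier_mads: float = 3.0,
    deep_split: int = 0,
    direction: str = "",
) -> ModuleSet:
    """Cluster significant genes into modules on their transport distances."""
    genes = sorted(significant_genes)
    if len(genes) < min_size:
        warnings.warn(
            f"only {len(genes)} significant genes (< min_size={min_size}); "
            "returning an empty module set",
            stacklevel=2,
        )
        return ModuleSet([], [], direction)
    sub = D_sub.submatrix(genes)
    d = 0.5 * (sub.D + sub.D.T)
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    labels = _dynamic_cut(Z, len(genes), min_size, deep_split)
    modules: list[GeneModule] = []
    outliers: list[str] = []
    for c in sorted(set(labels) - {0}):
        members = [i for i in range(len(genes)) if labels[i] == c]
        if len(members) >= 2:
            dd = d[np.ix_(members, members)]
            mean_intra = dd.sum(axis=1) / (len(members) - 1)
            med = np.median(mean_intra)
            mad = MAD_CONSTANT * np.median(np.abs(mean_intra - med))
            bad = mean_intra > med + outlier_mads * mad if mad > 0 else np.zeros(
                len(members), dtype=bool
            )
            outliers.extend(genes[members[i]] for i in np.flatnonzero(bad))
            members = [m for m, b in zip(members, bad) if not b]
        if len(members) >= min_size:
            modules.append(
                GeneModule(f"M{len(modules) + 1}", [genes[i] for i in members])
            )
    return ModuleSet(modules, sorted(outliers), direction)


def module_importance(module_set: ModuleSet, spec_result: SpectralResult) -> ModuleSet:
    """Fill per-module eigenvector fractions and importance scores.

    Modules are returned sorted by importance, descending.
    """
    assign = spec_result.gene_to_eigenvector()
    k = spec_result.knee
    lam = spec_result.eigenvalues[:k]
    lam_hat = lam / lam.sum() if lam.sum() != 0 else np.full(k, 1.0 / max(k, 1))
    for mod in module_set.modules:
        missing = [g for g in mod.gene_ids if g not in assign]
        if missing:
            raise ValueError(
                f"module {mod.module_id} contains genes with no contributing "
                f"eigenvector: {missing}"
            )
        counts = np.zeros(k)
        for g in mod.gene_ids:
            counts[assign[g]] += 1
        frac = counts / counts.sum()
        mod.eigenvector_fractions = {
            ell: float(frac[ell]) for ell in range(k) if frac[ell] > 0
        }
        mod.importance = float(np.dot(frac, lam_hat))
    module_set.modules.sort(key=lambda m: (-m.importance, m.module_id))
    for i, mod in enumerate(module_set.modules):
        mod.module_id = f"M{i + 1}"
    return module_set


def module_activity(
    expr: ExpressionMatrix,
    module_genes: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    control_scheme: str = "binned",
) -> np.ndarray:
    """Per-cell activity of a gene module, scaled to [0, 1].

    ``binned`` (default): mean module-gene expression minus the mean of
    control genes sampled from matching average-expression bins (the
    standard seeded control-gene scheme).  ``mean``: plain mean module
    expression.  The raw score is z-normalized across cells and min-max
    scaled; a constant raw score yields all zeros.
    """
    if not module_genes:
        raise ValueError("empty module")
    idx = [expr.gene_index(g) for g in module_genes]
    raw = expr.values[idx].mean(axis=0)
    if control_scheme == "binned":
        rng = np.random.default_rng(seed)
        avg = expr.values.mean(axis=1)
        order = np.argsort(avg, kind="stable")
        bin_of = np.empty(expr.n_genes, dtype=int)
        bins = np.array_split(order, min(n_bins, expr.n_genes))
        for b, members in enumerate(bins):
            bin_of[members] = b
        ctrl_idx: list[int] = []
        for gi in idx:
            pool = np.flatnonzero(bin_of == bin_of[gi])
            ctrl_idx.extend(rng.choice(pool, size=min(n_ctrl, pool.size), replace=True))
        raw = raw - expr.values[ctrl_idx].mean(axis=0)
    elif control_scheme != "mean":
        raise ValueError(f"unknown control scheme {control_scheme!r}")
    sd = raw.std(ddof=0)
    if sd == 0:
        return np.zeros(expr.n_cells)
    zscore = (raw - raw.mean()) / sd
    lo, hi = zscore.min(), zscore.max()
    return (zscore - lo) / (hi - lo)
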