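"""Benchmark evaluation: gene ranking, normalized AUPRC, robustness sweeps.

The benchmark metric is average precision rescaled for class imbalance:
AUPRC_norm = (AUPRC - p) / (1 - p) with p the positive fraction, so that a
random ranking scores ~0 and a perfect one exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import SpectralResult

__all__ = [
    "RankedGeneList",
    "BenchmarkResult",
    "rank_genes",
    "average_precision",
    "normalized_auprc",
    "jaccard_index",
    "robustness_sweep",
]


@dataclass
class RankedGeneList:
    gene_ids: list[str]  # best first
    scores: np.ndarray  # descending

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_ids) != self.scores.size:
            raise ValueError("gene_ids and scores must align")


@dataclass
class BenchmarkResult:
    auprc: float
    positive_fraction: float
    normalized_auprc: float


def rank_genes(spec_result: SpectralResult, use_all_selected: bool = False) -> RankedGeneList:
    """Rank genes by absolute loading of the first eigenvector.

    ``use_all_selected`` ranks by the maximum absolute loading across all
    knee-selected eigenvectors instead.  Ties break lexicographically by
    gene ID so rankings are deterministic.
    """
    if spec_result.eigenvectors.shape[1] < 1:
        raise ValueError("no eigenvectors available")
    if use_all_selected and spec_result.knee > 1:
        score = np.abs(spec_result.eigenvectors[:, : spec_result.knee]).max(axis=1)
    else:
        score = np.abs(spec_result.eigenvectors[:, 0])
    order = sorted(range(len(score)), key=lambda i: (-score[i], spec_result.gene_ids[i]))
    return RankedGeneList([spec_result.gene_ids[i] for i in order], score[order])


def average_precision(ranked_ids: list[str], positives: set[str]) -> float:
    """Step-wise average precision: mean of precision at each positive's rank."""
    hits = 0
    total = 0.0
    for rank, g in enumerate(ranked_ids, start=1):
        if g in positives:
            hits += 1
            total += hits / rank
    if hits == 0:
        return 0.0
    return total / len(positives)


def normalized_auprc(ranking: RankedGeneList, positives) -> BenchmarkResult:
    """Class-imbalance-corrected AUPRC of a ranking."""
    pos = set(positives)
    ranked = ranking.gene_ids
    if not pos or not pos.issubset(set(ranked)) or len(pos) >= len(ranked):
        raise ValueError("positives must be a nonempty proper subset of the ranked genes")
    ap = average_precision(ranked, pos)
    p = len(pos) / len(ranked)
    return BenchmarkResult(ap, p, (ap - p) / (1 - p))


def jaccard_index(a, b) -> float:
    """|a & b| / |a | b|; 1.0 for two empty sets by convention."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


def robustness_sweep(
    counts1,
    counts2,
    settings: list[dict],
    default_setting: dict | None = None,
    **pipeline_kwargs,
):
    """Significant-gene stability across graph-construction settings.

    Runs the full pipeline at the default setting and at every setting in
    ``settings`` (dicts of pipeline parameter overrides, e.g. ``{"k": 15}``
    or ``{"embedding": "pca"}``), and reports the Jaccard index of each
    setting's significant gene sets (both directions pooled) against the
    default's.  Returns a list of dicts, one per setting.
    """
    from .pipeline import PipelineConfig, run_pipeline

    def _sig(overrides: dict) -> set[str]:
        cfg = PipelineConfig(**{**pipeline_kwargs, **overrides})
        res = run_pipeline(counts1, counts2, cfg)
        return set(res.spectral["1_vs_2"].significant_genes) | set(
            res.spectral["2_vs_1"].significant_genes
        )

    base = _sig(default_setting or {})
    rows = []
    for s in settings:
        sig = _sig(s)
        rows.append(
            {
                "setting": dict(s),
                "n_significant": len(sig),
                "jaccard_vs_default": jaccard_index(sig, base),
            }
        )
    return rows
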