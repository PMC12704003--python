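"""End-to-end orchestration of the three-step workflow.

Step 1: per-condition cell graph -> geodesic cost matrix -> pairwise gene
transport distances.  Step 2: adaptive kernels, normalized operators and
the two directional differential operators.  Step 3: spectral selection
and local-FDR gene calling, followed by module assembly and importance
scoring.  Both directions are always computed; swapping the two input
conditions exactly swaps the direction labels of the outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .graph import cost_matrix, embed_cells, knn_graph
from .io import log_normalize, select_analysis_genes
from .modules import ModuleSet, assemble_modules, module_importance
from .spectral import (
    SpectralResult,
    adaptive_kernel,
    differential_operator,
    normalized_operator,
    spectral_select,
)
from .transport import GeneDistanceMatrix, pairwise_ot

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "save_result"]


@dataclass
class PipelineConfig:
    embedding: str = "diffusion_map"
    n_components: int | str = 10
    k: int = 10
    n_hvg: int = 500
    min_frac: float = 0.005
    max_frac: float = 0.5
    k_local: int = 10
    fdr_threshold: float = 0.2
    min_module_size: int = 5
    deep_split: int = 0
    scale_factor: float = 1e4
    n_workers: int = 1
    seed: int = 0
    extra_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    gene_ids: list[str]
    distances: dict[str, GeneDistanceMatrix]  # "cond1", "cond2"
    spectral: dict[str, SpectralResult]  # "1_vs_2", "2_vs_1"
    modules: dict[str, ModuleSet]
    config: PipelineConfig
    condition_labels: tuple[str, str]


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc


def run_pipeline(
    counts1: CountMatrix,
    counts2: CountMatrix,
    config: PipelineConfig | None = None,
    precomputed_distances: dict[str, GeneDistanceMatrix] | None = None,
) -> PipelineResult:
    """Run the full differential co-localization analysis on two conditions.

    ``precomputed_distances`` ({"cond1": ..., "cond2": ...}) skips the
    transport stage, e.g. to reuse distance matrices cached by an earlier
    run; they must cover the selected gene set.
    """
    cfg = config or PipelineConfig()
    expr1 = _stage("log_normalize(cond1)", log_normalize, counts1, cfg.scale_factor)
    expr2 = _stage("log_normalize(cond2)", log_normalize, counts2, cfg.scale_factor)
    genes = _stage(
        "select_analysis_genes",
        select_analysis_genes,
        expr1,
        expr2,
        n_hvg=cfg.n_hvg,
        min_frac=cfg.min_frac,
        max_frac=cfg.max_frac,
        extra_genes=cfg.extra_genes or None,
    )
    distances: dict[str, GeneDistanceMatrix] = {}
    for tag, expr in (("cond1", expr1), ("cond2", expr2)):
        if precomputed_distances is not None:
            cached = precomputed_distances[tag]
            missing = set(genes) - set(cached.gene_ids)
            if missing:
                raise ValueError(
                    f"precomputed distances for {tag} lack genes: {sorted(missing)[:5]}..."
                )
            distances[tag] = cached.submatrix(list(genes))
            continue
        emb = _stage(
            f"embed_cells({tag})", embed_cells, expr, cfg.embedding, cfg.n_components
        )
        g = _stage(f"knn_graph({tag})", knn_graph, emb, cfg.k)
        C = _stage(f"cost_matrix({tag})", cost_matrix, g)
        distances[tag] = _stage(
            f"pairwise_ot({tag})", pairwise_ot, expr, genes, C, cfg.n_workers
        )
    L = {}
    for tag in ("cond1", "cond2"):
        K = _stage(f"adaptive_kernel({tag})", adaptive_kernel, distances[tag], cfg.k_local)
        L[tag] = _stage(f"normalized_operator({tag})", normalized_operator, K)
    spectral: dict[str, SpectralResult] = {}
    modules: dict[str, ModuleSet] = {}
    for direction, num, den in (("1_vs_2", "cond1", "cond2"), ("2_vs_1", "cond2", "cond1")):
        Q = _stage(
            f"differential_operator({direction})",
            differential_operator,
            L[num],
            L[den],
            direction,
        )
        spec = _stage(
            f"spectral_select({direction})", spectral_select, Q, cfg.fdr_threshold
        )
        spectral[direction] = spec
        if len(spec.significant_genes) >= cfg.min_module_size:
            mods = _stage(
                f"assemble_modules({direction})",
                assemble_modules,
                spec.significant_genes,
                distances[num],
                cfg.min_module_size,
                deep_split=cfg.deep_split,
                direction=direction,
            )
            if mods.modules:
                mods = _stage(
                    f"module_importance({direction})", module_importance, mods, spec
                )
            modules[direction] = mods
        else:
            modules[direction] = ModuleSet([], [], direction)
    return PipelineResult(
        gene_ids=list(genes),
        distances=distances,
        spectral=spectral,
        modules=modules,
        config=cfg,
        condition_labels=(counts1.condition_label, counts2.condition_label),
    )


def save_result(result: PipelineResult, out_dir: str) -> None:
    """Serialize a pipeline result to TSV/JSON files under ``out_dir``.

    Layout: distances/ (gene distance matrices), spectra/ (eigenvalues and
    per-gene tables per direction), modules/ (membership and summaries),
    provenance.json (config, labels, regularizers).
    """
    for sub in ("distances", "spectra", "modules"):
        os.makedirs(os.path.join(out_dir, sub), exist_ok=True)
    for tag, D in result.distances.items():
        D.to_tsv(os.path.join(out_dir, "distances", f"{tag}.tsv"))
    for direction, spec in result.spectral.items():
        pd.DataFrame(
            {"eigenvalue": spec.eigenvalues, "selected": np.arange(len(spec.eigenvalues)) < spec.knee}
        ).to_csv(os.path.join(out_dir, "spectra", f"{direction}_eigenvalues.tsv"), sep="\t", index_label="rank")
        rows = []
        for ell, res in enumerate(spec.locfdr):
            for i, g in enumerate(spec.gene_ids):
                rows.append(
                    {
                        "gene": g,
                        "eigenvector": ell,
                        "loading": spec.eigenvectors[i, ell],
                        "z": res.z[i],
                        "local_fdr": res.fdr[i],
                        "significant": bool(res.significant[i]),
                    }
                )
        pd.DataFrame(rows).to_csv(
            os.path.join(out_dir, "spectra", f"{direction}_genes.tsv"), sep="\t", index=False
        )
    for direction, mods in result.modules.items():
        member_rows = [
            {"gene": g, "module": m.module_id, "direction": direction}
            for m in mods
            for g in m.gene_ids
        ]
        pd.DataFrame(member_rows, columns=["gene", "module", "direction"]).to_csv(
            os.path.join(out_dir, "modules", f"{direction}_membership.tsv"), sep="\t", index=False
        )
        summary_rows = [
            {"module": m.module_id, "size": m.size, "importance": m.importance}
            for m in mods
        ]
        pd.DataFrame(summary_rows, columns=["module", "size", "importance"]).to_csv(
            os.path.join(out_dir, "modules", f"{direction}_summary.tsv"), sep="\t", index=False
        )
    prov = {
        "config": result.config.to_dict(),
        "condition_labels": list(result.condition_labels),
        "n_genes_analyzed": len(result.gene_ids),
        "c_reg": {d: s.c_reg for d, s in result.spectral.items()},
        "knee": {d: int(s.knee) for d, s in result.spectral.items()},
        "significant_genes": {d: s.significant_genes for d, s in result.spectral.items()},
    }
    with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)
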