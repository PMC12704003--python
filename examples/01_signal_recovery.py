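"""Recover an injected co-localized gene group from a two-condition benchmark.

Builds a synthetic dataset (two 500-cell conditions split from one
population; 15 genes confined to a neighborhood of 10% of condition 2's
cells), runs the full analysis, and scores the gene ranking against the
known truth.
"""

import colodiff as cd

ds = cd.simulate_benchmark(
    cd.SimulationConfig(seed=0, background=cd.BackgroundParams(n_genes=400, n_cells=500))
)
print(f"conditions: {ds.counts1.n_cells} + {ds.counts2.n_cells} cells, "
      f"{ds.counts1.n_genes} genes, {len(ds.truth_genes)} injected")

res = cd.run_pipeline(
    ds.counts1, ds.counts2, cd.PipelineConfig(n_hvg=60, extra_genes=ds.truth_genes)
)

spec = res.spectral["2_vs_1"]  # direction: co-localized in condition 2, not 1
print(f"analyzed genes: {len(res.gene_ids)}")
print(f"knee-selected components: {spec.knee}")
print(f"top eigenvalues: {spec.eigenvalues[:4].round(2)}")

ranking = cd.rank_genes(spec)
truth = [g for g in ds.truth_genes if g in ranking.gene_ids]
bench = cd.normalized_auprc(ranking, truth)
print(f"normalized AUPRC: {bench.normalized_auprc:.3f}")
# A single eigenvalue far above the rest is the injected signal; normalized
# AUPRC 1.0 means every injected gene outranks every background gene
# (0 would be random ordering).
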