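# colodiff

Cluster-free, integration-free detection of **differential gene
co-localization** between two single-cell RNA-seq conditions.

## The problem

Two scRNA-seq experiments — a perturbation and a control, a mutant and a
wild type — often differ not in which genes are expressed overall, but in
*where* on the cell manifold groups of genes are coordinately active.  A
gene program may be confined to a small neighborhood of transcriptomically
similar cells in one condition and dispersed in the other.  Standard
differential co-expression tools compare correlations within predefined
cell clusters and miss signals confined to small subpopulations; cluster-
free differential expression tools require integrating the two conditions
into one latent space, which batch effects and genuine biological shifts
can distort.

`colodiff` avoids both requirements.  Each condition is analyzed on its
own cell manifold:

1. **Gene–gene optimal transport (OT).**  For condition $k$, a kNN graph
   over the cells (built in a diffusion-map or PCA embedding) defines a
   geodesic cost matrix $C^{(k)}$ of shortest-path distances.  Each gene's
   expression vector, normalized to sum to one, is a probability
   distribution over cells, and the distance between genes $i,j$ is the
   exact transport cost
   $D^{(k)}_{ij} = \min_{T\ge 0,\,T\mathbf 1 = g_i,\,T^\top\mathbf 1 = g_j} \sum_{a,b} T_{ab}\,C^{(k)}_{ab}.$
   Genes active in overlapping neighborhoods are close; genes active in
   distal subpopulations are far.
2. **Differential graph operators.**  $D^{(k)}$ becomes a locally adaptive
   Gaussian kernel $K^{(k)}$ and a symmetric normalized operator
   $L^{(k)} = A^{-1/2} K^{(k)} A^{-1/2}$.  Gene sets strongly connected in
   condition 1 but not condition 2 maximize the generalized Rayleigh
   quotient $v^\top L^{(1)} v \,/\, v^\top (L^{(2)} + c I) v$, computed
   stably through the symmetric operator
   $Q^{(1)} = (L^{(2)}+cI)^{-1/2} L^{(1)} (L^{(2)}+cI)^{-1/2}$
   (and symmetrically $Q^{(2)}$ for the opposite direction).
3. **Spectral gene selection.**  The number of informative eigenvectors of
   $Q$ is chosen at the knee of its eigenvalue spectrum; each selected
   eigenvector's loadings are z-transformed and genes are called by local
   false discovery rate under a standard-normal null.  Significant genes
   are grouped into co-localized modules by average-linkage clustering of
   their OT distances with an adaptive tree cut, scored by spectral
   importance $w_m = \sum_\ell c_{m,\ell}\, \hat\lambda_\ell$, and mapped
   back onto cells via module activity scores.

The package also ships the full synthetic benchmark: negative-binomial
two-condition backgrounds, neighborhood-confined signal injection, the
six-module demonstration layout, normalized-AUPRC evaluation and
graph-parameter robustness sweeps.

## Worked example

```python
import colodiff as cd

# a synthetic benchmark: two 500-cell conditions sharing one manifold,
# 15 genes confined to a 10%-of-cells neighborhood in condition 2
ds = cd.simulate_benchmark(cd.SimulationConfig(
    seed=0, background=cd.BackgroundParams(n_genes=400, n_cells=500)))

res = cd.run_pipeline(ds.counts1, ds.counts2,
                      cd.PipelineConfig(n_hvg=60, extra_genes=ds.truth_genes))

spec = res.spectral["2_vs_1"]          # direction: stronger in condition 2
print(spec.knee, spec.eigenvalues[:4].round(2))
ranking = cd.rank_genes(spec)
truth = [g for g in ds.truth_genes if g in ranking.gene_ids]
print(round(cd.normalized_auprc(ranking, truth).normalized_auprc, 3))
```

Output:

```
2 [8.33 2.57 1.67 1.24]
1.0
```

The leading eigenvalue (8.33) towers over the spectrum's tail — that
eigenvector carries the injected signal — and ranking genes by absolute
loading places all 15 injected genes on top: normalized AUPRC 1.0
(1 = perfect detection, 0 = random).  The same script is
`examples/01_signal_recovery.py`.

The same analysis from the shell:

```bash
colodiff simulate --out sim/ --seed 0 --n-genes 400 --n-cells 500
colodiff run --cond1 sim/cond1 --cond2 sim/cond2 --truth sim/truth.json \
             --out result/ --n-hvg 60
colodiff evaluate --truth sim/truth.json --result result/
```

See `examples/` for narrative scripts covering each capability.

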