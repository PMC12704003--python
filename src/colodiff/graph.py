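"""Per-condition cell geometry: embedding, kNN graph, geodesic cost matrix.

The ground cost for the gene transport problems is the all-pairs
shortest-path distance on a k-nearest-neighbor graph of the cells, built in
a low-dimensional embedding (diffusion map by default, PCA optionally).
Edge lengths are Euclidean distances in the embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import ExpressionMatrix
from .io import hvg_ranking
from .spectral import knee_index

__all__ = ["CellEmbedding", "CellGraph", "embed_cells", "knn_graph", "cost_matrix"]


@dataclass
class CellEmbedding:
    coords: np.ndarray  # cells x d
    method: str
    cell_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


@dataclass
class CellGraph:
    """Weighted undirected cell graph as an edge list (i < j)."""

    n_cells: int
    edges: np.ndarray  # (n_edges, 2) int
    lengths: np.ndarray  # (n_edges,) float
    k: int


def _scaled_hvg_matrix(expr: ExpressionMatrix, n_hvg: int, clip: float = 10.0) -> np.ndarray:
    """cells x genes matrix of the top HVGs, z-scored per gene and clipped."""
    ranks = hvg_ranking(expr)
    keep = [g for g in expr.gene_ids if ranks[g] < n_hvg]
    x = expr.subset_genes(keep).values.T  # cells x genes
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return np.clip((x - mu) / sd, -clip, clip)


def _adaptive_affinity(dist: np.ndarray, k_bw: int) -> np.ndarray:
    """Locally scaled Gaussian affinity with bandwidth = distance to the
    k_bw-th nearest neighbor, symmetrized by averaging."""
    n = dist.shape[0]
    kk = min(k_bw, n - 1)
    sigma = np.sort(dist, axis=1)[:, kk]
    sigma[sigma <= 0] = np.min(sigma[sigma > 0]) if np.any(sigma > 0) else 1.0
    r2 = dist**2
    w = 0.5 * (np.exp(-r2 / sigma[:, None] ** 2) + np.exp(-r2 / sigma[None, :] ** 2))
    return w


def embed_cells(
    expr: ExpressionMatrix,
    method: str = "diffusion_map",
    n_components: int | str = 10,
    n_hvg_embed: int = 2000,
    n_pcs: int = 10,
    k_bandwidth: int = 10,
) -> CellEmbedding:
    """Embed cells for graph construction.

    ``pca``: z-scored top-HVG matrix -> leading principal components.
    ``diffusion_map``: the PCA space above -> locally scaled Gaussian
    affinity -> symmetric normalized operator -> leading nontrivial
    eigenvectors scaled by their eigenvalues.  ``n_components='auto'``
    picks the count at the knee of the eigenvalue spectrum.
    """
    n_cells = expr.n_cells
    want = 10 if n_components == "auto" else int(n_components)
    if n_cells < want + 1:
        raise ValueError(f"need at least {want + 1} cells for {want} components")
    x = _scaled_hvg_matrix(expr, n_hvg_embed)
    if method == "pca":
        if n_components == "auto":
            n_components = n_pcs
        pca = PCA(n_components=int(n_components), svd_solver="full", random_state=0)
        coords = pca.fit_transform(x)
        return CellEmbedding(coords, "pca", expr.cell_ids)
    if method != "diffusion_map":
        raise ValueError(f"unknown embedding method {method!r}")
    pcs = PCA(n_components=min(n_pcs, min(x.shape) - 1), svd_solver="full", random_state=0)
    base = pcs.fit_transform(x)
    dist = cdist(base, base)
    w = _adaptive_affinity(dist, k_bandwidth)
    deg = w.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    op = w * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    evals, evecs = np.linalg.eigh(op)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # drop the trivial (constant after degree scaling) leading eigenvector
    lam = evals[1:]
    psi = evecs[:, 1:] * d_inv_sqrt[:, None]
    if n_components == "auto":
        scan = np.maximum(lam, 0.0)
        scan = np.sort(scan)[::-1]
        n_components = max(1, knee_index(scan))
    n_components = int(min(n_components, lam.shape[0]))
    coords = psi[:, :n_components] * lam[:n_components][None, :]
    # fix eigenvector signs deterministically (largest-|entry| positive)
    for c in range(coords.shape[1]):
        col = coords[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    return CellEmbedding(coords, "diffusion_map", expr.cell_ids)


def knn_graph(embedding: CellEmbedding, k: int = 10) -> CellGraph:
    """Union-symmetrized kNN graph with Euclidean edge lengths.

    If the raw graph is disconnected, components are bridged by their
    single closest inter-component pair, repeatedly, until connected.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = embedding.coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding.coords)
    dist, idx = nn.kneighbors(embedding.coords)
    edge_set: dict[tuple[int, int], float] = {}
    for i in range(n):
        picked = 0
        for j_pos in range(idx.shape[1]):
            j = int(idx[i, j_pos])
            if j == i:
                continue
            key = (min(i, j), max(i, j))
            edge_set.setdefault(key, float(dist[i, j_pos]))
            picked += 1
            if picked == k:
                break
    edges = np.array(sorted(edge_set), dtype=int).reshape(-1, 2)
    lengths = np.array([edge_set[tuple(e)] for e in edges])
    # connectivity repair: bridge closest inter-component pair until connected
    while True:
        adj = coo_matrix(
            (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
        )
        n_comp, labels = connected_components(adj, directed=False)
        if n_comp == 1:
            break
        # bridge component 0 to its nearest other component point pair
        in0 = np.flatnonzero(labels == labels[0])
        out0 = np.flatnonzero(labels != labels[0])
        d = cdist(embedding.coords[in0], embedding.coords[out0])
        a, b = np.unravel_index(np.argmin(d), d.shape)
        i, j = int(in0[a]), int(out0[b])
        key = (min(i, j), max(i, j))
        edges = np.vstack([edges, key])
        lengths = np.append(lengths, float(d[a, b]))
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        edges, lengths = edges[order], lengths[order]
    return CellGraph(n, edges, lengths, k)


def cost_matrix(graph: CellGraph) -> np.ndarray:
    """All-pairs shortest-path distances over the weighted cell graph."""
    n = graph.n_cells
    adj = coo_matrix(
        (graph.lengths, (graph.edges[:, 0], graph.edges[:, 1])), shape=(n, n)
    ).tocsr()
    c = shortest_path(adj, method="D", directed=False)
    if not np.all(np.isfinite(c)):
        raise ValueError("cell graph is disconnected; repair it upstream")
    return c
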