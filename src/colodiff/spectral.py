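"""Differential spectral comparison of two gene graphs.

For each condition the transport distances are converted into a locally
adaptive Gaussian kernel K and the symmetric normalized operator
L = A^{-1/2} K A^{-1/2} (A = degree matrix).  Gene sets that are densely
connected in condition a but not in condition b maximize the generalized
Rayleigh quotient v'L_a v / v'(L_b + c I)v, whose solutions are the top
eigenpairs of the symmetric operator

    Q = (L_b + c I)^{-1/2} L_a (L_b + c I)^{-1/2}.

The regularizer c is the eigenvalue of L_b at the knee of its spectrum
(a spectral filter that stops weak components of L_b from being amplified),
floored so that L_b + c I is positive definite.  Significant eigenvectors
are chosen at the knee of Q's spectrum; per-eigenvector gene loadings are
z-transformed and thresholded by local false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .locfdr import LocfdrResult, locfdr_select
from .transport import GeneDistanceMatrix

__all__ = [
    "KernelMatrix",
    "GraphOperator",
    "DiffOperator",
    "SpectralResult",
    "adaptive_kernel",
    "normalized_operator",
    "knee_index",
    "differential_operator",
    "spectral_select",
]

_PD_EPS = 1e-8


@dataclass
class KernelMatrix:
    K: np.ndarray
    bandwidths: np.ndarray
    k_local: int
    gene_ids: list[str]


@dataclass
class GraphOperator:
    L: np.ndarray
    degrees: np.ndarray
    gene_ids: list[str]


@dataclass
class DiffOperator:
    Q: np.ndarray
    direction: str  # e.g. "1_vs_2": numerator condition first
    c_reg: float
    gene_ids: list[str]


@dataclass
class SpectralResult:
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # columns, sign-fixed
    knee: int  # number of selected components
    gene_ids: list[str]
    direction: str
    c_reg: float
    locfdr: list[LocfdrResult] = field(default_factory=list)  # per selected vector
    significant_genes: list[str] = field(default_factory=list)  # deduplicated

    def gene_to_eigenvector(self) -> dict[str, int]:
        """Assign each significant gene to its highest-ranked (lowest index)
        eigenvector among those where it is significant."""
        assign: dict[str, int] = {}
        for ell, res in enumerate(self.locfdr):
            for i in np.flatnonzero(res.significant):
                g = self.gene_ids[i]
                if g not in assign:
                    assign[g] = ell
        return assign


def adaptive_kernel(D: GeneDistanceMatrix, k_local: int = 10) -> KernelMatrix:
    """Locally adaptive Gaussian kernel on transport distances.

    K_ij = (exp(-D_ij^2 / s_i^2) + exp(-D_ij^2 / s_j^2)) / 2 with s_i the
    distance from gene i to its k_local-th nearest other gene.  Zero
    bandwidths (duplicate gene distributions) are replaced by the smallest
    positive bandwidth.
    """
    d = D.D
    p = d.shape[0]
    if p < k_local + 1:
        raise ValueError(f"need at least {k_local + 1} genes for k_local={k_local}")
    off = np.sort(d + np.diag(np.full(p, np.inf)), axis=1)
    sigma = off[:, k_local - 1]
    if np.any(sigma <= 0):
        pos = sigma[sigma > 0]
        if pos.size == 0:
            raise ValueError("all adaptive bandwidths are zero")
        import warnings

        warnings.warn(
            "zero adaptive bandwidth (duplicate gene distributions); "
            "substituting smallest positive bandwidth",
            stacklevel=2,
        )
        sigma = np.where(sigma <= 0, pos.min(), sigma)
    r2 = d**2
    K = 0.5 * (np.exp(-r2 / sigma[:, None] ** 2) + np.exp(-r2 / sigma[None, :] ** 2))
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(K, sigma, k_local, list(D.gene_ids))


def normalized_operator(K: KernelMatrix) -> GraphOperator:
    """Degree-symmetrized operator L = A^{-1/2} K A^{-1/2}.

    L is similar to the row-stochastic random-walk matrix, so its spectrum
    lies in [-1, 1] with top eigenvalue exactly 1.
    """
    deg = K.K.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    L = K.K * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    return GraphOperator(L, deg, list(K.gene_ids))


def knee_index(values: np.ndarray, min_prefix: int = 10, tol: float = 1e-12) -> int:
    """Knee of a descending positive sequence by maximum chord distance.

    The chord joins the first and last point of the scanned prefix (the
    leading twentieth of the sequence, at least ``min_prefix`` points, capped
    at the sequence length); the knee is the index of the point with the
    largest perpendicular distance to it.  Scanning only the head of the
    spectrum keeps the chord anchored near the informative components: a
    long flat tail would otherwise drag the chord down and push the knee
    deep into noise.  For (near-)linear sequences where no point stands
    out the fallback is index 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    if np.any(np.diff(v) > 1e-12):
        raise ValueError("values must be sorted in descending order")
    npts = int(min(v.size, max(min_prefix, v.size // 20)))
    x = np.arange(npts, dtype=float)
    y = v[:npts]
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    nrm = np.hypot(*chord)
    if nrm < tol:
        return 1
    rel = np.stack([x - p0[0], y - p0[1]])
    dist = np.abs(chord[0] * rel[1] - chord[1] * rel[0]) / nrm
    if dist.max() <= tol:
        return 1
    return int(np.argmax(dist))


def differential_operator(
    L_num: GraphOperator, L_den: GraphOperator, direction: str = "1_vs_2"
) -> DiffOperator:
    """Directional differential operator Q = (L_den + cI)^{-1/2} L_num (...)^{-1/2}.

    The regularizer c is the denominator operator's eigenvalue at the knee
    of its spectrum, floored at -lambda_min + eps so the shifted operator
    is positive definite (the adaptive kernel is not guaranteed PSD).  The
    knee is scanned with the trivial Perron eigenvalue (always exactly 1,
    eigenvector proportional to the square-root degrees) excluded: the
    constant component carries no co-localization structure, and its fixed
    anchor at 1 would otherwise distort the chord geometry.
    """
    if L_num.gene_ids != L_den.gene_ids:
        raise ValueError("operators must share the same gene set and order")
    evals_d, evecs_d = np.linalg.eigh(L_den.L)
    desc = evals_d[::-1]
    scan = np.maximum.accumulate(desc[1:][::-1])[::-1]
    knee = knee_index(scan)
    c_knee = float(scan[knee])
    c_reg = max(c_knee, -float(evals_d.min()) + _PD_EPS)
    inv_sqrt = (evecs_d * (1.0 / np.sqrt(evals_d + c_reg))[None, :]) @ evecs_d.T
    Q = inv_sqrt @ L_num.L @ inv_sqrt
    Q = 0.5 * (Q + Q.T)
    return DiffOperator(Q, direction, c_reg, list(L_num.gene_ids))


def spectral_select(
    Q: DiffOperator,
    fdr_threshold: float = 0.2,
    run_locfdr: bool = True,
) -> SpectralResult:
    """Eigendecompose Q, pick components at the spectrum knee, call genes.

    Eigenvector signs are fixed so the largest-magnitude loading is
    positive.  An all-equal spectrum carries no differential signal and
    yields zero selected components.
    """
    evals, evecs = np.linalg.eigh(Q.Q)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for c in range(evecs.shape[1]):
        col = evecs[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            evecs[:, c] = -col
    if np.ptp(evals) <= 1e-12:
        knee = 0
    else:
        knee = knee_index(np.maximum.accumulate(evals[::-1])[::-1])
    result = SpectralResult(
        eigenvalues=evals,
        eigenvectors=evecs,
        knee=knee,
        gene_ids=list(Q.gene_ids),
        direction=Q.direction,
        c_reg=Q.c_reg,
    )
    if run_locfdr and knee > 0:
        sig: set[str] = set()
        for ell in range(knee):
            res = locfdr_select(evecs[:, ell], fdr_threshold=fdr_threshold)
            result.locfdr.append(res)
            sig.update(Q.gene_ids[i] for i in np.flatnonzero(res.significant))
        result.significant_genes = sorted(sig)
    return result
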