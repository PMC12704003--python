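"""Synthetic two-condition scRNA-seq benchmarks with injected co-localized signals.

Background counts follow a negative binomial with log-normal gene means and
log-normal cell library-size factors.  A co-localization signal confines a
group of genes to one transcriptomic neighborhood: inside the neighborhood
their counts are redrawn from NB(mu_signal, theta) thinned by dropout;
outside they are redrawn from NB(mu_noise, theta) thinned both by dropout
and by a background expression fraction p_outside, capped so that the
expected number of expressing cells outside never exceeds the number
inside.  All signal parameters (mu_signal = 95th percentile of gene means,
mu_noise = median, theta = median moment dispersion) are estimated from the
raw counts being perturbed, so injected genes look like real genes of the
dataset.  Every gene's entries are sampled independently: co-localization
arises purely from the shared neighborhood, with no cell-cell covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .containers import CountMatrix, GeneSet
from .graph import embed_cells
from .io import log_normalize

__all__ = [
    "BackgroundParams",
    "SimulationConfig",
    "CellNeighborhood",
    "SimulatedDataset",
    "generate_background",
    "pick_neighborhood",
    "candidate_genes",
    "estimate_signal_params",
    "inject_signal",
    "simulate_benchmark",
    "demo_preset",
]


@dataclass
class BackgroundParams:
    """Negative-binomial background model.

    Gene means are log-normal (``mean_log``, ``sd_log`` on the natural-log
    scale), cell library-size factors are log-normal with ``lib_sd_log``
    (mean factor 1), and all genes share dispersion ``theta``
    (var = mu + mu^2/theta).  Defaults give a median gene mean of ~0.14
    counts/cell and per-gene detection fractions mostly between 2% and 40%,
    typical of droplet scRNA-seq after removing unexpressed genes.
    """

    n_genes: int = 1000
    n_cells: int = 1400
    mean_log: float = -2.0
    sd_log: float = 1.1
    theta: float = 2.0
    lib_sd_log: float = 0.3


@dataclass
class SimulationConfig:
    neighborhood_frac: float = 0.10
    p_dropout: float = 0.4
    n_perturbed_genes: int = 15
    p_outside_baseline: float = 0.3
    seed: int = 0
    background: BackgroundParams = field(default_factory=BackgroundParams)
    inject_into: int = 2  # which condition carries the signal (1 or 2)
    # True: one population of 2 x n_cells randomly split into two halves
    # (no batch difference, the baseline scenario); False: two independent
    # background draws (a strong synthetic batch-effect analog).
    shared_background: bool = True

    def __post_init__(self) -> None:
        for name in ("neighborhood_frac", "p_dropout", "p_outside_baseline"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.n_perturbed_genes <= 0:
            raise ValueError("n_perturbed_genes must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CellNeighborhood:
    core_cell: int
    members: np.ndarray  # cell indices, core included

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=int)
        if self.core_cell not in self.members:
            raise ValueError("core cell must belong to the neighborhood")


@dataclass
class SimulatedDataset:
    counts1: CountMatrix
    counts2: CountMatrix
    truth_genes: list[str]
    neighborhoods: dict[str, CellNeighborhood]
    config: SimulationConfig
    module_genes: dict[str, list[str]] = field(default_factory=dict)


def _child_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31 - 1))


def generate_background(
    params: BackgroundParams, seed: int, condition_label: str = ""
) -> CountMatrix:
    """Draw a genes x cells NB count matrix; deterministic given seed."""
    if params.n_genes <= 0 or params.n_cells <= 0:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    mu_g = rng.lognormal(params.mean_log, params.sd_log, size=params.n_genes)
    lib = rng.lognormal(-params.lib_sd_log**2 / 2, params.lib_sd_log, size=params.n_cells)
    mu = mu_g[:, None] * lib[None, :]
    p = params.theta / (params.theta + mu)
    counts = rng.negative_binomial(params.theta, p)
    genes = [f"g{i:04d}" for i in range(params.n_genes)]
    cells = [f"{condition_label or 'c'}_{j:04d}" for j in range(params.n_cells)]
    return CountMatrix(counts, genes, cells, condition_label)


def split_background(
    params: BackgroundParams, seed: int, labels: tuple[str, str] = ("cond1", "cond2")
) -> tuple[CountMatrix, CountMatrix]:
    """One population of 2 x n_cells, randomly split into two halves.

    The two halves share the cell manifold exactly (no batch difference),
    mirroring a random split of a homogeneous cell population.
    """
    double = BackgroundParams(**{**asdict(params), "n_cells": 2 * params.n_cells})
    pool = generate_background(double, seed, "pool")
    rng = np.random.default_rng(_child_seed(seed, 97))
    perm = rng.permutation(pool.n_cells)
    halves = []
    for h, lab in enumerate(labels):
        cols = np.sort(perm[h * params.n_cells : (h + 1) * params.n_cells])
        halves.append(
            CountMatrix(
                pool.values[:, cols],
                pool.gene_ids,
                [f"{lab}_{pool.cell_ids[c]}" for c in cols],
                lab,
            )
        )
    return halves[0], halves[1]


def pick_neighborhood(
    counts: CountMatrix,
    frac: float,
    seed: int,
    exclude: np.ndarray | None = None,
) -> CellNeighborhood:
    """Random core cell plus its nearest cells in top-10-PC space.

    PCs are computed on the log-normalized pre-injection matrix.  Cells in
    ``exclude`` cannot serve as members (used to keep several injected
    neighborhoods disjoint).
    """
    n = counts.n_cells
    size = int(round(frac * n))
    if size < 2:
        raise ValueError(f"neighborhood of {size} cells is too small; raise frac")
    emb = embed_cells(log_normalize(counts), method="pca", n_components=min(10, n - 1))
    rng = np.random.default_rng(seed)
    allowed = np.ones(n, dtype=bool)
    if exclude is not None and len(exclude):
        allowed[np.asarray(exclude, dtype=int)] = False
    if allowed.sum() < size:
        raise ValueError("not enough unexcluded cells for the requested neighborhood")
    candidates = np.flatnonzero(allowed)
    core = int(rng.choice(candidates))
    d = np.linalg.norm(emb.coords - emb.coords[core], axis=1)
    d[~allowed] = np.inf
    members = np.argsort(d, kind="stable")[:size]
    return CellNeighborhood(core, np.sort(members))


def candidate_genes(counts_test: CountMatrix, counts_other: CountMatrix) -> GeneSet:
    """Genes eligible for signal injection, judged on raw counts.

    (1) expressed in 0.5-50% of the test condition's cells and detected in
    at least one cell of the other condition; (2) variance greater than
    mean (negative-binomial-like overdispersion) in the test condition.
    """
    shared = sorted(set(counts_test.gene_ids) & set(counts_other.gene_ids))
    if not shared:
        raise ValueError("conditions share no genes")
    it = [counts_test.gene_index(g) for g in shared]
    io_ = [counts_other.gene_index(g) for g in shared]
    x = counts_test.values[it]
    frac = (x > 0).mean(axis=1)
    var = x.var(axis=1, ddof=1)
    mean = x.mean(axis=1)
    detected_other = (counts_other.values[io_] > 0).any(axis=1)
    ok = (frac >= 0.005) & (frac <= 0.5) & detected_other & (var > mean)
    selected = [g for g, o in zip(shared, ok) if o]
    if not selected:
        raise ValueError("no candidate genes satisfy the injection criteria")
    return GeneSet(
        selected,
        {g: {"frequency_band": True, "overdispersed": True} for g in selected},
    )


def estimate_signal_params(counts: CountMatrix) -> tuple[float, float, float]:
    """(mu_signal, mu_noise, theta) from raw counts.

    mu_signal / mu_noise are the 95th percentile / median of gene-wise mean
    counts; theta is the median of moment dispersions
    theta_g = mu_g^2 / (var_g - mu_g) over overdispersed genes.
    """
    mean = counts.values.mean(axis=1)
    var = counts.values.var(axis=1, ddof=1)
    mu_signal = float(np.percentile(mean, 95))
    mu_noise = float(np.median(mean))
    over = var > mean
    if not np.any(over):
        raise ValueError("no overdispersed genes; cannot estimate dispersion")
    theta = float(np.median(mean[over] ** 2 / (var[over] - mean[over])))
    return mu_signal, mu_noise, theta


def inject_signal(
    counts: CountMatrix,
    neighborhood: CellNeighborhood,
    genes: list[str],
    config: SimulationConfig,
    seed: int,
) -> CountMatrix:
    """Return a copy of ``counts`` with the genes' rows replaced by the
    neighborhood-confined signal model.  Other genes are untouched."""
    mu_signal, mu_noise, theta = estimate_signal_params(counts)
    rng = np.random.default_rng(seed)
    n = counts.n_cells
    inside = np.zeros(n, dtype=bool)
    inside[neighborhood.members] = True
    n_in = int(inside.sum())
    n_out = n - n_in
    p_outside = min(config.p_outside_baseline, n_in / n_out) if n_out else 0.0
    keep = 1.0 - config.p_dropout
    new_values = counts.values.copy()
    for g in genes:
        gi = counts.gene_index(g)
        row = np.zeros(n, dtype=np.int64)
        x_in = rng.negative_binomial(theta, theta / (theta + mu_signal), size=n_in)
        row[inside] = x_in * rng.binomial(1, keep, size=n_in)
        x_out = rng.negative_binomial(theta, theta / (theta + mu_noise), size=n_out)
        row[~inside] = (
            x_out * rng.binomial(1, p_outside, size=n_out) * rng.binomial(1, keep, size=n_out)
        )
        new_values[gi] = row
    return CountMatrix(
        new_values, counts.gene_ids, counts.cell_ids, counts.condition_label
    )


def simulate_benchmark(
    config: SimulationConfig,
    background1: CountMatrix | None = None,
    background2: CountMatrix | None = None,
) -> SimulatedDataset:
    """Single-signal benchmark: one condition is the untouched reference,
    the other receives one injected co-localized gene group."""
    seed = config.seed
    if background1 is None and background2 is None:
        if config.shared_background:
            background1, background2 = split_background(
                config.background, _child_seed(seed, 1)
            )
        else:
            background1 = generate_background(
                config.background, _child_seed(seed, 1), "cond1"
            )
            background2 = generate_background(
                config.background, _child_seed(seed, 2), "cond2"
            )
    elif background1 is None or background2 is None:
        raise ValueError("supply both backgrounds or neither")
    test, other = (
        (background2, background1) if config.inject_into == 2 else (background1, background2)
    )
    cand = candidate_genes(test, other)
    rng = np.random.default_rng(_child_seed(seed, 3))
    if len(cand) < config.n_perturbed_genes:
        raise ValueError(
            f"only {len(cand)} candidate genes for {config.n_perturbed_genes} requested"
        )
    genes = sorted(rng.choice(cand.gene_ids, size=config.n_perturbed_genes, replace=False))
    nb = pick_neighborhood(test, config.neighborhood_frac, _child_seed(seed, 4))
    injected = inject_signal(test, nb, genes, config, _child_seed(seed, 5))
    c1, c2 = (
        (background1, injected) if config.inject_into == 2 else (injected, background2)
    )
    return SimulatedDataset(
        counts1=c1,
        counts2=c2,
        truth_genes=list(genes),
        neighborhoods={f"signal@cond{config.inject_into}": nb},
        config=config,
        module_genes={"signal": list(genes)},
    )


def demo_preset(
    seed: int = 0,
    background: BackgroundParams | None = None,
    module_size: int = 10,
    config: SimulationConfig | None = None,
) -> SimulatedDataset:
    """Six-module demonstration layout on a randomly split population.

    One background population is split into two biologically identical
    halves.  Six disjoint neighborhoods are anchored at core cells of the
    joint PC embedding, so every neighborhood occupies the same manifold
    region in both halves.  Two modules per condition are private —
    injected into that condition's cells only — and two are shared.
    Shared modules are injected once into the merged population before
    the split: their neighborhoods contain cells from both halves and
    each cell carries a single draw, so the shared signal is identical in
    distribution (and in realization) across the two conditions.  A
    correct analysis flags each condition's private modules in the
    corresponding direction and ignores the shared ones.
    """
    if config is None:
        config = SimulationConfig(seed=seed)
    if background is not None:
        config.background = background
    config.seed = seed
    params = config.background
    double = BackgroundParams(**{**asdict(params), "n_cells": 2 * params.n_cells})
    pool = generate_background(double, _child_seed(seed, 1), "pool")
    split_rng = np.random.default_rng(_child_seed(_child_seed(seed, 1), 97))
    perm = split_rng.permutation(pool.n_cells)
    cols = {1: np.sort(perm[: params.n_cells]), 2: np.sort(perm[params.n_cells :])}
    half_of = np.empty(pool.n_cells, dtype=int)
    half_of[cols[1]] = 1
    half_of[cols[2]] = 2

    def _halves(src: CountMatrix) -> dict[int, CountMatrix]:
        return {
            h: CountMatrix(
                src.values[:, cols[h]],
                src.gene_ids,
                [f"cond{h}_{src.cell_ids[c]}" for c in cols[h]],
                f"cond{h}",
            )
            for h in (1, 2)
        }

    bgs = _halves(pool)
    cand = sorted(
        set(candidate_genes(bgs[1], bgs[2])) & set(candidate_genes(bgs[2], bgs[1]))
    )
    need = 6 * module_size
    if len(cand) < need:
        raise ValueError(f"only {len(cand)} two-way candidate genes; need {need}")
    rng = np.random.default_rng(_child_seed(seed, 10))
    chosen = rng.choice(cand, size=need, replace=False)
    # shared modules claim their neighborhoods first: their manifold
    # regions must match across conditions exactly, while private-module
    # regions are differential by design and tolerate fringe placement
    names = ["Ca", "Cb", "M1a", "M1b", "M2a", "M2b"]
    module_genes = {
        nm: sorted(chosen[i * module_size : (i + 1) * module_size])
        for i, nm in enumerate(names)
    }
    # the pre-injection joint embedding anchors every neighborhood
    emb = embed_cells(
        log_normalize(pool), method="pca", n_components=min(10, pool.n_cells - 1)
    )
    size = int(round(config.neighborhood_frac * params.n_cells))
    if size < 2:
        raise ValueError("neighborhood too small; raise neighborhood_frac")
    nb_rng = np.random.default_rng(_child_seed(seed, 20))
    taken = np.zeros(pool.n_cells, dtype=bool)
    neighborhoods: dict[str, CellNeighborhood] = {}
    joint_members: dict[str, np.ndarray] = {}
    for nm in names:
        free = np.flatnonzero(~taken)
        core = int(nb_rng.choice(free))
        d = np.linalg.norm(emb.coords - emb.coords[core], axis=1)
        d[taken] = np.inf
        members = []
        for h in (1, 2):
            dd = np.where(half_of == h, d, np.inf)
            members.append(np.sort(np.argsort(dd, kind="stable")[:size]))
        both = np.sort(np.concatenate(members))
        taken[both] = True
        joint_members[nm] = both
        neighborhoods[nm] = CellNeighborhood(
            core if core in both else int(both[0]), both
        )
    # shared modules: one draw on the merged population
    current_pool = pool
    for mi, nm in enumerate(("Ca", "Cb")):
        nb = CellNeighborhood(int(joint_members[nm][0]), joint_members[nm])
        current_pool = inject_signal(
            current_pool, nb, module_genes[nm], config, _child_seed(seed, 40 + mi)
        )
    halves = _halves(current_pool)
    # private modules: injected into one half's cells only
    pos_in_half = {h: {int(c): i for i, c in enumerate(cols[h])} for h in (1, 2)}
    plans = {1: ["M1a", "M1b"], 2: ["M2a", "M2b"]}
    out: dict[int, CountMatrix] = {}
    for cond, mods in plans.items():
        current = halves[cond]
        for mi, nm in enumerate(mods):
            local = np.array(
                sorted(
                    pos_in_half[cond][int(c)]
                    for c in joint_members[nm]
                    if half_of[c] == cond
                )
            )
            nb = CellNeighborhood(int(local[0]), local)
            current = inject_signal(
                current, nb, module_genes[nm], config, _child_seed(seed, 50 + 10 * cond + mi)
            )
        out[cond] = current
    private = sorted(
        module_genes["M1a"] + module_genes["M1b"] + module_genes["M2a"] + module_genes["M2b"]
    )
    return SimulatedDataset(
        counts1=out[1],
        counts2=out[2],
        truth_genes=private,
        neighborhoods=neighborhoods,
        config=config,
        module_genes=module_genes,
    )
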