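import itertools

import numpy as np
import pytest

from colodiff import assemble_modules, module_activity, module_importance
from colodiff.containers import ExpressionMatrix
from colodiff.modules import GeneModule, ModuleSet
from colodiff.spectral import SpectralResult
from colodiff.transport import GeneDistanceMatrix


def block_distance_matrix(rng, sizes, intra=0.1, inter=10.0):
    """Distance matrix of tight blocks far apart, with small jitter."""
    p = sum(sizes)
    D = np.full((p, p), inter) + rng.normal(0, 0.01, size=(p, p))
    start = 0
    for s in sizes:
        block = slice(start, start + s)
        D[block, block] = intra + rng.normal(0, 0.005, size=(s, s))
        start += s
    D = np.abs(0.5 * (D + D.T))
    np.fill_diagonal(D, 0.0)
    return GeneDistanceMatrix(D, [f"g{i:03d}" for i in range(p)])


def best_two_partition(D, genes):
    """Oracle: exhaustive 2-partition minimizing mean intra-cluster distance."""
    idx = range(len(genes))
    best, best_val = None, np.inf
    for r in range(1, len(genes) // 2 + 1):
        for left in itertools.combinations(idx, r):
            right = tuple(i for i in idx if i not in left)
            val = 0.0
            for side in (left, right):
                if len(side) > 1:
                    sub = D[np.ix_(side, side)]
                    val += sub.sum() / (len(side) * (len(side) - 1))
            if val < best_val:
                best_val, best = val, (left, right)
    return best


class TestAssembleModules:
    def test_two_blocks_recovered(self, rng):
        D = block_distance_matrix(rng, [10, 10])
        ms = assemble_modules(list(D.gene_ids), D, min_size=5)
        assert len(ms) == 2
        sizes = sorted(m.size for m in ms)
        assert sizes == [10, 10]
        got = {frozenset(m.gene_ids) for m in ms}
        left, right = best_two_partition(D.D, D.gene_ids)
        expected = {
            frozenset(D.gene_ids[i] for i in left),
            frozenset(D.gene_ids[i] for i in right),
        }
        assert got == expected

    def test_small_cluster_dropped(self, rng):
        D = block_distance_matrix(rng, [10, 4])
        ms = assemble_modules(list(D.gene_ids), D, min_size=5)
        assert len(ms) == 1
        assert ms.modules[0].size == 10

    def test_outlier_gene_excluded(self, rng):
        # 6-gene block where one gene sits far from the others
        D = block_distance_matrix(rng, [6, 8], intra=1.0, inter=200.0)
        d = D.D.copy()
        d[5, :6] = 50.0
        d[:6, 5] = 50.0
        d[5, 5] = 0.0
        D = GeneDistanceMatrix(d, D.gene_ids)
        ms = assemble_modules(list(D.gene_ids), D, min_size=5)
        outlier_mod = [m for m in ms if "g005" not in m.gene_ids and m.size == 5]
        assert outlier_mod, "expected g005 removed from its module"
        assert "g005" in ms.outlier_genes

    def test_mad_rule_hand_computation(self, rng):
        # mean intra distances [1,1,1,1,1,50]: median 1, MAD 0 -> fall back
        # keeps everyone; jitter makes MAD > 0 and excludes the outlier
        D = block_distance_matrix(rng, [7], intra=1.0)
        d = D.D.copy()
        d[6, :] = 50.0
        d[:, 6] = 50.0
        d[6, 6] = 0.0
        ms = assemble_modules(list(D.gene_ids), GeneDistanceMatrix(d, D.gene_ids), min_size=5)
        assert "g006" in ms.outlier_genes

    def test_too_few_genes_warns_empty(self, rng):
        D = block_distance_matrix(rng, [3])
        with pytest.warns(UserWarning, match="min_size"):
            ms = assemble_modules(list(D.gene_ids), D, min_size=5)
        assert len(ms) == 0

    def test_input_order_invariance(self, rng):
        D = block_distance_matrix(rng, [8, 8, 8])
        genes = list(D.gene_ids)
        ms1 = assemble_modules(genes, D, min_size=5)
        ms2 = assemble_modules(list(reversed(genes)), D, min_size=5)
        assert {frozenset(m.gene_ids) for m in ms1} == {frozenset(m.gene_ids) for m in ms2}

    def test_outlier_filter_idempotent(self, rng):
        D = block_distance_matrix(rng, [10, 10])
        ms1 = assemble_modules(list(D.gene_ids), D, min_size=5)
        survivors = [g for m in ms1 for g in m.gene_ids]
        ms2 = assemble_modules(survivors, D.submatrix(sorted(survivors)), min_size=5)
        assert ms2.outlier_genes == []


def make_spectral_result(gene_ids, sig_by_vector, eigenvalues):
    """Construct a SpectralResult with prescribed per-vector significance."""
    from colodiff.locfdr import LocfdrResult

    p = len(gene_ids)
    k = len(sig_by_vector)
    res = SpectralResult(
        eigenvalues=np.asarray(eigenvalues, dtype=float),
        eigenvectors=np.eye(p, k),
        knee=k,
        gene_ids=list(gene_ids),
        direction="1_vs_2",
        c_reg=0.5,
    )
    for sig in sig_by_vector:
        mask = np.array([g in sig for g in gene_ids])
        res.locfdr.append(
            LocfdrResult(
                z=np.zeros(p), fdr=np.ones(p), pi0=1.0, significant=mask, threshold=0.2
            )
        )
    res.significant_genes = sorted({g for s in sig_by_vector for g in s})
    return res


class TestModuleImportance:
    def test_gene_assigned_to_highest_ranked_eigenvector(self):
        genes = [f"g{i}" for i in range(6)]
        spec = make_spectral_result(
            genes, [set(genes[:3]), set(genes[:5])], [0.6, 0.4, 0.1]
        )
        assert spec.gene_to_eigenvector()["g0"] == 0
        assert spec.gene_to_eigenvector()["g3"] == 1

    def test_single_vector_module_weight_one(self):
        genes = [f"g{i}" for i in range(5)]
        spec = make_spectral_result(genes, [set(genes)], [0.7])
        ms = ModuleSet([GeneModule("M1", genes)], [], "1_vs_2")
        ms = module_importance(ms, spec)
        assert ms.modules[0].importance == pytest.approx(1.0)

    def test_even_split_weight(self):
        genes = [f"g{i}" for i in range(10)]
        spec = make_spectral_result(
            genes, [set(genes[:5]), set(genes[5:])], [0.6, 0.4]
        )
        ms = ModuleSet([GeneModule("M1", genes)], [], "1_vs_2")
        ms = module_importance(ms, spec)
        # lambda_hat = (0.6, 0.4), fractions (0.5, 0.5) -> w = 0.5
        assert ms.modules[0].importance == pytest.approx(0.5)

    def test_unassigned_gene_is_error(self):
        genes = [f"g{i}" for i in range(5)]
        spec = make_spectral_result(genes, [set(genes[:4])], [0.7])
        ms = ModuleSet([GeneModule("M1", genes)], [], "1_vs_2")
        with pytest.raises(ValueError, match="no contributing"):
            module_importance(ms, spec)

    def test_modules_sorted_by_importance(self):
        genes = [f"g{i}" for i in range(10)]
        spec = make_spectral_result(
            genes, [set(genes[:5]), set(genes)], [0.8, 0.2]
        )
        ms = ModuleSet(
            [GeneModule("A", genes[5:]), GeneModule("B", genes[:5])], [], "1_vs_2"
        )
        ms = module_importance(ms, spec)
        assert ms.modules[0].gene_ids == genes[:5]
        assert ms.modules[0].importance >= ms.modules[1].importance


class TestModuleActivity:
    def test_constant_expression_all_zero(self):
        expr = ExpressionMatrix(
            np.ones((30, 10)), [f"g{i}" for i in range(30)], [f"c{j}" for j in range(10)]
        )
        scores = module_activity(expr, ["g0", "g1"], seed=0)
        np.testing.assert_array_equal(scores, 0.0)

    def test_range_attained(self, random_expr):
        scores = module_activity(random_expr, random_expr.gene_ids[:4], seed=0)
        assert scores.min() == pytest.approx(0.0)
        assert scores.max() == pytest.approx(1.0)

    def test_empty_module_rejected(self, random_expr):
        with pytest.raises(ValueError, match="empty"):
            module_activity(random_expr, [])

    def test_seed_reproducibility(self, random_expr):
        s1 = module_activity(random_expr, random_expr.gene_ids[:5], seed=7)
        s2 = module_activity(random_expr, random_expr.gene_ids[:5], seed=7)
        np.testing.assert_array_equal(s1, s2)

    def test_mean_scheme_matches_direct_computation(self, random_expr):
        genes = random_expr.gene_ids[:3]
        scores = module_activity(random_expr, genes, control_scheme="mean")
        idx = [random_expr.gene_index(g) for g in genes]
        raw = random_expr.values[idx].mean(axis=0)
        z = (raw - raw.mean()) / raw.std()
        expected = (z - z.min()) / (z.max() - z.min())
        np.testing.assert_allclose(scores, expected, atol=1e-12)
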