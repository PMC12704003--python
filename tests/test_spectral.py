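import numpy as np
import pytest
from scipy.linalg import eigh as generalized_eigh

from colodiff import (
    adaptive_kernel,
    differential_operator,
    knee_index,
    normalized_operator,
    spectral_select,
)
from colodiff.spectral import DiffOperator, GraphOperator
from colodiff.transport import GeneDistanceMatrix


def random_kernel_operator(rng, p=30):
    pts = rng.random((p, 3))
    D = np.linalg.norm(pts[:, None] - pts[None], axis=2)
    K = adaptive_kernel(GeneDistanceMatrix(D, [f"g{i}" for i in range(p)]), k_local=5)
    return normalized_operator(K)


class TestAdaptiveKernel:
    def test_three_gene_toy(self):
        D = GeneDistanceMatrix(
            np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]]),
            ["a", "b", "c"],
        )
        K = adaptive_kernel(D, k_local=1)
        np.testing.assert_allclose(K.bandwidths, [1.0, 1.0, 1.0])
        assert K.K[0, 1] == pytest.approx(np.exp(-1.0))
        np.testing.assert_allclose(np.diag(K.K), 1.0)

    def test_symmetric_for_any_distance_matrix(self, rng):
        pts = rng.random((20, 2))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        K = adaptive_kernel(GeneDistanceMatrix(D, [f"g{i}" for i in range(20)]), k_local=3)
        np.testing.assert_allclose(K.K, K.K.T, atol=1e-15)
        assert np.all(K.K > 0) and np.all(K.K <= 1 + 1e-15)

    def test_duplicate_distribution_warns(self):
        D = np.array(
            [[0.0, 0.0, 1.0, 1.2], [0.0, 0.0, 1.0, 1.2], [1.0, 1.0, 0.0, 0.7], [1.2, 1.2, 0.7, 0.0]]
        )
        with pytest.warns(UserWarning, match="bandwidth"):
            K = adaptive_kernel(GeneDistanceMatrix(D, list("abcd")), k_local=1)
        assert np.all(K.bandwidths > 0)


class TestNormalizedOperator:
    def test_perron_eigenpair(self, rng):
        L = random_kernel_operator(rng)
        evals, evecs = np.linalg.eigh(L.L)
        assert evals[-1] == pytest.approx(1.0, abs=1e-10)
        top = evecs[:, -1]
        expected = np.sqrt(L.degrees)
        expected /= np.linalg.norm(expected)
        assert abs(np.dot(top, expected)) == pytest.approx(1.0, abs=1e-8)

    def test_spectrum_in_unit_interval(self, rng):
        for _ in range(5):
            L = random_kernel_operator(rng, p=25)
            evals = np.linalg.eigvalsh(L.L)
            assert evals.max() <= 1 + 1e-10
            assert evals.min() >= -1 - 1e-10

    def test_identity_kernel_gives_identity(self):
        from colodiff.spectral import KernelMatrix

        K = KernelMatrix(np.eye(4), np.ones(4), 1, list("abcd"))
        L = normalized_operator(K)
        np.testing.assert_allclose(L.L, np.eye(4), atol=1e-15)


class TestKneeIndex:
    def test_sharp_elbow(self):
        assert knee_index(np.array([10, 9, 1, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3])) == 2

    def test_single_leading_value(self):
        assert knee_index(np.array([5, 1, 0.98, 0.96, 0.94, 0.92, 0.9, 0.88, 0.86, 0.84])) == 1

    def test_linear_decay_fallback(self):
        assert knee_index(np.linspace(10, 1, 12)) == 1

    def test_non_descending_rejected(self):
        with pytest.raises(ValueError, match="descending"):
            knee_index(np.array([1.0, 2.0, 3.0]))

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            knee_index(np.array([2.0, 1.0]))


class TestDifferentialOperator:
    def test_spectrum_matches_generalized_eigenproblem(self, rng):
        for _ in range(5):
            L1 = random_kernel_operator(rng, p=25)
            L2 = random_kernel_operator(rng, p=25)
            L2.gene_ids = L1.gene_ids
            Q = differential_operator(L1, L2)
            lam_q = np.sort(np.linalg.eigvalsh(Q.Q))
            shifted = L2.L + Q.c_reg * np.eye(25)
            lam_gen = np.sort(generalized_eigh(L1.L, shifted, eigvals_only=True))
            np.testing.assert_allclose(lam_q, lam_gen, atol=1e-8)

    def test_equal_operators_monotone_spectrum_map(self, rng):
        L = random_kernel_operator(rng, p=30)
        Q = differential_operator(L, L)
        lam_l = np.sort(np.linalg.eigvalsh(L.L))
        expected = lam_l / (lam_l + Q.c_reg)
        got = np.sort(np.linalg.eigvalsh(Q.Q))
        np.testing.assert_allclose(got, expected, atol=1e-9)
        assert np.all(np.diff(expected) >= -1e-12)  # strictly increasing map

    def test_gene_order_mismatch_rejected(self, rng):
        L1 = random_kernel_operator(rng, p=20)
        L2 = random_kernel_operator(rng, p=20)
        L2.gene_ids = list(reversed(L1.gene_ids))
        with pytest.raises(ValueError, match="gene set"):
            differential_operator(L1, L2)

    def test_swap_gives_opposite_direction(self, rng):
        L1 = random_kernel_operator(rng, p=20)
        L2 = random_kernel_operator(rng, p=20)
        L2.gene_ids = L1.gene_ids
        Q12 = differential_operator(L1, L2, "1_vs_2")
        Q21 = differential_operator(L2, L1, "2_vs_1")
        assert Q12.direction != Q21.direction
        # numerator/denominator exchange: spectra differ but both well-defined
        assert np.all(np.isfinite(np.linalg.eigvalsh(Q12.Q)))
        assert np.all(np.isfinite(np.linalg.eigvalsh(Q21.Q)))


class TestSpectralSelect:
    def test_identity_operator_no_components(self):
        Q = DiffOperator(np.eye(60), "1_vs_2", 0.5, [f"g{i}" for i in range(60)])
        res = spectral_select(Q)
        assert res.knee == 0
        assert res.significant_genes == []

    def test_sign_convention(self, rng):
        a = rng.standard_normal((30, 30))
        Q = DiffOperator(a + a.T, "1_vs_2", 0.5, [f"g{i}" for i in range(30)])
        res = spectral_select(Q, run_locfdr=False)
        for c in range(res.eigenvectors.shape[1]):
            col = res.eigenvectors[:, c]
            assert col[np.argmax(np.abs(col))] > 0

    def test_eigenvalues_descending_unit_vectors(self, rng):
        a = rng.standard_normal((25, 25))
        Q = DiffOperator(a + a.T, "1_vs_2", 0.5, [f"g{i}" for i in range(25)])
        res = spectral_select(Q, run_locfdr=False)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        np.testing.assert_allclose(
            np.linalg.norm(res.eigenvectors, axis=0), 1.0, atol=1e-10
        )

    def test_planted_block_detected(self, rng):
        # two dense blocks on top of weak noise: 2 clear components
        p = 100
        Q = rng.normal(0, 0.01, size=(p, p))
        Q = 0.5 * (Q + Q.T)
        # unequal strengths keep the two top eigenvalues non-degenerate, so
        # each eigenvector aligns with one block
        for strength, block in ((0.6, range(0, 10)), (0.45, range(10, 20))):
            for i in block:
                for j in block:
                    Q[i, j] += strength
        res = spectral_select(DiffOperator(Q, "1_vs_2", 0.5, [f"g{i}" for i in range(p)]))
        assert res.knee == 2
        sig = set(res.significant_genes)
        assert {f"g{i}" for i in range(20)} <= sig
        assert len(sig - {f"g{i}" for i in range(20)}) <= 2
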