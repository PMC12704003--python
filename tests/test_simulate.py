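import numpy as np
import pytest

from colodiff import (
    BackgroundParams,
    SimulationConfig,
    candidate_genes,
    generate_background,
    inject_signal,
    pick_neighborhood,
    simulate_benchmark,
)
from colodiff.containers import CountMatrix
from colodiff.simulate import estimate_signal_params


class TestGenerateBackground:
    def test_deterministic_given_seed(self, tiny_background):
        a = generate_background(tiny_background, seed=5)
        b = generate_background(tiny_background, seed=5)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.gene_ids == b.gene_ids

    def test_dimensions_honored(self, tiny_background):
        cm = generate_background(tiny_background, seed=1)
        assert cm.values.shape == (tiny_background.n_genes, tiny_background.n_cells)

    def test_overdispersion(self):
        # NB moment identity var = mu + mu^2/theta -> var > mu on average
        params = BackgroundParams(n_genes=300, n_cells=400, theta=1.5)
        cm = generate_background(params, seed=2)
        mean = cm.values.mean(axis=1)
        var = cm.values.var(axis=1, ddof=1)
        assert np.mean(var - mean) > 0


class TestPickNeighborhood:
    def test_size_and_core_membership(self, tiny_background):
        cm = generate_background(tiny_background, seed=3)
        nb = pick_neighborhood(cm, frac=0.1, seed=0)
        assert len(nb.members) == round(0.1 * cm.n_cells)
        assert nb.core_cell in nb.members

    def test_members_are_nearest_to_core(self, tiny_background):
        from colodiff import embed_cells, log_normalize

        cm = generate_background(tiny_background, seed=3)
        nb = pick_neighborhood(cm, frac=0.15, seed=1)
        emb = embed_cells(log_normalize(cm), "pca", n_components=10)
        d = np.linalg.norm(emb.coords - emb.coords[nb.core_cell], axis=1)
        inside = np.zeros(cm.n_cells, dtype=bool)
        inside[nb.members] = True
        assert d[inside].max() <= d[~inside].min() + 1e-12

    def test_too_small_fraction_rejected(self, tiny_background):
        cm = generate_background(tiny_background, seed=3)
        with pytest.raises(ValueError, match="too small"):
            pick_neighborhood(cm, frac=0.001, seed=0)


class TestCandidateGenes:
    def _pair(self):
        params = BackgroundParams(n_genes=200, n_cells=300)
        return (
            generate_background(params, seed=10, condition_label="t"),
            generate_background(params, seed=11, condition_label="o"),
        )

    def test_high_frequency_rejected(self):
        test, other = self._pair()
        vals = test.values.copy()
        vals[0] = 1  # 100% frequency
        test = CountMatrix(vals, test.gene_ids, test.cell_ids)
        assert test.gene_ids[0] not in candidate_genes(test, other)

    def test_underdispersed_rejected(self):
        test, other = self._pair()
        vals = test.values.copy()
        # constant nonzero on 30% of cells: var < mean
        row = np.zeros(test.n_cells, dtype=int)
        row[: int(0.3 * test.n_cells)] = 1
        vals[1] = row
        test = CountMatrix(vals, test.gene_ids, test.cell_ids)
        g = test.gene_ids[1]
        assert vals[1].var() < vals[1].mean()
        assert g not in candidate_genes(test, other)

    def test_criteria_verified_on_accepted_genes(self):
        test, other = self._pair()
        cand = candidate_genes(test, other)
        assert len(cand) > 0
        for g in list(cand)[:20]:
            row = test.values[test.gene_index(g)]
            frac = (row > 0).mean()
            assert 0.005 <= frac <= 0.5
            assert row.var(ddof=1) > row.mean()
            assert (other.values[other.gene_index(g)] > 0).any()


class TestInjectSignal:
    @pytest.fixture()
    def setup(self):
        params = BackgroundParams(n_genes=200, n_cells=400)
        cm = generate_background(params, seed=20)
        nb = pick_neighborhood(cm, frac=0.1, seed=0)
        cfg = SimulationConfig(seed=0, background=params)
        genes = cm.gene_ids[:5]
        return cm, nb, cfg, genes

    def test_p_outside_min_rule(self):
        # |nb| = 100, 1000 outside, baseline 0.3 -> p_outside = 0.1
        assert min(0.3, 100 / 1000) == pytest.approx(0.1)

    def test_full_dropout_zeroes_injected_rows(self, setup):
        cm, nb, cfg, genes = setup
        cfg2 = SimulationConfig(
            p_dropout=0.999999999, seed=0, background=cfg.background
        )
        out = inject_signal(cm, nb, genes, cfg2, seed=1)
        for g in genes:
            assert out.values[out.gene_index(g)].sum() == 0

    def test_other_genes_untouched(self, setup):
        cm, nb, cfg, genes = setup
        out = inject_signal(cm, nb, genes, cfg, seed=1)
        others = [g for g in cm.gene_ids if g not in genes]
        for g in others[:50]:
            np.testing.assert_array_equal(
                out.values[out.gene_index(g)], cm.values[cm.gene_index(g)]
            )

    def test_outside_expression_never_exceeds_inside(self, setup):
        cm, nb, cfg, genes = setup
        inside = np.zeros(cm.n_cells, dtype=bool)
        inside[nb.members] = True
        counts_in, counts_out = [], []
        for seed in range(10):
            out = inject_signal(cm, nb, genes, cfg, seed=seed)
            for g in genes:
                row = out.values[out.gene_index(g)]
                counts_in.append((row[inside] > 0).sum())
                counts_out.append((row[~inside] > 0).sum())
        # Monte-Carlo check of the localization guarantee, in expectation
        assert np.mean(counts_out) <= np.mean(counts_in)

    def test_dispersion_estimator_moment_identity(self):
        rng = np.random.default_rng(0)
        theta_true, mu = 2.0, 3.0
        vals = rng.negative_binomial(theta_true, theta_true / (theta_true + mu), size=(200, 2000))
        cm = CountMatrix(vals, [f"g{i}" for i in range(200)], [f"c{j}" for j in range(2000)])
        _, _, theta = estimate_signal_params(cm)
        assert theta == pytest.approx(theta_true, rel=0.2)


class TestSimulateBenchmark:
    def test_reference_condition_untouched(self):
        from colodiff.simulate import split_background

        cfg = SimulationConfig(
            seed=4, background=BackgroundParams(n_genes=200, n_cells=250)
        )
        ds = simulate_benchmark(cfg)
        ref, _ = split_background(cfg.background, _seed_of(cfg, 1))
        np.testing.assert_array_equal(ds.counts1.values, ref.values)

    def test_truth_size(self):
        cfg = SimulationConfig(
            seed=4, n_perturbed_genes=12, background=BackgroundParams(n_genes=250, n_cells=250)
        )
        ds = simulate_benchmark(cfg)
        assert len(ds.truth_genes) == 12

    def test_bit_identical_regeneration(self):
        cfg = SimulationConfig(
            seed=9, background=BackgroundParams(n_genes=200, n_cells=250)
        )
        a = simulate_benchmark(cfg)
        b = simulate_benchmark(cfg)
        np.testing.assert_array_equal(a.counts1.values, b.counts1.values)
        np.testing.assert_array_equal(a.counts2.values, b.counts2.values)
        assert a.truth_genes == b.truth_genes
        np.testing.assert_array_equal(
            a.neighborhoods["signal@cond2"].members, b.neighborhoods["signal@cond2"].members
        )


def _seed_of(cfg, salt):
    from colodiff.simulate import _child_seed

    return _child_seed(cfg.seed, salt)
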