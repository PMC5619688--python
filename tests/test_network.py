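import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from mixt import (
    adjacency,
    build_network_modules,
    correlation_matrix,
    detect_modules,
    export_edges,
    merge_modules,
    topological_overlap,
)
from mixt.synthetic import SyntheticConfig, TissueConfig, generate
from .conftest import make_expression

from acceptance import tom_brute_force


def square(values, n=None):
    a = np.asarray(values, dtype=float)
    idx = [f"g{i}" for i in range(len(a))]
    return pd.DataFrame(a, index=idx, columns=idx)


class TestCorrelationMatrix:
    def test_identical_and_negated_rows(self):
        base = np.array([1.0, 3.0, 2.0, 5.0])
        em = make_expression(np.vstack([base, base, -base]))
        c = correlation_matrix(em)
        assert c.iloc[0, 1] == pytest.approx(1.0)
        assert c.iloc[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(c), 1.0)

    def test_matches_per_pair_pearson(self, rng):
        em = make_expression(rng.normal(size=(10, 20)))
        c = correlation_matrix(em)
        for i in range(10):
            for j in range(i + 1, 10):
                expected = pearsonr(em.values.iloc[i], em.values.iloc[j])[0]
                assert c.iloc[i, j] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(c.values, c.values.T, atol=1e-12)

    def test_zero_variance_gene_named(self, rng):
        x = rng.normal(size=(3, 10))
        x[1] = 4.2
        em = make_expression(x)
        with pytest.raises(ValueError, match="g1"):
            correlation_matrix(em)

    def test_too_few_samples(self, rng):
        em = make_expression(rng.normal(size=(4, 2)))
        with pytest.raises(ValueError, match="3 samples"):
            correlation_matrix(em)


class TestAdjacency:
    @pytest.mark.parametrize("s, beta, expected", [
        (1.0, 6, 1.0),
        (-0.5, 6, 0.015625),
        (0.0, 6, 0.0),
        (1.0, 12, 1.0),
    ])
    def test_soft_threshold_values(self, s, beta, expected):
        sim = square([[1.0, s], [s, 1.0]])
        assert adjacency(sim, beta=beta).iloc[0, 1] == pytest.approx(expected)

    def test_beta_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            adjacency(square(np.eye(2)), beta=0)

    def test_large_beta_approaches_indicator(self):
        vals = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 1.0], [0.0, 1.0, 1.0]])
        a = adjacency(square(vals), beta=200).to_numpy()
        assert np.allclose(a, (np.abs(vals) == 1.0).astype(float), atol=1e-30)


class TestTopologicalOverlap:
    def test_two_gene_hand_value(self):
        adj = square([[0.0, 0.5], [0.5, 0.0]])
        tom = topological_overlap(adj)
        # numerator 0.5, denominator min(0.5, 0.5) + 1 - 0.5
        assert tom.iloc[0, 1] == pytest.approx(0.5)
        assert tom.iloc[0, 0] == 1.0

    def test_identical_neighbors_full_adjacency_gives_one(self):
        # unit-weight clique: identical neighbor profiles and a_ij = 1
        adj = square([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        tom = topological_overlap(adj)
        assert tom.iloc[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        n = 20
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        fast = topological_overlap(square(a)).to_numpy()
        assert np.abs(fast - tom_brute_force(a)).max() < 1e-12


class TestDetectModules:
    def _planted(self, seed=7, sizes=(60, 60), corr=0.9, n=200, n_noise=0):
        n_genes = sum(sizes) + n_noise
        cfg = SyntheticConfig(
            seed=seed, n_patients=n, n_controls=0,
            tumor=TissueConfig(n_genes=n_genes, module_sizes=list(sizes),
                               module_corr=corr),
            blood=TissueConfig(n_genes=n_genes, module_sizes=list(sizes),
                               module_corr=corr))
        return generate(cfg)

    def test_two_planted_blocks_recovered_exactly(self):
        cohort, truth = self._planted()
        _, mods = build_network_modules(cohort.tumor)
        assert len(mods) == 2
        planted = truth.membership["tumor"]
        for label, genes in mods.modules().items():
            assert len(set(planted[genes])) == 1  # each module is one planted block
            assert len(genes) == 60

    def test_noise_genes_labeled_grey(self):
        cohort, truth = self._planted(n_noise=100)
        _, mods = build_network_modules(cohort.tumor)
        planted = truth.membership["tumor"]
        noise = planted.index[planted == "grey"]
        assert (mods.assignment[noise] == "grey").all()
        assert len(mods) == 2

    def test_split_block_remerged_by_eigengenes(self, rng):
        # two 60-gene sub-blocks whose factors correlate 0.85: the cut splits
        # them, the eigengene merge reunites them into a single module
        n = 200
        f1 = rng.standard_normal(n)
        f2 = 0.85 * f1 + np.sqrt(1 - 0.85**2) * rng.standard_normal(n)
        lam = np.sqrt(0.8 / 0.2)
        x = np.vstack([lam * f1 + rng.standard_normal((60, n)),
                       lam * f2 + rng.standard_normal((60, n))])
        em = make_expression(x)
        _, merged = build_network_modules(em, merge_threshold=0.75)
        assert len(merged) == 1
        _, unmerged = build_network_modules(em, merge_threshold=0.999)
        assert len(unmerged) == 2

    def test_gene_order_invariance(self, rng):
        cohort, _ = self._planted(seed=3)
        em = cohort.tumor
        perm = rng.permutation(len(em.gene_ids))
        shuffled = make_expression(em.values.to_numpy()[perm],
                                   genes=list(em.gene_ids[perm]),
                                   samples=list(em.sample_ids))
        _, mods_a = build_network_modules(em)
        _, mods_b = build_network_modules(shuffled)
        # identical partition up to labels
        a = mods_a.assignment.sort_index()
        b = mods_b.assignment.sort_index()
        cross = pd.crosstab(a, b)
        assert (cross.gt(0).sum(axis=1) == 1).all()
        assert (cross.gt(0).sum(axis=0) == 1).all()

    def test_merge_idempotent(self):
        cohort, _ = self._planted(seed=5)
        em = cohort.tumor
        _, mods = build_network_modules(em)
        again = merge_modules(mods.assignment, em, em.patient_samples)
        assert (again == mods.assignment).all()

    def test_too_few_genes_error(self, rng):
        em = make_expression(rng.normal(size=(10, 30)))
        tom = topological_overlap(adjacency(correlation_matrix(em)))
        with pytest.raises(ValueError, match="too few genes"):
            detect_modules(tom, em, min_module_size=30)

    def test_nonfinite_tom_error(self, rng):
        em = make_expression(rng.normal(size=(80, 30)))
        tom = topological_overlap(adjacency(correlation_matrix(em)))
        tom.iloc[0, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            detect_modules(tom, em, min_module_size=10)


class TestExportEdges:
    def test_all_zero_tom_gives_empty_graph(self):
        tom = square(np.eye(3))
        edges = export_edges(tom, threshold=0.1)
        assert len(edges) == 0

    def test_single_edge_two_nodes(self):
        vals = np.full((3, 3), 0.05)
        vals[0, 1] = vals[1, 0] = 0.2
        np.fill_diagonal(vals, 1.0)
        edges = export_edges(square(vals), threshold=0.1)
        assert len(edges) == 1
        assert set(edges.iloc[0][["gene_a", "gene_b"]]) == {"g0", "g1"}

    def test_zero_threshold_complete_graph(self, rng):
        n = 6
        vals = rng.uniform(0.01, 0.5, size=(n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        edges = export_edges(square(vals), threshold=0.0)
        assert len(edges) == n * (n - 1) // 2
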