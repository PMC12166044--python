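"""Network construction and module discovery against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netstrat.containers import ConfigurationError, DataError, ExpressionMatrix
from netstrat.coexpression import (
    adjacency,
    bicor,
    bicor_matrix,
    detect_modules,
    kme,
    module_eigengene,
    module_stability,
    select_variable_genes,
    topological_overlap,
    topological_significance,
)
from netstrat.containers import WeightedNetwork

from oracles import bicor_brute, tom_dissim_brute


def _expr(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"{prefix}{i}" for i in range(values.shape[0])],
            columns=[f"s{j}" for j in range(values.shape[1])],
        ),
        scale="log2",
    )


class TestSelectVariableGenes:
    def test_identity_when_all_requested(self, rng):
        expr = _expr(rng.normal(size=(10, 5)))
        out = select_variable_genes(expr, 10)
        pd.testing.assert_frame_equal(out.values, expr.values)

    def test_constant_gene_dropped_first(self, rng):
        vals = rng.normal(size=(6, 8))
        vals[3] = 2.5
        expr = _expr(vals)
        out = select_variable_genes(expr, 5)
        assert "g3" not in out.gene_ids

    def test_module_genes_enriched_in_selection(self):
        from netstrat.synthetic import generate_reference_cohort

        expr, truth = generate_reference_cohort(
            n_samples=80, n_genes=400, module_sizes=(100,), loading_range=(0.8, 1.2),
            noise_sd=0.5, seed=5,
        )
        out = select_variable_genes(expr, 100)
        module = set(truth.genes_of(1))
        frac = len(module & set(out.gene_ids)) / 100
        # var(module gene) = loading^2 + noise^2 >= 0.89 vs background 0.25
        assert frac > 0.9


class TestBicor:
    def test_self_and_anti_correlation(self, rng):
        x = rng.normal(size=30)
        assert bicor(x, x) == pytest.approx(1.0)
        assert bicor(x, -x) == pytest.approx(-1.0)

    def test_matches_direct_estimator_definition(self, rng):
        for _ in range(20):
            x = rng.normal(size=50)
            y = 0.3 * x + rng.normal(size=50)
            assert bicor(x, y) == pytest.approx(bicor_brute(x, y), abs=1e-12)

    def test_mad_zero_falls_back_to_pearson(self):
        # >half the values identical -> MAD = 0 -> Pearson on that vector
        x = np.array([1.0, 1.0, 1.0, 1.0, 2.0, 3.0])
        y = np.array([0.5, 1.2, 0.8, 1.1, 2.2, 2.9])
        expected = bicor_brute(x, y)
        assert bicor(x, y) == pytest.approx(expected, abs=1e-12)
        assert abs(bicor(x, y) - np.corrcoef(x, y)[0, 1]) < 0.5  # sane magnitude

    def test_constant_vector_undefined(self):
        r = bicor_matrix(np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]]))
        assert np.isnan(r[0, 1])

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            bicor([1.0, 2.0], [3.0, 4.0])


class TestAdjacency:
    def test_perfect_correlation_power_five(self, rng):
        x = rng.normal(size=20)
        expr = _expr(np.vstack([x, 2 * x + 1, -x]))
        net = adjacency(expr, power=5)
        assert net.adjacency[0, 1] == pytest.approx(1.0)
        assert net.adjacency[0, 2] == pytest.approx(0.0)  # signed-hybrid truncation

    def test_halfway_correlation_raised_to_power(self):
        # bicor 0.5 -> adjacency 0.5^5 = 0.03125
        assert 0.5**5 == 0.03125

    def test_monotone_in_correlation(self, rng):
        # increasing bicor never decreases adjacency
        x = rng.normal(size=100)
        rows = [x + rng.normal(scale=s, size=100) for s in (0.2, 0.6, 1.5)]
        expr = _expr(np.vstack([x] + rows))
        net = adjacency(expr, power=5)
        r = bicor_matrix(expr.values.to_numpy())
        order_r = np.argsort(r[0, 1:])
        order_a = np.argsort(net.adjacency[0, 1:])
        assert list(order_r) == list(order_a)

    def test_nonpositive_power_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            adjacency(_expr(rng.normal(size=(3, 5))), power=0)


class TestTopologicalOverlap:
    def test_two_gene_perfect_edge(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        net = WeightedNetwork(adjacency=a, gene_ids=pd.Index(["a", "b"]))
        d = topological_overlap(net)
        # k1 = k2 = 1: TOM = (0 + 1) / (1 + 1 - 1) = 1 -> dissimilarity 0
        assert d[0, 1] == pytest.approx(0.0)

    def test_empty_network_fully_dissimilar(self):
        a = np.zeros((4, 4))
        net = WeightedNetwork(adjacency=a, gene_ids=pd.Index(list("abcd")))
        d = topological_overlap(net)
        off = d[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        net = WeightedNetwork(adjacency=a, gene_ids=pd.Index([f"g{i}" for i in range(n)]))
        assert np.allclose(topological_overlap(net), tom_dissim_brute(a), atol=1e-12)


class TestDetectModules:
    def _block_dissim(self, sizes, within=0.05, between=1.0):
        n = sum(sizes)
        d = np.full((n, n), between)
        pos = 0
        for s in sizes:
            d[pos : pos + s, pos : pos + s] = within
            pos += s
        np.fill_diagonal(d, 0.0)
        return d, [f"g{i}" for i in range(n)]

    def test_two_planted_blocks_recovered_exactly(self):
        d, genes = self._block_dissim([50, 50])
        out = detect_modules(d, genes, min_size=30)
        assert out.module_sizes == {1: 50, 2: 50}
        assert out.labels.iloc[:50].nunique() == 1
        assert out.labels.iloc[50:].nunique() == 1

    def test_all_ones_dissimilarity_leaves_everything_unassigned(self):
        d, genes = self._block_dissim([60], within=1.0)
        out = detect_modules(d, genes, min_size=30)
        assert (out.labels == 0).all()

    def test_small_clusters_dissolved(self):
        d, genes = self._block_dissim([50, 10])
        out = detect_modules(d, genes, min_size=30, pam_stage=False)
        assert out.module_sizes == {1: 50}
        assert (out.labels.iloc[50:] == 0).all()

    def test_permutation_equivariance(self, rng):
        d, genes = self._block_dissim([40, 35], within=0.1)
        d += rng.uniform(0, 0.01, d.shape)
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        out = detect_modules(d, genes, min_size=20)
        perm = rng.permutation(len(genes))
        out_p = detect_modules(d[np.ix_(perm, perm)], [genes[i] for i in perm], min_size=20)
        # same partition of gene ids regardless of input order
        for m in out.module_ids:
            genes_m = set(out.genes_of(m))
            assert any(genes_m == set(out_p.genes_of(k)) for k in out_p.module_ids)

    def test_fewer_genes_than_min_size_warns(self):
        d, genes = self._block_dissim([10])
        with pytest.warns(UserWarning):
            out = detect_modules(d, genes, min_size=30)
        assert (out.labels == 0).all()


class TestEigengene:
    def test_rank_one_module_recovers_factor(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=25)
        loadings = rng.uniform(0.5, 1.5, 8)
        vals = np.outer(loadings, f) + 5.0
        expr = _expr(vals)
        model, scores = module_eigengene(expr, expr.gene_ids)
        assert abs(np.corrcoef(scores["PC1"], f)[0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_two_identical_genes_pc1_explains_everything(self, rng):
        x = rng.normal(size=10)
        expr = _expr(np.vstack([x, x]))
        model, _ = module_eigengene(expr, expr.gene_ids)
        assert model.explained_variance[0] == pytest.approx(1.0)

    def test_orientation_sign_invariant(self, rng):
        # orientation ties PC1 to mean standardized expression, so the
        # arbitrary sign of the decomposition can never flip reported scores
        expr = _expr(rng.normal(size=(12, 30)))
        _, s1 = module_eigengene(expr, expr.gene_ids)
        flipped = ExpressionMatrix(expr.values.iloc[::-1], scale="log2")
        _, s2 = module_eigengene(flipped, flipped.gene_ids)
        assert np.allclose(s1["PC1"], s2["PC1"], atol=1e-9)
        z = expr.values.sub(expr.values.mean(axis=1), axis=0).div(
            expr.values.std(axis=1, ddof=1), axis=0
        )
        assert np.corrcoef(s1["PC1"], z.mean(axis=0))[0, 1] >= 0

    def test_pc_axes_orthogonal(self, rng):
        expr = _expr(rng.normal(size=(15, 40)))
        model, _ = module_eigengene(expr, expr.gene_ids)
        assert abs(np.dot(model.eigenvectors[0], model.eigenvectors[1])) < 1e-9
        assert np.linalg.norm(model.eigenvectors[0]) == pytest.approx(1.0)

    def test_constant_gene_dropped_with_warning(self, rng):
        vals = rng.normal(size=(5, 10))
        vals[2] = 3.0
        expr = _expr(vals)
        with pytest.warns(UserWarning):
            model, _ = module_eigengene(expr, expr.gene_ids)
        assert "g2" not in model.gene_ids


class TestKme:
    def test_top_loading_gene_in_noiseless_module(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=30)
        expr = _expr(np.vstack([2 * f, 1 * f, 0.5 * f]))
        _, scores = module_eigengene(expr, expr.gene_ids)
        k = kme(expr, scores["PC1"])
        assert k.abs().max() == pytest.approx(1.0, abs=1e-9)

    def test_background_gene_kme_near_zero(self, rng):
        n = 400
        f = rng.normal(size=n)
        background = rng.normal(size=(50, n))
        expr = _expr(background)
        k = kme(expr, pd.Series(f, index=expr.sample_ids))
        assert k.abs().mean() < 2 / np.sqrt(n)

    def test_constant_gene_flagged_nan(self, rng):
        vals = rng.normal(size=(3, 10))
        vals[1] = 7.0
        expr = _expr(vals)
        k = kme(expr, pd.Series(rng.normal(size=10), index=expr.sample_ids))
        assert np.isnan(k["g1"]) and not np.isnan(k["g0"])


class TestSignificanceGate:
    def test_planted_module_passes_random_set_does_not(self, small_reference):
        expr, truth = small_reference
        net = adjacency(expr, power=5)
        d = topological_overlap(net)
        found = detect_modules(d, expr.gene_ids)
        sig = topological_significance(net, found, n_random=100, seed=0)
        assert sig["passed"].all()
        # a random pseudo-module of the same size should sit inside the null
        rng = np.random.default_rng(1)
        pseudo = pd.Series(0, index=expr.gene_ids)
        pseudo[rng.choice(expr.gene_ids, 40, replace=False)] = 1
        from netstrat.containers import ModuleAssignment

        sig2 = topological_significance(
            net, ModuleAssignment(labels=pseudo), n_random=100, seed=2
        )
        assert abs(sig2.loc[1, "median_z"]) < 3

    def test_module_equal_to_universe_has_zero_z(self, rng):
        vals = rng.normal(size=(30, 20))
        expr = _expr(vals)
        net = adjacency(expr, power=2)
        labels = pd.Series(1, index=expr.gene_ids)
        from netstrat.containers import ModuleAssignment

        sig = topological_significance(net, ModuleAssignment(labels=labels),
                                       n_random=20, seed=0)
        assert sig.loc[1, "median_z"] == pytest.approx(0.0, abs=1e-9)


class TestStability:
    def test_single_full_iteration_is_self_comparison(self, small_reference):
        expr, truth = small_reference
        net = adjacency(expr)
        d = topological_overlap(net)
        found = detect_modules(d, expr.gene_ids)
        stab = module_stability(expr, found, n_iter=1, frac=1.0, seed=0)
        assert np.allclose(stab.to_numpy(), 1.0)

    def test_planted_blocks_more_stable_than_noise(self):
        from netstrat.synthetic import generate_reference_cohort

        expr, truth = generate_reference_cohort(
            n_samples=50, n_genes=120, module_sizes=(40,), loading_range=(0.8, 1.2),
            noise_sd=0.4, seed=9,
        )
        net = adjacency(expr)
        found = detect_modules(topological_overlap(net), expr.gene_ids)
        stab = module_stability(expr, found, n_iter=8, frac=0.632, seed=1)
        assert stab.min() > 0.6
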