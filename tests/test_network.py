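import numpy as np
import pandas as pd
import pytest

from stemniche.matrix import ExpressionMatrix
from stemniche.network import (
    NetworkConfig,
    Signature,
    _correlation,
    adjacency_from_correlation,
    derive_signature,
    detect_modules,
    malignant_markers,
    module_eigengene,
    module_eigengenes,
    module_trait_correlation,
    pick_soft_threshold,
    tom_similarity,
)


def brute_force_tom(a):
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.zeros_like(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


class TestTom:
    def test_complete_graph(self):
        a = np.ones((5, 5)) - np.eye(5)
        tom = tom_similarity(a)
        np.testing.assert_allclose(tom, 1.0)

    def test_zero_adjacency(self):
        tom = tom_similarity(np.zeros((4, 4)))
        np.testing.assert_allclose(tom, np.eye(4))

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            a = rng.uniform(0.0, 1.0, size=(6, 6))
            a = (a + a.T) / 2.0
            np.fill_diagonal(a, 0.0)
            np.testing.assert_allclose(tom_similarity(a), brute_force_tom(a), atol=1e-12)

    def test_rejects_out_of_range(self):
        a = np.full((3, 3), 2.0)
        np.fill_diagonal(a, 0.0)
        with pytest.raises(ValueError):
            tom_similarity(a)

    def test_rejects_nonzero_diagonal(self):
        with pytest.raises(ValueError):
            tom_similarity(np.eye(3))


class TestSoftThreshold:
    def test_fit_table_one_row_per_power(self, rng):
        x = rng.normal(size=(40, 60))
        config = NetworkConfig(power_grid=(1, 3, 5))
        _, table = pick_soft_threshold(x, config)
        assert list(table["power"]) == [1, 3, 5]

    def test_scale_free_structure_gets_low_power(self, rng):
        """Hub-structured expression reaches the R2 target at a low power."""
        n_mc, n_genes = 60, 200
        # latent hub factors with power-law loadings concentrate connectivity
        factors = rng.normal(size=(n_mc, 6))
        loadings = rng.normal(size=(6, n_genes)) * (
            rng.pareto(2.0, size=n_genes) + 0.1
        )
        x = factors @ loadings + rng.normal(0.0, 0.5, size=(n_mc, n_genes))
        power, table = pick_soft_threshold(x, NetworkConfig(r2_target=0.8))
        ok = table[table["r2"] >= 0.8]
        if len(ok):
            assert power == ok["power"].iloc[0]
        else:
            assert power == table.loc[table["r2"].idxmax(), "power"]

    def test_too_few_metacells_errors(self, rng):
        with pytest.raises(ValueError):
            pick_soft_threshold(rng.normal(size=(10, 30)))

    def test_constant_gene_dropped_with_warning(self, rng):
        x = rng.normal(size=(35, 20))
        x[:, 0] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            pick_soft_threshold(x)

    def test_adjacency_monotone_in_power(self, rng):
        cor = _correlation(rng.normal(size=(10, 50)))
        a2 = adjacency_from_correlation(cor, 2, "unsigned")
        a4 = adjacency_from_correlation(cor, 4, "unsigned")
        off = ~np.eye(10, dtype=bool)
        assert np.all(a4[off] <= a2[off] + 1e-15)


class TestModules:
    def planted_blocks(self, rng, n_mc=50, block=50, noise=400):
        f1 = rng.normal(size=n_mc)
        f2 = rng.normal(size=n_mc)
        x1 = f1[:, None] + rng.normal(0.0, 0.4, size=(n_mc, block))
        x2 = f2[:, None] + rng.normal(0.0, 0.4, size=(n_mc, block))
        xn = rng.normal(size=(n_mc, noise))
        x = np.hstack([x1, x2, xn])
        genes = (
            [f"A{i}" for i in range(block)]
            + [f"B{i}" for i in range(block)]
            + [f"N{i}" for i in range(noise)]
        )
        return x, genes

    def test_two_planted_blocks_recovered(self, rng):
        x, genes = self.planted_blocks(rng)
        cor = _correlation(x.T)
        adj = adjacency_from_correlation(cor, 6, "unsigned")
        gm = detect_modules(tom_similarity(adj), genes, min_module_size=30)
        non_grey = [m for m in gm.unique() if m != "grey"]
        assert len(non_grey) >= 2
        found_a = found_b = False
        for m in non_grey:
            members = set(gm.index[gm == m])
            a_set = {g for g in genes if g.startswith("A")}
            b_set = {g for g in genes if g.startswith("B")}
            if len(members & a_set) / len(members | a_set) >= 0.8:
                found_a = True
            if len(members & b_set) / len(members | b_set) >= 0.8:
                found_b = True
        assert found_a and found_b

    def test_min_module_size_all_grey(self, rng):
        x, genes = self.planted_blocks(rng, block=5, noise=10)
        cor = _correlation(x.T)
        tom = tom_similarity(adjacency_from_correlation(cor, 6, "unsigned"))
        with pytest.warns(UserWarning, match="grey"):
            gm = detect_modules(tom, genes, min_module_size=100)
        assert (gm == "grey").all()

    def test_labels_partition_genes(self, signature_run):
        gm = signature_run.modules.gene_module
        assert gm.index.is_unique
        assert gm.notna().all()


class TestEigengene:
    def test_identical_genes(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        expr = pd.DataFrame({f"g{i}": profile for i in range(4)})
        eig = module_eigengene(expr, expr.columns)
        r = np.corrcoef(eig, profile)[0, 1]
        assert abs(r) > 1.0 - 1e-9
        assert r > 0  # orientation rule

    def test_matches_svd_oracle(self, rng):
        x = rng.normal(size=(12, 5))
        expr = pd.DataFrame(x, columns=[f"g{i}" for i in range(5)])
        eig = module_eigengene(expr, expr.columns)
        z = (x - x.mean(axis=0)) / x.std(axis=0)
        u, _, _ = np.linalg.svd(z, full_matrices=False)
        oracle = u[:, 0] if np.dot(u[:, 0], z.mean(axis=1)) >= 0 else -u[:, 0]
        np.testing.assert_allclose(eig, oracle, atol=1e-9)

    def test_orientation_always_positive(self, rng):
        for _ in range(10):
            x = rng.normal(size=(15, 6))
            expr = pd.DataFrame(x, columns=[f"g{i}" for i in range(6)])
            eig = module_eigengene(expr, expr.columns)
            z = (x - x.mean(axis=0)) / x.std(axis=0)
            assert np.corrcoef(eig, z.mean(axis=1))[0, 1] >= 0

    def test_unit_norm(self, signature_run):
        eg = signature_run.modules.eigengenes
        np.testing.assert_allclose(np.linalg.norm(eg.to_numpy(), axis=0), 1.0)

    def test_degenerate_module_errors(self):
        expr = pd.DataFrame({"g0": np.ones(5), "g1": np.arange(5.0)})
        with pytest.raises(ValueError, match="degenerate"):
            module_eigengene(expr, ["g0", "g1"])


class TestTraitCorrelation:
    def test_trait_equals_eigengene(self, rng):
        eg = pd.DataFrame({"m": rng.normal(size=50)})
        tab = module_trait_correlation(eg, eg["m"].to_numpy())
        assert tab["r"].iloc[0] == pytest.approx(1.0)
        assert tab["p"].iloc[0] < 1e-20

    def test_anticorrelated(self):
        eg = pd.DataFrame({"m": [1.0, 2.0, 3.0]})
        tab = module_trait_correlation(eg, np.array([3.0, 2.0, 1.0]))
        assert tab["r"].iloc[0] == pytest.approx(-1.0)

    def test_independent_noise_small_r(self, rng):
        hits = 0
        for _ in range(50):
            eg = pd.DataFrame({"m": rng.normal(size=100)})
            tab = module_trait_correlation(eg, rng.normal(size=100))
            hits += abs(tab["r"].iloc[0]) >= 0.3
        assert hits <= 2

    def test_zero_variance_trait_errors(self, rng):
        eg = pd.DataFrame({"m": rng.normal(size=20)})
        with pytest.raises(ValueError):
            module_trait_correlation(eg, np.ones(20))


class TestMarkersAndSignature:
    def make_two_group(self, rng, shift_gene_factor=4.0, n=200):
        counts = rng.poisson(2.0, size=(20, n)).astype(float)
        mask = np.zeros(n, dtype=bool)
        mask[: n // 2] = True
        counts[0, mask] = rng.poisson(2.0 * shift_gene_factor, size=mask.sum())
        m = ExpressionMatrix(
            counts=counts,
            genes=np.asarray([f"g{i}" for i in range(20)], dtype=object),
            obs_names=np.asarray([f"c{i}" for i in range(n)], dtype=object),
        )
        return m, mask

    def test_shifted_gene_included_flat_excluded(self, rng):
        m, mask = self.make_two_group(rng)
        markers = malignant_markers(m, mask)
        assert "g0" in markers
        assert "g1" not in markers

    def test_exclusive_gene_included(self, rng):
        m, mask = self.make_two_group(rng)
        counts = m.dense_counts()
        counts[2, :] = 0.0
        counts[2, mask] = 5.0
        m2 = ExpressionMatrix(counts=counts, genes=m.genes, obs_names=m.obs_names)
        assert "g2" in malignant_markers(m2, mask)

    def test_empty_group_errors(self, rng):
        m, _ = self.make_two_group(rng)
        with pytest.raises(ValueError):
            malignant_markers(m, np.zeros(m.n_obs, dtype=bool))

    def test_tiny_group_warns_p_one(self, rng):
        m, _ = self.make_two_group(rng, n=20)
        mask = np.zeros(20, dtype=bool)
        mask[:2] = True
        with pytest.warns(UserWarning):
            markers = malignant_markers(m, mask)
        assert markers == []  # p forced to 1 blocks every gene

    def test_derive_signature_intersection(self):
        sig = derive_signature(["A", "B", "C"], ["B", "C", "D"], name="x")
        assert sig.genes == ["B", "C"]

    def test_disjoint_sets_error(self):
        with pytest.raises(ValueError, match="disjoint"):
            derive_signature(["A"], ["B"])

    def test_signature_requires_genes(self):
        with pytest.raises(ValueError):
            Signature(name="empty", genes=[])
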