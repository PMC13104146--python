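import networkx as nx
import numpy as np
import pandas as pd
import pytest

from stemniche import io
from stemniche.matrix import ExpressionMatrix, SpotGrid
from stemniche.niche import (
    caf_subtype_scores,
    colocalization,
    compare_regions,
    deconvolve_spots,
    extract_boundary,
    lattice_adjacency,
    spot_correlation,
)
from stemniche.sim.spatial import lattice_distance


def full_grid(n_rows, n_cols, lattice="square", n_genes=3):
    coords = [(r, c) for r in range(n_rows) for c in range(n_cols)]
    n = len(coords)
    m = ExpressionMatrix(
        counts=np.ones((n_genes, n)),
        genes=np.asarray([f"g{i}" for i in range(n_genes)], dtype=object),
        obs_names=np.asarray([f"s{i}" for i in range(n)], dtype=object),
    )
    return SpotGrid(
        matrix=m,
        array_row=[r for r, _ in coords],
        array_col=[c for _, c in coords],
        lattice=lattice,
    )


def oracle_boundary(grid, tumor, width):
    """Independent oracle: closed-form lattice metric (valid on full
    rectangular lattices, where graph distance equals the metric)."""
    rows, cols = grid.array_row, grid.array_col
    region = np.full(grid.n_spots, "non_tumor", dtype=object)
    nt = ~tumor
    for i in np.where(tumor)[0]:
        d = lattice_distance(rows[i], cols[i], rows[nt], cols[nt], grid.lattice).min()
        region[i] = "boundary" if d <= width else "core"
    return region


class TestLattice:
    def test_interior_hex_degree_six(self):
        grid = full_grid(5, 5, "hex")
        g = lattice_adjacency(grid)
        center = 2 * 5 + 2
        assert g.degree[center] == 6

    def test_corner_square_degree_two(self):
        grid = full_grid(4, 4, "square")
        g = lattice_adjacency(grid)
        assert g.degree[0] == 2

    def test_adjacency_symmetric(self):
        g = lattice_adjacency(full_grid(6, 6, "hex"))
        assert isinstance(g, nx.Graph)  # undirected by construction
        for u, v in g.edges:
            assert g.has_edge(v, u)

    def test_duplicate_coordinates_rejected(self):
        m = ExpressionMatrix(
            counts=np.ones((2, 2)),
            genes=np.asarray(["a", "b"], dtype=object),
            obs_names=np.asarray(["s0", "s1"], dtype=object),
        )
        with pytest.raises(ValueError, match="duplicate"):
            SpotGrid(matrix=m, array_row=[0, 0], array_col=[0, 0])


class TestBoundary:
    def test_seven_by_seven_block(self):
        """7x7 tumor block on an 11x11 square lattice, width 2: 40 boundary
        and 9 core spots."""
        grid = full_grid(11, 11, "square")
        tumor = (
            (grid.array_row >= 2) & (grid.array_row <= 8)
            & (grid.array_col >= 2) & (grid.array_col <= 8)
        )
        labels = extract_boundary(tumor, lattice_adjacency(grid), width=2)
        assert (labels.region == "boundary").sum() == 40
        assert (labels.region == "core").sum() == 9

    def test_single_isolated_tumor_spot(self):
        grid = full_grid(5, 5, "square")
        tumor = np.zeros(25, dtype=bool)
        tumor[12] = True
        labels = extract_boundary(tumor, lattice_adjacency(grid), width=2)
        assert (labels.region == "boundary").sum() == 1
        assert (labels.region == "core").sum() == 0

    def test_width_zero_no_boundary(self):
        grid = full_grid(5, 5, "square")
        tumor = np.ones(25, dtype=bool)
        tumor[0] = False
        labels = extract_boundary(tumor, lattice_adjacency(grid), width=0)
        assert (labels.region == "boundary").sum() == 0

    @pytest.mark.parametrize("lattice", ["square", "hex"])
    def test_matches_metric_oracle(self, lattice, rng):
        for _ in range(5):
            grid = full_grid(12, 14, lattice)
            tumor = rng.random(grid.n_spots) < 0.4
            if tumor.sum() == 0 or (~tumor).sum() == 0:
                continue
            labels = extract_boundary(tumor, lattice_adjacency(grid), width=2)
            np.testing.assert_array_equal(
                labels.region, oracle_boundary(grid, tumor, 2)
            )

    def test_no_tumor_errors(self):
        grid = full_grid(4, 4, "square")
        with pytest.raises(ValueError):
            extract_boundary(np.zeros(16, dtype=bool), lattice_adjacency(grid))

    def test_all_tumor_warns(self):
        grid = full_grid(4, 4, "square")
        with pytest.warns(UserWarning):
            labels = extract_boundary(np.ones(16, dtype=bool), lattice_adjacency(grid))
        assert (labels.region == "boundary").all()


class TestCompareRegions:
    def make_labels(self, n_b, n_c):
        from stemniche.niche import NicheLabels

        region = np.asarray(["boundary"] * n_b + ["core"] * n_c, dtype=object)
        return NicheLabels(region=region, distance_to_margin=np.zeros(n_b + n_c))

    def test_null_calibration(self, rng):
        rejections = 0
        for _ in range(200):
            vals = rng.normal(size=60)
            res = compare_regions(vals, self.make_labels(30, 30))
            rejections += res["p"] <= 0.05
        assert rejections / 200 <= 0.10

    def test_planted_shift_detected(self, rng):
        vals = np.concatenate([rng.normal(3.0, 1.0, 50), rng.normal(0.0, 1.0, 50)])
        res = compare_regions(vals, self.make_labels(50, 50))
        assert res["p"] < 0.01
        assert res["median_diff"] > 0

    def test_swapped_labels_flip_sign(self, rng):
        vals = np.concatenate([rng.normal(3.0, 1.0, 50), rng.normal(0.0, 1.0, 50)])
        a = compare_regions(vals, self.make_labels(50, 50))
        b = compare_regions(vals[::-1], self.make_labels(50, 50))
        assert np.sign(a["median_diff"]) == -np.sign(b["median_diff"])

    def test_degenerate_sizes_error(self, rng):
        with pytest.raises(ValueError):
            compare_regions(rng.normal(size=4), self.make_labels(2, 2))


class TestColocalization:
    def test_direct_count(self):
        a = np.array([1, 1, 1, 1, 0.0])
        b = np.array([1, 1, 1, 0, 1.0])
        classes, pct = colocalization(a, b)
        assert pct == pytest.approx(60.0)
        assert list(classes) == ["A+B+", "A+B+", "A+B+", "A+only", "B+only"]

    def test_identical_vectors_hundred_percent(self, rng):
        a = rng.poisson(1.0, 100).astype(float)
        a[0] = 1.0  # ensure at least one expressing spot
        _, pct = colocalization(a, a)
        assert pct == 100.0

    def test_scaling_invariance(self, rng):
        a = rng.poisson(1.0, 200).astype(float)
        b = rng.poisson(1.0, 200).astype(float)
        a[0] = b[0] = 1.0
        _, p1 = colocalization(a, b)
        _, p2 = colocalization(a * 7.3, b * 0.2)
        assert p1 == p2

    def test_binomial_recovery(self, rng):
        """Planted 0.8 double-positive fraction on 2000 spots recovered
        within +-5 points."""
        n = 2000
        cls = rng.choice(["AB", "A", "B"], size=n, p=[0.8, 0.1, 0.1])
        a = np.isin(cls, ["AB", "A"]).astype(float)
        b = np.isin(cls, ["AB", "B"]).astype(float)
        _, pct = colocalization(a, b)
        assert abs(pct - 80.0) <= 5.0

    def test_no_expression_errors(self):
        with pytest.raises(ValueError):
            colocalization(np.zeros(10), np.zeros(10))


class TestSpotCorrelation:
    def test_identical(self, rng):
        a = rng.normal(size=50)
        r, _ = spot_correlation(a, a, "pearson")
        assert r == pytest.approx(1.0)

    def test_monotone_map_spearman_one(self, rng):
        a = rng.normal(size=50)
        r, _ = spot_correlation(a, np.exp(a), "spearman")
        assert r == pytest.approx(1.0)

    def test_null_small(self, rng):
        hits = 0
        for _ in range(100):
            r, _ = spot_correlation(rng.normal(size=500), rng.normal(size=500), "pearson")
            hits += abs(r) >= 0.15
        assert hits <= 3

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            spot_correlation(np.ones(20), np.arange(20.0))


class TestDeconvolution:
    def profiles(self):
        genes = [f"g{i}" for i in range(60)]
        rng = np.random.default_rng(1)
        p = rng.uniform(1.0, 10.0, size=(3, 60))
        p[0, :20] *= 10
        p[1, 20:40] *= 10
        p[2, 40:] *= 10
        # equal per-cell depth so count-share equals cell-share proportions
        p = p / p.sum(axis=1, keepdims=True) * 1e4
        return pd.DataFrame(p, index=["t0", "t1", "t2"], columns=genes)

    def grid_from_lam(self, lam):
        n = lam.shape[1]
        side = int(np.ceil(np.sqrt(n)))
        m = ExpressionMatrix(
            counts=lam,
            genes=np.asarray([f"g{i}" for i in range(lam.shape[0])], dtype=object),
            obs_names=np.asarray([f"s{i}" for i in range(n)], dtype=object),
        )
        return SpotGrid(
            matrix=m,
            array_row=[i // side for i in range(n)],
            array_col=[i % side for i in range(n)],
            lattice="square",
        )

    def test_pure_spot(self):
        prof = self.profiles()
        lam = prof.to_numpy().T[:, [0, 1, 2]]  # three pure spots
        res = deconvolve_spots(self.grid_from_lam(lam), prof)
        np.testing.assert_allclose(np.diag(res.to_numpy()), 1.0, atol=1e-6)

    def test_half_half_mixture(self):
        prof = self.profiles()
        mix = 0.5 * prof.iloc[0].to_numpy() + 0.5 * prof.iloc[1].to_numpy()
        res = deconvolve_spots(self.grid_from_lam(mix[:, None]), prof)
        assert abs(res.iloc[0, 0] - 0.5) < 0.01
        assert abs(res.iloc[0, 1] - 0.5) < 0.01

    def test_rows_sum_to_one(self, rng):
        prof = self.profiles()
        lam = rng.uniform(1.0, 5.0, size=(60, 9))
        res = deconvolve_spots(self.grid_from_lam(lam), prof)
        np.testing.assert_allclose(res.sum(axis=1), 1.0, atol=1e-6)
        assert (res.to_numpy() >= -1e-12).all()

    def test_rank_deficient_errors(self):
        prof = self.profiles()
        prof.iloc[2] = prof.iloc[0]
        with pytest.raises(ValueError, match="rank"):
            deconvolve_spots(self.grid_from_lam(np.ones((60, 2))), prof)

    def test_recovers_planted_proportions(self, spatial_section, reference_profiles):
        grid, truth = spatial_section
        res = deconvolve_spots(grid, reference_profiles)
        shared = [c for c in truth.proportions.columns]
        est = res[shared].to_numpy()
        true = truth.proportions.to_numpy()
        err = np.abs(est - true).mean()
        assert err < 0.15


class TestCafScores:
    def test_single_gene_signature(self, rng):
        counts = rng.poisson(3.0, size=(4, 30)).astype(float) + 1
        m = ExpressionMatrix(
            counts=counts,
            genes=np.asarray(["FAP", "a", "b", "c"], dtype=object),
            obs_names=np.asarray([f"s{i}" for i in range(30)], dtype=object),
        )
        grid = SpotGrid(
            matrix=m, array_row=list(range(30)), array_col=[0] * 30, lattice="square"
        )
        scores = caf_subtype_scores(grid, {"myCAF": ["FAP"]})
        np.testing.assert_allclose(
            scores["myCAF"].to_numpy(), m.normalized(log=True)[0]
        )

    def test_planted_ring_mycaf_enriched(self, spatial_section):
        grid, truth = spatial_section
        caf = caf_subtype_scores(
            grid, io.read_gmt(io.package_data_path("caf_signatures.gmt"))
        )
        boundary = truth.region == "boundary"
        far = truth.region == "non_tumor"
        assert caf.loc[boundary, "myCAF"].mean() > caf.loc[far, "myCAF"].mean()
        assert np.isfinite(caf.to_numpy()).all()

    def test_mycaf_tracks_csc_gene(self, spatial_section):
        grid, _ = spatial_section
        caf = caf_subtype_scores(
            grid, io.read_gmt(io.package_data_path("caf_signatures.gmt"))
        )
        dsg2 = grid.matrix.dense_counts()[list(grid.matrix.genes).index("DSG2")]
        r, _ = spot_correlation(dsg2, caf["myCAF"].to_numpy(), "pearson")
        assert r > 0.3

    def test_empty_signature_errors(self, spatial_section):
        grid, _ = spatial_section
        with pytest.raises(ValueError):
            caf_subtype_scores(grid, {"x": ["NOT_A_GENE"]})
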