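import itertools

import numpy as np
import pytest

from streamfd.trait_space import DistanceMatrix
from streamfd.fd_metrics import (
    InsufficientSpeciesError,
    community_weighted_mean,
    functional_dispersion,
    functional_distinctiveness,
    functional_divergence,
    functional_evenness,
    functional_richness,
    rao_q,
    redundancy_slope,
)

from conftest import random_fuzzy_traits, space_from_coords


def dmat_from(arr, taxa=None):
    arr = np.asarray(arr, dtype=float)
    taxa = tuple(taxa) if taxa else tuple(f"t{i}" for i in range(arr.shape[0]))
    return DistanceMatrix(taxa, arr)


class TestFunctionalRichness:
    def test_pool_equals_present_gives_one(self):
        sp = space_from_coords([[0, 0], [1, 0], [0, 1], [0.6, 0.6]])
        raw, std = functional_richness(sp, list(sp.taxa))
        assert std == pytest.approx(1.0, abs=1e-12)

    def test_triangle_area(self):
        sp = space_from_coords([[0, 0], [1, 0], [0, 1]])
        raw, _ = functional_richness(sp, list(sp.taxa))
        assert raw == pytest.approx(0.5, abs=1e-9)

    def test_hull_volume_matches_tetrahedral_decomposition(self):
        # signed simplex decomposition from an interior point as oracle
        from scipy.spatial import ConvexHull

        rng = np.random.default_rng(42)
        for _ in range(20):
            pts = rng.uniform(size=(10, 3))
            sp = space_from_coords(pts)
            raw, _ = functional_richness(sp, list(sp.taxa))
            hull = ConvexHull(pts)
            center = pts.mean(axis=0)
            vol = 0.0
            for simplex in hull.simplices:
                mat = pts[simplex] - center
                vol += abs(np.linalg.det(mat)) / 6.0
            assert raw == pytest.approx(vol, rel=1e-9)

    def test_hull_grows_when_taxon_added(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(size=(9, 2))
        sp = space_from_coords(pts)
        taxa = list(sp.taxa)
        raw_small, _ = functional_richness(sp, taxa[:6], pool=taxa)
        raw_big, _ = functional_richness(sp, taxa[:7], pool=taxa)
        assert raw_big >= raw_small - 1e-12

    def test_degenerate_set_flagged_missing(self):
        sp = space_from_coords([[0.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
        raw, std = functional_richness(sp, list(sp.taxa))
        assert np.isnan(raw) and np.isnan(std)


class TestFunctionalEvenness:
    def test_equidistant_collinear_equal_weights_is_one(self):
        sp = space_from_coords([[0.0], [1.0], [2.0]])
        w = np.full(3, 1 / 3)
        assert functional_evenness(sp, list(sp.taxa), w) == pytest.approx(1.0, abs=1e-9)

    def test_clumped_fixture(self):
        # 1-D points 0, 0.1, 2 with equal weights -> PEW (0.05, 0.95) -> 0.1
        sp = space_from_coords([[0.0], [0.1], [2.0]])
        w = np.full(3, 1 / 3)
        assert functional_evenness(sp, list(sp.taxa), w) == pytest.approx(0.1, abs=1e-9)

    def test_mst_matches_exhaustive_minimum_spanning_tree(self):
        # total MST length equals the exhaustive minimum over spanning trees
        import networkx as nx
        from scipy.sparse.csgraph import minimum_spanning_tree
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(11)
        for _ in range(20):
            s = int(rng.integers(4, 7))
            pts = rng.uniform(size=(s, 2))
            dmat = squareform(pdist(pts))
            mst_len = minimum_spanning_tree(dmat).sum()
            g = nx.complete_graph(s)
            best = np.inf
            for edges in itertools.combinations(g.edges, s - 1):
                t = nx.Graph(edges)
                if t.number_of_nodes() == s and nx.is_tree(t):
                    best = min(best, sum(dmat[i, j] for i, j in edges))
            assert mst_len == pytest.approx(best, rel=1e-12)

    def test_too_few_species(self):
        sp = space_from_coords([[0.0], [1.0]])
        with pytest.raises(InsufficientSpeciesError):
            functional_evenness(sp, list(sp.taxa), np.array([0.5, 0.5]))


class TestFunctionalDivergence:
    def test_equilateral_triangle_any_weights_is_one(self):
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        sp = space_from_coords(pts)
        for w in ([1 / 3] * 3, [0.7, 0.2, 0.1]):
            assert functional_divergence(sp, list(sp.taxa), np.array(w)) == pytest.approx(
                1.0, abs=1e-9
            )

    def test_collinear_hand_fixture(self):
        sp = space_from_coords([[0.0], [1.0], [2.0]])
        w = np.full(3, 1 / 3)
        assert functional_divergence(sp, list(sp.taxa), w) == pytest.approx(0.6, abs=1e-9)

    def test_matches_formula_transcription_on_random_communities(self):
        from scipy.spatial import ConvexHull

        rng = np.random.default_rng(13)
        for _ in range(20):
            s = int(rng.integers(4, 10))
            pts = rng.uniform(size=(s, 2))
            w = rng.dirichlet(np.ones(s))
            sp = space_from_coords(pts)
            got = functional_divergence(sp, list(sp.taxa), w)
            verts = ConvexHull(pts).vertices
            g = pts[verts].mean(axis=0)
            dg = np.sqrt(((pts - g) ** 2).sum(axis=1))
            dbar = dg.mean()
            dd = float((w * (dg - dbar)).sum())
            dabs = float((w * np.abs(dg - dbar)).sum())
            expected = (dd + dbar) / (dabs + dbar)
            assert got == pytest.approx(expected, abs=1e-12)
            assert 0.0 <= got <= 1.0

    def test_coincident_taxa_flagged(self):
        sp = space_from_coords([[1.0, 1.0]] * 4)
        assert np.isnan(functional_divergence(sp, list(sp.taxa), np.full(4, 0.25)))


class TestFunctionalDispersion:
    def test_single_taxon_zero(self):
        sp = space_from_coords([[3.0, 4.0]])
        assert functional_dispersion(sp, list(sp.taxa), np.array([1.0])) == 0.0

    def test_two_taxa_equal_weights_half_distance(self):
        sp = space_from_coords([[0.0], [1.0]])
        assert functional_dispersion(sp, list(sp.taxa), np.array([0.5, 0.5])) == pytest.approx(0.5)

    def test_weighted_hand_fixture(self):
        sp = space_from_coords([[0.0], [1.0]])
        w = np.array([0.75, 0.25])
        assert functional_dispersion(sp, list(sp.taxa), w) == pytest.approx(0.375, abs=1e-9)

    def test_invariant_to_order_and_split_duplication(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(size=(6, 3))
        w = rng.dirichlet(np.ones(6))
        sp = space_from_coords(pts)
        taxa = list(sp.taxa)
        base = functional_dispersion(sp, taxa, w)
        perm = rng.permutation(6)
        sp2 = space_from_coords(pts[perm], taxa=[taxa[i] for i in perm])
        assert functional_dispersion(sp2, [taxa[i] for i in perm], w[perm]) == pytest.approx(base)
        # duplicate taxon 0 with split abundance
        pts_dup = np.vstack([pts, pts[0]])
        w_dup = np.concatenate([w, [w[0] / 2]])
        w_dup[0] /= 2
        sp3 = space_from_coords(pts_dup, taxa=taxa + ["t0_dup"])
        assert functional_dispersion(sp3, taxa + ["t0_dup"], w_dup) == pytest.approx(base)


class TestRaoQ:
    def test_single_taxon_zero(self):
        d = dmat_from([[0.0]])
        assert rao_q(d, list(d.taxa), np.array([1.0])) == 0.0

    def test_two_taxa_hand_fixture(self):
        d = dmat_from([[0, 1.0], [1.0, 0]])
        assert rao_q(d, list(d.taxa), np.array([0.5, 0.5])) == pytest.approx(0.5, abs=1e-12)

    def test_matches_double_sum_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            s = int(rng.integers(2, 12))
            m = rng.uniform(0, 1, size=(s, s))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            d = dmat_from(m)
            w = rng.dirichlet(np.ones(s))
            expected = sum(
                w[i] * w[j] * m[i, j] for i in range(s) for j in range(s)
            )
            assert rao_q(d, list(d.taxa), w) == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_split_duplication(self):
        rng = np.random.default_rng(23)
        s = 5
        m = rng.uniform(0, 1, size=(s, s))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        w = rng.dirichlet(np.ones(s))
        base = rao_q(dmat_from(m), [f"t{i}" for i in range(s)], w)
        # duplicate taxon 0: distances copied, abundance split
        m2 = np.zeros((s + 1, s + 1))
        m2[:s, :s] = m
        m2[s, :s] = m[0]
        m2[:s, s] = m[0]
        w2 = np.concatenate([w, [w[0] / 2]])
        w2[0] /= 2
        base2 = rao_q(dmat_from(m2), [f"t{i}" for i in range(s + 1)], w2)
        assert base2 == pytest.approx(base, abs=1e-12)


class TestCwmAndDistinctiveness:
    def test_cwm_single_taxon_is_its_row(self, trait_pool):
        taxon = trait_pool.taxa[0]
        cwm = community_weighted_mean(trait_pool, [taxon], np.array([1.0]))
        np.testing.assert_allclose(cwm.to_numpy(), trait_pool.values.loc[taxon].to_numpy())

    def test_cwm_two_taxa_hand_fixture(self):
        import pandas as pd
        from streamfd.core_data import fuzzy_scale

        raw = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["a", "b"], columns=["x", "y"])
        tm = fuzzy_scale(raw, {"g": ["x", "y"]})
        cwm = community_weighted_mean(tm, ["a", "b"], np.array([0.25, 0.75]))
        assert cwm["x"] == pytest.approx(0.75)

    def test_cwm_group_sums_conserved(self, trait_pool):
        rng = np.random.default_rng(9)
        present = list(rng.choice(trait_pool.complete_taxa(), size=12, replace=False))
        w = rng.dirichlet(np.ones(12))
        cwm = community_weighted_mean(trait_pool, present, w)
        for mods in trait_pool.groups.values():
            assert cwm[mods].sum() == pytest.approx(1.0, abs=1e-9)

    def test_distinctiveness_two_taxa_equals_their_distance(self):
        d = dmat_from([[0, 0.37], [0.37, 0]])
        per, mean = functional_distinctiveness(d, list(d.taxa), np.array([2.0, 9.0]))
        assert per.tolist() == pytest.approx([0.37, 0.37])
        assert mean == pytest.approx(0.37)

    def test_distinctiveness_hand_fixture(self):
        # D_A = (0.2*1 + 0.4*3) / 4 = 0.35
        m = np.array([[0, 0.2, 0.4], [0.2, 0, 0.9], [0.4, 0.9, 0]])
        d = dmat_from(m, taxa=["A", "B", "C"])
        per, _ = functional_distinctiveness(d, ["A", "B", "C"], np.array([5.0, 1.0, 3.0]))
        assert per["A"] == pytest.approx(0.35, abs=1e-9)

    def test_identical_taxa_all_zero(self):
        d = dmat_from(np.zeros((4, 4)))
        per, mean = functional_distinctiveness(d, list(d.taxa), np.ones(4))
        assert np.allclose(per, 0) and mean == 0.0


class TestMetricCoupling:
    def test_fdis_and_raoq_strongly_rank_correlated(self, default_cfg, trait_pool, community):
        """FDis and RaoQ measure dispersion on the same geometry and track each
        other closely across the default scenario's yearly communities."""
        from streamfd import gower_distance, pcoa, rank_correlation
        from streamfd.fd_metrics import community_fd, fd_table

        comm = community.align_to(trait_pool.taxa)
        d = gower_distance(trait_pool)
        space = pcoa(d, m=13)
        fd = fd_table(community_fd(comm, space, d))
        rho, _ = rank_correlation(fd["fdis"].to_numpy(), fd["raoq"].to_numpy())
        assert rho > 0.9


class TestRedundancySlope:
    def test_constant_fd_gives_zero_slope(self):
        rich = np.arange(10, 20, dtype=float)
        slope, se, r2, p = redundancy_slope(rich, np.full(10, 0.4))
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_identity_line(self):
        rich = np.arange(10, 20, dtype=float)
        slope, se, r2, p = redundancy_slope(rich, rich)
        assert slope == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(31)
        x = rng.uniform(10, 40, size=10)
        y = 0.3 * x + rng.normal(0, 1, size=10)
        slope, se, r2, p = redundancy_slope(x, y)
        xc = x - x.mean()
        beta = float((xc * y).sum() / (xc**2).sum())
        assert slope == pytest.approx(beta, rel=1e-12)

    def test_zero_richness_variance_rejected(self):
        with pytest.raises(ValueError):
            redundancy_slope(np.full(5, 3.0), np.arange(5.0))
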