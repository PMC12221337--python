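import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

import sedibiome as sb
from sedibiome import CommunityTable


def euclid_dm(points, ids=None):
    ids = ids or [f"p{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(np.asarray(points, dtype=float))), ids=ids)


class TestPCoA:
    def test_recovers_euclidean_configuration(self):
        pts = np.array([[0, 0], [3, 0], [3, 4], [0, 5]], dtype=float)
        res = sb.pcoa(euclid_dm(pts), k=2)
        got = res.coordinates.to_numpy()
        # compare interpoint distances (configuration up to isometry)
        np.testing.assert_allclose(pdist(got), pdist(pts), atol=1e-8)

    def test_all_zero_distances(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = sb.pcoa(dm, k=2)
        assert res.coordinates.shape[1] == 0  # no positive eigenvalues

    def test_eigenvalue_sum_equals_trace(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 3))
        dm = euclid_dm(pts)
        res = sb.pcoa(dm, k=3)
        d = dm.data
        n = d.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d * d) @ j
        assert res.eigenvalues.sum() == pytest.approx(np.trace(b), abs=1e-9)


class TestNMDS:
    def test_collinear_points_fit_in_one_dimension(self):
        pts = np.array([[i, 0] for i in range(8)], dtype=float)
        res = sb.nmds(euclid_dm(pts), k=1, n_starts=8, seed=0)
        assert res.stress < 0.01

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        dm = euclid_dm(rng.normal(size=(9, 4)))
        r1 = sb.nmds(dm, k=2, n_starts=4, seed=7)
        r2 = sb.nmds(dm, k=2, n_starts=4, seed=7)
        assert r1.stress == r2.stress
        pd.testing.assert_frame_equal(r1.coordinates, r2.coordinates)


class TestUPGMA:
    def test_hand_join_heights(self):
        dm = DistanceMatrix(np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0.0]]),
                            ids=["A", "B", "C"])
        newick = sb.upgma_dendrogram(dm)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        # A and B join first at height 0.5; C attaches at height 2
        leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
        assert leaves["A"].edge.length == pytest.approx(0.5)
        assert leaves["C"].edge.length == pytest.approx(2.0)
        assert leaves["A"].parent_node is leaves["B"].parent_node

    def test_identical_samples_join_at_zero(self):
        dm = DistanceMatrix(np.array([[0, 0, 3], [0, 0, 3], [3, 3, 0.0]]),
                            ids=["A", "B", "C"])
        tree = dendropy.Tree.get(data=sb.upgma_dendrogram(dm), schema="newick")
        leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
        assert leaves["A"].edge.length == pytest.approx(0.0)

    def test_output_is_ultrametric(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(7, 3))
        newick = sb.upgma_dendrogram(euclid_dm(pts))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        depths = []
        for leaf in tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length
                node = node.parent_node
            depths.append(d)
        assert max(depths) - min(depths) < 1e-9

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            sb.upgma_dendrogram(DistanceMatrix(np.zeros((1, 1)), ids=["x"]))


class TestANOSIM:
    def test_perfect_separation_gives_r_one(self):
        pts = np.array([[0, 0], [0.1, 0], [0, 0.1], [10, 10], [10.1, 10], [10, 10.1]])
        dm = euclid_dm(pts, ids=[f"s{i}" for i in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=[f"s{i}" for i in range(6)])
        r, p = sb.anosim(dm, groups, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p >= 1 / 100

    def test_single_group_rejected(self):
        dm = euclid_dm(np.random.default_rng(0).normal(size=(4, 2)),
                       ids=list("abcd"))
        groups = pd.Series(["x"] * 4, index=list("abcd"))
        with pytest.raises(ValueError):
            sb.anosim(dm, groups, n_perm=9, seed=0)

    def test_matches_skbio_r_statistic(self):
        import skbio.stats.distance as skd
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(9, 3))
        ids = [f"s{i}" for i in range(9)]
        dm = euclid_dm(pts, ids=ids)
        groups = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=ids)
        r, _ = sb.anosim(dm, groups, n_perm=9, seed=0)
        res = skd.anosim(dm, grouping=list(groups), permutations=9)
        assert r == pytest.approx(res["test statistic"], abs=1e-12)


class TestMantel:
    def test_identity_and_scale_invariance(self):
        rng = np.random.default_rng(4)
        dm = euclid_dm(rng.normal(size=(8, 2)))
        r, _ = sb.mantel(dm, dm, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        scaled = DistanceMatrix(2 * dm.data, ids=list(dm.ids))
        r2, _ = sb.mantel(dm, scaled, method="pearson", n_perm=99, seed=0)
        assert r2 == pytest.approx(1.0)

    def test_constant_triangle_rejected(self):
        n = 5
        d = np.ones((n, n)) - np.eye(n)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])
        rng = np.random.default_rng(5)
        other = euclid_dm(rng.normal(size=(n, 2)), ids=list(dm.ids))
        with pytest.raises(ValueError):
            sb.mantel(dm, other)

    def test_p_respects_add_one_bound(self):
        rng = np.random.default_rng(6)
        d1 = euclid_dm(rng.normal(size=(7, 2)))
        d2 = euclid_dm(rng.normal(size=(7, 2)), ids=list(d1.ids))
        _, p = sb.mantel(d1, d2, n_perm=99, seed=0)
        assert p >= 1 / 100


class TestGeoDistances:
    def test_identical_points_and_degree_of_longitude(self):
        coords = pd.DataFrame({"latitude": [0.0, 0.0, 0.0],
                               "longitude": [0.0, 0.0, 1.0]},
                              index=["a", "b", "c"])
        d = sb.geo_distances(coords).data
        assert d[0, 1] == pytest.approx(0.0)
        assert d[0, 2] == pytest.approx(111.19, abs=0.01)

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(7)
        coords = pd.DataFrame({"latitude": rng.uniform(-60, 60, 20),
                               "longitude": rng.uniform(-170, 170, 20)},
                              index=[f"s{i}" for i in range(20)])
        d = sb.geo_distances(coords).data
        np.testing.assert_allclose(d, d.T, atol=1e-9)
        for _ in range(100):
            i, j, k = rng.choice(20, 3, replace=False)
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_out_of_range_rejected(self):
        coords = pd.DataFrame({"latitude": [95.0], "longitude": [0.0]}, index=["a"])
        with pytest.raises(ValueError):
            sb.geo_distances(coords)


class TestPCNM:
    def _collinear(self, n, spacing_km):
        dlat = spacing_km / 6371.0 * 180 / np.pi
        return pd.DataFrame({"latitude": [30 + i * dlat for i in range(n)],
                             "longitude": [120.0] * n},
                            index=[f"s{i}" for i in range(n)])

    def test_truncation_is_mst_longest_edge(self):
        basis = sb.pcnm(sb.geo_distances(self._collinear(6, 50.0)))
        assert basis.truncation_km == pytest.approx(50.0, abs=0.5)

    def test_vectors_orthogonal_and_centred(self):
        basis = sb.pcnm(sb.geo_distances(self._collinear(10, 30.0)))
        v = basis.vectors.to_numpy()
        np.testing.assert_allclose(v.mean(axis=0), 0.0, atol=1e-9)
        gram = v.T @ v
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)

    def test_moran_eigenvector_sign_structure(self):
        # along a transect the leading eigenvector behaves like a half-wave:
        # it has one fewer sign change than the second
        basis = sb.pcnm(sb.geo_distances(self._collinear(10, 30.0)))
        def sign_changes(v):
            s = np.sign(v[np.abs(v) > 1e-10])
            return int((s[1:] != s[:-1]).sum())
        assert sign_changes(basis.vectors.iloc[:, 0].to_numpy()) \
            == sign_changes(basis.vectors.iloc[:, 1].to_numpy()) - 1

    def test_coincident_sites_rejected(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        with pytest.raises(ValueError):
            sb.pcnm(dm)


class TestConstrainedOrdination:
    # fixture shared with the R vegan oracle that produced the frozen values
    Y = np.array([[10, 3, 0, 2, 5], [8, 4, 1, 3, 6], [2, 9, 4, 6, 1],
                  [1, 10, 6, 5, 0], [0, 2, 12, 9, 3], [1, 1, 10, 11, 4]])
    X = pd.DataFrame({"a": [1, 2, 3, 4, 5, 6.0], "b": [2, 1, 4, 3, 6, 5.0]},
                     index=[f"s{i}" for i in range(6)])

    def _table(self):
        return CommunityTable(pd.DataFrame(
            self.Y, index=[f"s{i}" for i in range(6)],
            columns=[f"o{j}" for j in range(5)]))

    def test_rda_matches_vegan(self):
        res = sb.constrained_ordination(self._table(), self.X, mode="rda",
                                        n_perm=9, seed=0)
        np.testing.assert_allclose(res.eigenvalues, [0.1464943, 0.00141877],
                                   rtol=1e-5)
        assert res.total_inertia == pytest.approx(0.2288986, rel=1e-5)

    def test_cca_matches_vegan(self):
        res = sb.constrained_ordination(self._table(), self.X, mode="cca",
                                        n_perm=9, seed=0)
        np.testing.assert_allclose(res.eigenvalues, [0.3552685, 0.001204959],
                                   rtol=1e-5)
        assert res.total_inertia == pytest.approx(0.5641408, rel=1e-5)

    def test_noiseless_recovery_of_single_gradient(self):
        # counts engineered so sqrt(relative abundance) is linear in x
        x = np.linspace(0, 1, 8)
        h1 = 0.3 + 0.4 * x
        h2 = np.sqrt(1 - h1 ** 2)
        rel = np.column_stack([h1 ** 2, h2 ** 2])
        counts = np.round(rel * 1e6).astype(int)
        table = CommunityTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(8)], columns=["u", "v"]))
        pred = pd.DataFrame({"x": x}, index=table.sample_ids)
        res = sb.constrained_ordination(table, pred, mode="rda", n_perm=9, seed=0)
        assert res.proportion_explained[0] > 0.99

    def test_relabelling_invariance(self):
        res = sb.constrained_ordination(self._table(), self.X, mode="rda",
                                        n_perm=9, seed=0)
        perm = [3, 1, 4, 0, 5, 2]
        t2 = CommunityTable(self._table().counts.iloc[perm])
        x2 = self.X.iloc[perm]
        res2 = sb.constrained_ordination(t2, x2, mode="rda", n_perm=9, seed=0)
        np.testing.assert_allclose(res.eigenvalues, res2.eigenvalues, atol=1e-10)

    def test_too_many_predictors_rejected(self):
        x = pd.DataFrame(np.random.default_rng(0).normal(size=(6, 6)),
                         index=[f"s{i}" for i in range(6)])
        with pytest.raises(ValueError, match="predictor"):
            sb.constrained_ordination(self._table(), x, mode="rda", n_perm=9, seed=0)


class TestVariationPartitioning:
    def _table(self, rng, n=12, m=6):
        counts = rng.poisson(20, size=(n, m)) + 1
        return CommunityTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(n)],
            columns=[f"o{j}" for j in range(m)]))

    def test_decomposition_identity(self):
        rng = np.random.default_rng(8)
        t = self._table(rng)
        env = pd.DataFrame({"e1": rng.normal(size=12), "e2": rng.normal(size=12)},
                           index=t.sample_ids)
        space = pd.DataFrame({"v1": rng.normal(size=12)}, index=t.sample_ids)
        vpa = sb.variation_partitioning(t, env, space)
        total = vpa.pure_env + vpa.shared + vpa.pure_space + vpa.unexplained
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_space_contributes_nothing(self):
        rng = np.random.default_rng(9)
        n = 40
        x = np.linspace(-1, 1, n)
        h1 = 0.5 + 0.3 * x
        h2 = np.sqrt(1 - h1 ** 2)
        counts = np.round(np.column_stack([h1 ** 2, h2 ** 2]) * 1e6).astype(int)
        t = CommunityTable(pd.DataFrame(counts, index=[f"s{i}" for i in range(n)],
                                        columns=["u", "v"]))
        env = pd.DataFrame({"x": x}, index=t.sample_ids)
        z = rng.normal(size=n)
        z = z - z.mean()
        z = z - x @ z / (x @ x) * x          # orthogonalise against the gradient
        space = pd.DataFrame({"z": z}, index=t.sample_ids)
        vpa = sb.variation_partitioning(t, env, space)
        assert abs(vpa.pure_space) < 0.05
        assert abs(vpa.shared) < 0.05
        assert vpa.pure_env > 0.9

    def test_unit_rescaling_of_predictors_is_neutral(self):
        rng = np.random.default_rng(10)
        t = self._table(rng)
        env = pd.DataFrame({"e": rng.normal(size=12)}, index=t.sample_ids)
        space = pd.DataFrame({"v": rng.normal(size=12)}, index=t.sample_ids)
        v1 = sb.variation_partitioning(t, env, space)
        v2 = sb.variation_partitioning(t, env * 1000.0, space / 7.0)
        assert v1.pure_env == pytest.approx(v2.pure_env, abs=1e-10)
        assert v1.shared == pytest.approx(v2.shared, abs=1e-10)

    def test_empty_block_rejected(self):
        rng = np.random.default_rng(11)
        t = self._table(rng)
        env = pd.DataFrame(index=t.sample_ids)
        space = pd.DataFrame({"v": rng.normal(size=12)}, index=t.sample_ids)
        with pytest.raises(ValueError):
            sb.variation_partitioning(t, env, space)
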