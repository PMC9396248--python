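import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from ileumatlas import embed_cluster as ec


def _sig_pcs_oracle(pct):
    """Exhaustive two-criteria scan, independent of the implementation."""
    n = len(pct)
    a = None
    for i in range(n - 1):
        if pct[i] - pct[i + 1] > 0.1:
            a = i + 1
    b = None
    cum = 0.0
    for j in range(n):
        cum += pct[j]
        if cum >= 90.0 and pct[j] < 5.0 and b is None:
            b = j + 1
    hits = [c for c in (a, b) if c is not None]
    return min(hits) if hits else n


class TestLognormalize:
    def test_values_and_zeros(self, small_atlas):
        _, adata, _ = small_atlas
        import anndata as ad
        import scipy.sparse as sp

        toy = ad.AnnData(X=sp.csr_matrix(np.array([[100, 9900], [1, 0]])))
        norm = ec.lognormalize(toy, scale_factor=1e4)
        x = np.asarray(norm.X.todense())
        assert x[0, 0] == pytest.approx(np.log(101.0))
        assert x[1, 1] == 0.0

    def test_scale_factor_monotonicity(self):
        import anndata as ad
        import scipy.sparse as sp

        toy = ad.AnnData(X=sp.csr_matrix(np.array([[3, 7], [2, 8]])))
        lo = np.asarray(ec.lognormalize(toy, 1e4).X.todense())
        hi = np.asarray(ec.lognormalize(toy, 2e4).X.todense())
        nz = lo > 0
        assert np.all(hi[nz] > lo[nz])

    def test_zero_libsize_rejected(self):
        import anndata as ad
        import scipy.sparse as sp

        toy = ad.AnnData(X=sp.csr_matrix(np.array([[0, 0], [1, 1]])))
        with pytest.raises(ValueError, match="zero-libsize"):
            ec.lognormalize(toy)


class TestSignificantPCs:
    def test_single_informative_pc(self):
        v = np.zeros(30)
        v[0] = 100.0
        assert ec.significant_pcs(v) == 1

    def test_cumulative_criterion_fires_first(self):
        # flat 4.6s reach 90% cumulative at PC 20 (criterion B), while the
        # only >0.1 change sits later at PC 21 (criterion A)
        v = np.array([4.6] * 20 + [2.0] + [0.0] * 4)
        assert _sig_pcs_oracle(v) == 20
        assert ec.significant_pcs(v) == 20

    def test_flat_spectrum(self):
        assert ec.significant_pcs(np.full(100, 1.0)) == 90

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            ec.significant_pcs(np.array([]))

    def test_matches_exhaustive_scan_on_random_spectra(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(2, 120)
            raw = rng.exponential(1.0, n)
            pct = 100.0 * np.sort(raw)[::-1] / raw.sum()
            if rng.random() < 0.3:  # sometimes unsorted / unnormalized
                pct = rng.permutation(pct) * rng.uniform(0.5, 1.5)
            got = ec.significant_pcs(pct)
            assert got == _sig_pcs_oracle(pct)
            assert got <= len(pct)


class TestSNNGraph:
    def test_symmetry_and_identical_neighbor_sets(self):
        rng = np.random.default_rng(1)
        # two tight twin points inside a blob share their k-NN set
        blob = rng.normal(0, 1, (50, 3))
        twins = np.array([[10.0, 10, 10], [10.000001, 10, 10]])
        far = rng.normal(20, 0.5, (10, 3))
        coords = np.vstack([blob, twins, far])
        emb = ec.Embedding(coords, np.ones(3), 3)
        g = ec.build_snn(emb, k=5)
        eid = g.get_eid(50, 51, error=False)
        assert eid >= 0
        assert g.es[eid]["weight"] == pytest.approx(1.0)
        assert not g.is_directed()

    def test_separated_blobs_have_no_cross_edges(self):
        rng = np.random.default_rng(2)
        coords = np.vstack([rng.normal(0, 0.1, (30, 2)), rng.normal(100, 0.1, (30, 2))])
        g = ec.build_snn(ec.Embedding(coords, np.ones(2), 2), k=5)
        for e in g.es:
            assert (e.source < 30) == (e.target < 30)

    def test_k_at_least_n_rejected(self):
        emb = ec.Embedding(np.zeros((5, 2)), np.ones(2), 2)
        with pytest.raises(ValueError, match="k="):
            ec.build_snn(emb, k=5)


class TestClusterGraph:
    def test_two_cliques_yield_two_components(self):
        import igraph

        g = igraph.Graph.Full(10) + igraph.Graph.Full(12)
        labels = ec.cluster_graph(g, resolution=1.0, seed=0)
        assert labels.nunique() == 2
        assert labels[:10].nunique() == 1 and labels[10:].nunique() == 1
        # labels ordered by decreasing size: the 12-clique gets label 0
        assert (labels == 0).sum() == 12

    def test_recovers_planted_types(self, clean_five_type):
        _, adata, truth = clean_five_type
        _, emb, _ = ec.recluster(adata, resolution=1.0, seed=0)
        g = ec.build_snn(emb, k=30)
        labels = ec.cluster_graph(g, resolution=1.0, seed=0)
        assert adjusted_rand_score(truth["true_type"], labels) > 0.8

    def test_same_seed_identical_labels(self, clean_five_type):
        _, adata, _ = clean_five_type
        _, emb, _ = ec.recluster(adata, resolution=1.0, seed=0)
        g = ec.build_snn(emb, k=30)
        l1 = ec.cluster_graph(g, resolution=2.0, seed=3)
        l2 = ec.cluster_graph(g, resolution=2.0, seed=3)
        assert l1.equals(l2)

    def test_duplicated_cells_partition_unchanged(self, clean_five_type):
        import anndata as ad

        _, adata, truth = clean_five_type
        norm, emb, _ = ec.recluster(adata, resolution=1.0, seed=0)
        labels = ec.cluster_graph(ec.build_snn(emb, k=30), resolution=1.0, seed=0)
        doubled = ad.concat([adata, adata], merge="same", index_unique="-")
        norm2, emb2, _ = ec.recluster(doubled, resolution=1.0, seed=0)
        # duplication doubles local density, so the matched neighborhood
        # size doubles as well
        labels2 = ec.cluster_graph(ec.build_snn(emb2, k=60), resolution=1.0, seed=0)
        n = adata.n_obs
        assert adjusted_rand_score(labels, labels2[:n]) > 0.95
        assert (labels2[:n].to_numpy() == labels2[n:].to_numpy()).mean() > 0.95


class TestClusterTree:
    def _embedding(self, centroids, spread, n_per, seed=0):
        rng = np.random.default_rng(seed)
        coords = np.vstack([rng.normal(c, spread, (n_per, len(c))) for c in centroids])
        labels = pd.Series(np.repeat(np.arange(len(centroids)), n_per))
        return ec.Embedding(coords, np.ones(coords.shape[1]), coords.shape[1]), labels

    def test_nearest_pair_merges_first(self):
        emb, labels = self._embedding([[0, 0], [1, 0], [10, 0]], 0.01, 20)
        z, _ = ec.cluster_tree(emb, labels)
        assert set(z[0, :2].astype(int)) == {0, 1}

    def test_binary_tree_has_c_minus_1_merges(self):
        emb, labels = self._embedding([[0, 0], [3, 0], [6, 0], [9, 9]], 0.01, 10)
        z, leaves = ec.cluster_tree(emb, labels)
        assert z.shape[0] == 3
        assert sorted(leaves) == [0, 1, 2, 3]

    def test_topology_invariant_to_cluster_relabeling(self):
        emb, labels = self._embedding([[0, 0], [2, 0], [8, 0], [9, 9]], 0.01, 10)
        z1, _ = ec.cluster_tree(emb, labels)
        # relabel clusters 0..3 -> 3..0 (same geometry, different ids)
        z2, _ = ec.cluster_tree(emb, labels.map({0: 3, 1: 2, 2: 1, 3: 0}))
        c1 = squareform(cophenet(z1))
        c2 = squareform(cophenet(z2))
        perm = [3, 2, 1, 0]
        assert np.allclose(c1, c2[np.ix_(perm, perm)])

    def test_single_cluster_rejected(self):
        emb, _ = self._embedding([[0, 0]], 0.01, 10)
        with pytest.raises(ValueError, match="2 clusters"):
            ec.cluster_tree(emb, pd.Series(np.zeros(10, dtype=int)))


class TestPseudobulkMDS:
    def test_identical_profiles_land_together_and_3_sample_exactness(self):
        import anndata as ad
        import scipy.sparse as sp

        rng = np.random.default_rng(3)
        base = rng.integers(1, 20, (30, 50))
        x = np.vstack([base, base, rng.integers(1, 40, (30, 50))])
        samples = ["s1"] * 30 + ["s2"] * 30 + ["s3"] * 30
        adata = ad.AnnData(X=sp.csr_matrix(x))
        adata.obs["sample_id"] = samples
        norm = ec.lognormalize(adata)
        coords = ec.pseudobulk_mds(norm, n_top_genes=50)
        d = squareform(pdist(coords.to_numpy()))
        assert d[0, 1] == pytest.approx(0.0, abs=1e-8)
        # classical MDS reproduces all pairwise distances exactly for n=3
        profiles = np.vstack(
            [
                np.asarray(norm.X[np.array(samples) == s].mean(axis=0)).ravel()
                for s in ("s1", "s2", "s3")
            ]
        )
        var = profiles.var(axis=0)
        top = np.argsort(var)[::-1][:50]
        d_in = squareform(pdist(profiles[:, top]))
        assert np.allclose(d, d_in, atol=1e-8)

    def test_composition_groups_separate(self, small_atlas):
        _, adata, _ = small_atlas
        from ileumatlas import qc

        m = qc.compute_qc_metrics(adata)
        kept, _ = qc.filter_cells(m)
        norm = ec.lognormalize(adata[kept].copy())
        coords = ec.pseudobulk_mds(norm).to_numpy()
        samples = sorted(pd.unique(norm.obs["sample_id"]))
        nonpp = [i for i, s in enumerate(samples) if s.endswith("nonPP")]
        rich = [i for i in range(len(samples)) if i not in nonpp]
        d = squareform(pdist(coords))
        within = np.mean([d[i, j] for i in rich for j in rich if i < j])
        between = np.mean([d[i, j] for i in rich for j in nonpp])
        assert between > within

    def test_fewer_than_three_samples_rejected(self):
        import anndata as ad
        import scipy.sparse as sp

        adata = ad.AnnData(X=sp.csr_matrix(np.ones((4, 5))))
        adata.obs["sample_id"] = ["a", "a", "b", "b"]
        with pytest.raises(ValueError, match="3 samples"):
            ec.pseudobulk_mds(ec.lognormalize(adata))
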