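import itertools

import numpy as np
import pandas as pd
import pytest

from ileumatlas import synthetic_data as sd
from ileumatlas import topics_modules as tm
from ileumatlas.embed_cluster import Embedding


def _three_topic_data(n_per=200, seed=11):
    cfg = sd.ileum_default_config(n_cells_per_sample=3 * n_per, seed=seed)
    comp = {"B": 1 / 3, "CD4_T": 1 / 3, "ILC": 1 / 3}
    cfg.samples = [sd.SampleSpec("s1", "a1", "ileum", comp)]
    cfg.doublet_rate = 0.0
    cfg.lowq_rate = 0.0
    cfg.type_profiles = {t: {t: 0.85, "housekeeping": 0.15} for t in comp}
    cfg.dirichlet_concentration = 30.0
    adata, truth = sd.generate_atlas(cfg)
    var, midx = sd._build_gene_universe(cfg)
    f_prog = sd._program_matrix(cfg, var, midx)
    progs = list(cfg.programs)
    true_f = np.vstack(
        [
            np.array([cfg.type_profiles[t].get(p, 0.0) for p in progs]) @ f_prog
            for t in comp
        ]
    )
    return adata, truth, true_f


def best_permutation_cosine(true_f, fitted_f):
    k = true_f.shape[0]
    best = -1.0
    for perm in itertools.permutations(range(k)):
        cos = min(
            float(
                np.dot(true_f[i], fitted_f[perm[i]])
                / (np.linalg.norm(true_f[i]) * np.linalg.norm(fitted_f[perm[i]]))
            )
            for i in range(k)
        )
        best = max(best, cos)
    return best


class TestFitTopics:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(2.0, (30, 10))
        fit = tm.fit_topics(x, K=1)
        assert np.all(fit.L == 1.0)
        pooled = x.sum(axis=0) / x.sum()
        assert np.allclose(fit.F[0], pooled)

    def test_recovery_and_monotonicity(self):
        adata, _, true_f = _three_topic_data()
        fit = tm.fit_topics(adata, K=3, seed=0, max_iter=100)
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))
        assert np.allclose(fit.L.sum(axis=1), 1.0, atol=1e-8)
        assert np.allclose(fit.F.sum(axis=1), 1.0, atol=1e-8)
        assert best_permutation_cosine(true_f, fit.F) > 0.9

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            tm.fit_topics(np.ones((5, 4)), K=6)

    def test_same_seed_same_fit(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(1.5, (40, 20))
        f1 = tm.fit_topics(x, K=2, seed=9, n_restarts=1, max_iter=20)
        f2 = tm.fit_topics(x, K=2, seed=9, n_restarts=1, max_iter=20)
        assert np.array_equal(f1.L, f2.L) and np.array_equal(f1.F, f2.F)


class TestTopicEnrichment:
    def _fit(self, F, usage=None):
        K, G = F.shape
        L = np.full((4, K), 1.0 / K) if usage is None else usage
        return tm.TopicFit(L=L, F=F, loglik_trace=[0.0], K=K, seed=0)

    def test_exclusive_gene_capped(self):
        F = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5]])
        tab = tm.topic_enrichment(self._fit(F))
        lfc = tab[(tab["topic"] == 0) & (tab["gene"] == "g0")]["lfc"].iloc[0]
        assert lfc == pytest.approx(np.log(1e6))

    def test_uniform_gene_has_zero_lfc(self):
        F = np.array([[0.4, 0.6], [0.4, 0.6]])
        tab = tm.topic_enrichment(self._fit(F))
        assert np.allclose(tab["lfc"], 0.0)

    def test_planted_marker_top_ranked(self):
        adata, _, true_f = _three_topic_data(n_per=100, seed=3)
        fit = tm.fit_topics(adata, K=3, seed=0, max_iter=60)
        tab = tm.topic_enrichment(fit)
        b_markers = {
            g for g in adata.var_names if adata.var.loc[g, "program"] == "B"
        }
        # the fitted topic matching B must rank B markers at its top
        for t in range(3):
            top = tab[tab["topic"] == t].head(30)["gene"]
            if len(set(top) & b_markers) > 15:
                break
        else:
            pytest.fail("no fitted topic enriched for the planted B block")


class TestDetectionMatrix:
    def test_values_above_median(self):
        import anndata as ad
        import scipy.sparse as sp

        x = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        det, med = tm.detection_matrix(ad.AnnData(X=sp.csr_matrix(x)))
        assert med[0] == 3.0
        assert det[:, 0].tolist() == [False, False, False, True, True]

    def test_majority_zero_gene_reduces_to_nonzero_detection(self):
        import anndata as ad
        import scipy.sparse as sp

        x = np.array([[0.0], [0.0], [0.0], [2.0], [3.0]])
        det, med = tm.detection_matrix(ad.AnnData(X=sp.csr_matrix(x)))
        assert med[0] == 0.0
        assert det[:, 0].tolist() == [False, False, False, True, True]

    def test_constant_gene_detected_nowhere(self):
        import anndata as ad
        import scipy.sparse as sp

        x = np.full((4, 1), 2.5)
        det, _ = tm.detection_matrix(ad.AnnData(X=sp.csr_matrix(x)))
        assert not det.any()


@pytest.fixture(scope="module")
def blob_embedding():
    rng = np.random.default_rng(0)
    n = 800
    coords = np.vstack([rng.normal(0, 1, (n // 2, 5)), rng.normal(6, 1, (n // 2, 5))])
    return Embedding(coords, np.ones(5), 5), n


class TestHaystack:
    def test_localized_gene_hits_permutation_floor(self, blob_embedding):
        emb, n = blob_embedding
        rng = np.random.default_rng(1)
        det = rng.random((n, 20)) < 0.3
        det[:, 0] = False
        det[: n // 2, 0] = rng.random(n // 2) < 0.5
        res = tm.haystack_dge(det, emb, n_grid=40, n_perm=100, seed=2)
        assert res.table["p_value"].iloc[0] == pytest.approx(1.0 / 101.0)

    def test_uniform_detection_not_significant(self, blob_embedding):
        emb, n = blob_embedding
        rng = np.random.default_rng(2)
        det = rng.random((n, 40)) < 0.3
        res = tm.haystack_dge(det, emb, n_grid=40, n_perm=100, seed=3)
        assert (res.table["p_value"] < 0.05).mean() <= 0.10

    def test_degenerate_genes_flagged(self, blob_embedding):
        emb, n = blob_embedding
        det = np.zeros((n, 2), dtype=bool)
        det[:, 1] = True
        res = tm.haystack_dge(det, emb, n_grid=10, n_perm=10, seed=0)
        assert res.table["flagged"].all()
        assert (res.table["p_value"] == 1.0).all()
        assert (res.table["kl_stat"] == 0.0).all()

    def test_kl_equals_brute_force_oracle(self):
        """20-cell, 3-grid instance against an independent double loop."""
        from sklearn.cluster import KMeans
        from sklearn.metrics import pairwise_distances

        rng = np.random.default_rng(7)
        coords = rng.normal(0, 1, (20, 3))
        emb = Embedding(coords, np.ones(3), 3)
        det = rng.random((20, 4)) < 0.5
        res = tm.haystack_dge(det, emb, n_grid=3, n_perm=10, seed=5)
        km = KMeans(3, random_state=5, n_init=2).fit(coords)
        d = pairwise_distances(coords, km.cluster_centers_)
        sigma = max(float(np.median(d.min(axis=1))), 1e-12)
        w = np.exp(-(d**2) / (2 * sigma**2))
        q = w.sum(axis=0)
        q = q / q.sum()
        eps = 1e-9
        for g in range(4):
            p = np.zeros(3)
            for c in range(20):
                if det[c, g]:
                    for k in range(3):
                        p[k] += w[c, k]
            pn = (p + eps) / (p + eps).sum()
            qn = (q + eps) / (q + eps).sum()
            kl = sum(pn[k] * np.log(pn[k] / qn[k]) for k in range(3))
            assert res.table["kl_stat"].iloc[g] == pytest.approx(kl, abs=1e-12)


class TestModules:
    def _anticorrelated_result(self):
        rng = np.random.default_rng(3)
        n = 400
        coords = np.vstack([rng.normal(0, 1, (n // 2, 4)), rng.normal(6, 1, (n // 2, 4))])
        emb = Embedding(coords, np.ones(4), 4)
        det = np.zeros((n, 12), dtype=bool)
        for j in range(6):  # block A: blob 1
            det[: n // 2, j] = rng.random(n // 2) < 0.6
        for j in range(6, 12):  # block B: blob 2
            det[n // 2 :, j] = rng.random(n // 2) < 0.6
        res = tm.haystack_dge(det, emb, n_grid=30, n_perm=50, seed=1)
        return res, det

    def test_anticorrelated_blocks_recovered(self):
        res, det = self._anticorrelated_result()
        modules = tm.build_modules(res, det, k=2, top_n=12)
        groups = [set(modules.index[modules == m]) for m in (1, 2)]
        expected = [{f"g{j}" for j in range(6)}, {f"g{j}" for j in range(6, 12)}]
        assert groups == expected or groups == expected[::-1]

    def test_duplicate_profiles_share_a_module(self):
        res, det = self._anticorrelated_result()
        res.P[1] = res.P[0]  # force identical grid profiles
        modules = tm.build_modules(res, det, k=2, top_n=12)
        assert modules.iloc[0] == modules.iloc[1]

    def test_k_equal_to_gene_count_gives_singletons(self):
        res, det = self._anticorrelated_result()
        modules = tm.build_modules(res, det, k=12, top_n=12)
        assert modules.nunique() == 12

    def test_k_above_selected_genes_rejected(self):
        res, det = self._anticorrelated_result()
        with pytest.raises(ValueError, match="exceeds"):
            tm.build_modules(res, det, k=13, top_n=12)


class TestModuleScores:
    def test_fraction_detected(self):
        det = np.array([[True, True, True, True], [False] * 4, [True, False, False, False]])
        modules = pd.Series([1, 1, 1, 1], index=[f"g{j}" for j in range(4)])
        scores = tm.module_scores(det, modules, [f"g{j}" for j in range(4)])
        assert scores[1].tolist() == [1.0, 0.0, 0.25]

    def test_smoothing_averages_over_neighbors(self):
        det = np.array([[True], [True], [False], [False]])
        modules = pd.Series([1], index=["g0"])
        coords = np.array([[0.0], [0.1], [10.0], [10.1]])
        emb = Embedding(coords, np.ones(1), 1)
        scores = tm.module_scores(det, modules, ["g0"], smooth_k=2, embedding=emb)
        assert scores[1].tolist() == [1.0, 1.0, 0.0, 0.0]
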