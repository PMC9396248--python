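"""Grade-of-membership topic model and embedding-aware differential
detection with gene modules and per-cell module detection scores.

The topic model is the multinomial grade-of-membership model: cell c's
counts are multinomial with gene probabilities sum_t L[c,t]·F[t,g], L rows
and F rows on the simplex, maximized by EM.  The differential-detection
statistic measures, for each gene, the KL divergence between the
grid-kernel-weighted distribution of the cells detecting it and the
distribution of all cells over the same grid, with significance from a
stratified permutation null.  "Detection" means log-normalized expression
strictly above the gene's dataset-wide median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import average, fcluster, leaves_list
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .embed_cluster import Embedding

__all__ = [
    "TopicFit",
    "HaystackResult",
    "fit_topics",
    "topic_enrichment",
    "detection_matrix",
    "haystack_dge",
    "build_modules",
    "module_scores",
]


@dataclass
class TopicFit:
    L: np.ndarray  # cells x K, rows on the simplex
    F: np.ndarray  # K x genes, rows on the simplex
    loglik_trace: list[float]
    K: int
    seed: int
    gene_names: list[str] = field(default_factory=list)


def _em_once(
    r: np.ndarray,
    c: np.ndarray,
    x: np.ndarray,
    n_cells: int,
    n_genes: int,
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> TopicFit:
    L = rng.dirichlet(np.ones(K), size=n_cells)
    F = rng.dirichlet(np.ones(n_genes), size=K)
    lib = np.bincount(r, weights=x, minlength=n_cells)
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        # E-step at nonzero entries: responsibilities ∝ L[c,t]·F[t,g]
        phi = L[r] * F[:, c].T  # nnz x K
        denom = phi.sum(axis=1)
        loglik = float(np.sum(x * np.log(denom + 1e-300)))
        trace.append(loglik)
        phi /= (denom + 1e-300)[:, None]
        w = phi * x[:, None]
        # M-step: renormalized expected counts
        for t in range(K):
            L[:, t] = np.bincount(r, weights=w[:, t], minlength=n_cells)
            F[t] = np.bincount(c, weights=w[:, t], minlength=n_genes)
        L /= np.maximum(lib, 1e-300)[:, None]
        L /= L.sum(axis=1, keepdims=True)
        F /= F.sum(axis=1, keepdims=True)
        if prev > -np.inf and abs(loglik - prev) <= tol * abs(prev):
            break
        prev = loglik
    return TopicFit(L=L, F=F, loglik_trace=trace, K=K, seed=0)


def fit_topics(
    counts: ad.AnnData | sp.spmatrix | np.ndarray,
    K: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    n_restarts: int = 3,
) -> TopicFit:
    """Fit the grade-of-membership model by EM, keeping the best of
    ``n_restarts`` Dirichlet(1)-initialized runs.

    K=1 is allowed as a closed-form edge case (all weight on one topic,
    gene distribution = pooled frequencies).
    """
    gene_names: list[str] = []
    if isinstance(counts, ad.AnnData):
        gene_names = list(counts.var_names)
        counts = counts.X
    xmat = sp.coo_matrix(counts)
    if xmat.data.size and xmat.data.min() < 0:
        raise ValueError("counts must be non-negative")
    n_cells, n_genes = xmat.shape
    if not 1 <= K <= min(n_cells, n_genes):
        raise ValueError(f"K={K} out of range for {n_cells} cells x {n_genes} genes")
    r, c, x = xmat.row, xmat.col, xmat.data.astype(float)
    if K == 1:
        pooled = np.bincount(c, weights=x, minlength=n_genes)
        F = (pooled / pooled.sum())[None, :]
        loglik = float(np.sum(x * np.log(F[0, c] + 1e-300)))
        return TopicFit(
            L=np.ones((n_cells, 1)), F=F, loglik_trace=[loglik], K=1, seed=seed,
            gene_names=gene_names,
        )
    best: TopicFit | None = None
    for i in range(n_restarts):
        rng = np.random.default_rng((seed + 1000003 * i) % (2**31))
        fit = _em_once(r, c, x, n_cells, n_genes, K, rng, max_iter, tol)
        if best is None or fit.loglik_trace[-1] > best.loglik_trace[-1]:
            best = fit
    assert best is not None
    best.seed = seed
    best.gene_names = gene_names
    return best


def topic_enrichment(fit: TopicFit, lfc_cap: float = float(np.log(1e6))) -> pd.DataFrame:
    """Per-gene per-topic log-fold enrichment against the usage-weighted
    mean of the other topics, capped at ``lfc_cap``."""
    usage = fit.L.sum(axis=0)
    rows = []
    genes = fit.gene_names or [f"g{j}" for j in range(fit.F.shape[1])]
    for t in range(fit.K):
        others = [s for s in range(fit.K) if s != t]
        w = usage[others]
        if w.sum() == 0:
            w = np.ones(len(others))
        baseline = np.average(fit.F[others], axis=0, weights=w)
        with np.errstate(divide="ignore"):
            lfc = np.log(fit.F[t] + 0.0) - np.log(baseline + 0.0)
        lfc = np.where(np.isnan(lfc), 0.0, lfc)
        lfc = np.clip(lfc, -lfc_cap, lfc_cap)
        for j in np.argsort(lfc)[::-1]:
            rows.append({"topic": t, "gene": genes[j], "lfc": lfc[j], "F": fit.F[t, j]})
    return pd.DataFrame(rows)


def detection_matrix(norm: ad.AnnData) -> tuple[np.ndarray, np.ndarray]:
    """Binary detection per cell: expression strictly above the gene's
    dataset-wide median.  Genes with median 0 reduce to nonzero detection.
    Returns (cells x genes bool matrix, per-gene thresholds)."""
    x = norm.X.tocsc() if sp.issparse(norm.X) else sp.csc_matrix(norm.X)
    dense = np.asarray(x.todense())
    med = np.median(dense, axis=0)
    return dense > med[None, :], med


@dataclass
class HaystackResult:
    table: pd.DataFrame  # per-gene kl_stat, p_value, p_adj, flagged
    P: np.ndarray  # genes x grid detection profiles
    Q: np.ndarray  # grid reference distribution
    grid_centers: np.ndarray
    bandwidth: float


def _kl(p_counts: np.ndarray, q: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Row-wise KL(P||Q) with additive smoothing then renormalization."""
    p = p_counts + eps
    p = p / p.sum(axis=-1, keepdims=True)
    qq = q + eps
    qq = qq / qq.sum()
    return np.sum(p * np.log(p / qq), axis=-1)


def haystack_dge(
    detection: np.ndarray,
    embedding: Embedding,
    n_grid: int = 100,
    n_perm: int = 200,
    seed: int = 0,
    gene_names: list[str] | None = None,
) -> HaystackResult:
    """KL statistic for embedding-localized detection, per gene.

    Grid points are k-means centroids in significant-PC space; each cell
    contributes Gaussian kernel weight exp(−d²/2σ²) to every grid point
    with σ the median cell-to-nearest-centroid distance.  The null
    permutes the detection indicator across cells within deciles of
    per-cell total detection count.  Genes detected in no or all cells are
    flagged with stat 0 and p 1.
    """
    det = np.asarray(detection, dtype=bool)
    n_cells, n_genes = det.shape
    if n_grid >= n_cells:
        raise ValueError("n_grid must be smaller than the number of cells")
    coords = embedding.sig_coords
    km = KMeans(n_clusters=n_grid, random_state=int(seed) % (2**31), n_init=2).fit(coords)
    centers = km.cluster_centers_
    d = pairwise_distances(coords, centers)
    sigma = float(np.median(d.min(axis=1)))
    sigma = max(sigma, 1e-12)
    w = np.exp(-(d**2) / (2.0 * sigma**2))  # cells x grid
    q = w.sum(axis=0)
    q = q / q.sum()

    detf = det.astype(np.float64)
    counts = detf.sum(axis=0)
    degenerate = (counts == 0) | (counts == n_cells)
    s_obs = w.T @ detf  # grid x genes
    kl_obs = _kl(s_obs.T, q)
    kl_obs[degenerate] = 0.0
    p_grid = s_obs.T / np.maximum(s_obs.sum(axis=0)[:, None], 1e-300)

    # stratified permutation null: cells binned by total detection count
    per_cell = detf.sum(axis=1)
    order = np.argsort(per_cell, kind="stable")
    n_strata = min(10, n_cells)
    strata = [order[np.array_split(np.arange(n_cells), n_strata)[i]] for i in range(n_strata)]
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_genes)
    wt = w.T.copy()
    for _ in range(n_perm):
        perm = np.arange(n_cells)
        for s in strata:
            perm[s] = rng.permutation(s)
        s_null = wt @ detf[perm]
        kl_null = _kl(s_null.T, q)
        exceed += kl_null >= kl_obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    p[degenerate] = 1.0
    p_adj = multipletests(p, method="fdr_bh")[1]
    genes = gene_names if gene_names is not None else [f"g{j}" for j in range(n_genes)]
    table = pd.DataFrame(
        {
            "gene": genes,
            "kl_stat": kl_obs,
            "p_value": p,
            "p_adj": p_adj,
            "flagged": degenerate,
        }
    ).set_index("gene")
    return HaystackResult(table=table, P=p_grid, Q=q, grid_centers=centers, bandwidth=sigma)


def build_modules(
    result: HaystackResult,
    detection: np.ndarray,
    p_cut: float | None = 1e-10,
    k: int = 3,
    top_n: int | None = None,
) -> pd.Series:
    """Cluster selected genes into k modules by correlation distance
    between their grid-level detection profiles (average linkage).

    Selection is ``p_adj < p_cut``; with permutation-based p-values whose
    floor is 1/(1+n_perm), a rank-based alternative (``top_n`` by KL
    statistic) is available.  Modules are labeled 1..k in dendrogram leaf
    order.
    """
    tab = result.table
    ok = ~tab["flagged"].to_numpy()
    if top_n is not None:
        idx = np.argsort(np.where(ok, tab["kl_stat"].to_numpy(), -np.inf))[::-1][:top_n]
        sel = np.zeros(len(tab), dtype=bool)
        sel[idx] = True
        sel &= ok
    else:
        sel = ok & (tab["p_adj"].to_numpy() < p_cut)
    genes = tab.index.to_numpy()[sel]
    if len(genes) < k:
        raise ValueError(f"k={k} exceeds the {len(genes)} genes passing selection")
    prof = result.P[sel]
    sd = prof.std(axis=1)
    corr = np.corrcoef(prof)
    corr = np.clip(np.nan_to_num(corr, nan=0.0), -1.0, 1.0)
    dist = 1.0 - corr
    # flat profiles: identical to each other (distance 0), maximally far
    # from non-flat ones (correlation undefined -> treated as 0)
    flat = sd == 0
    if flat.any():
        dist[np.ix_(flat, flat)] = 0.0
    from scipy.spatial.distance import squareform

    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)
    z = average(squareform(dist, checks=False))
    raw = fcluster(z, t=k, criterion="maxclust")
    # relabel 1..k following dendrogram leaf order
    leaf_order = leaves_list(z)
    seen: dict[int, int] = {}
    for leaf in leaf_order:
        if raw[leaf] not in seen:
            seen[raw[leaf]] = len(seen) + 1
    labels = np.array([seen[v] for v in raw])
    return pd.Series(labels, index=pd.Index(genes, name="gene"), name="module")


def module_scores(
    detection: np.ndarray,
    modules: pd.Series,
    gene_names: list[str],
    smooth_k: int = 0,
    embedding: Embedding | None = None,
) -> pd.DataFrame:
    """Per-cell module detection score: fraction of the module's genes
    detected in the cell, optionally averaged over the cell's ``smooth_k``
    nearest embedding neighbors (inclusive)."""
    det = np.asarray(detection, dtype=float)
    name_to_col = {g: j for j, g in enumerate(gene_names)}
    cols = {}
    for m in sorted(modules.unique()):
        genes = modules.index[modules == m]
        if len(genes) == 0:
            raise ValueError(f"module {m} is empty")
        idx = [name_to_col[g] for g in genes]
        cols[m] = det[:, idx].mean(axis=1)
    scores = pd.DataFrame(cols)
    if smooth_k > 0:
        if embedding is None:
            raise ValueError("smoothing requires an embedding")
        nn = NearestNeighbors(n_neighbors=smooth_k).fit(embedding.sig_coords)
        _, idx = nn.kneighbors(embedding.sig_coords)
        scores = pd.DataFrame(
            {m: scores[m].to_numpy()[idx].mean(axis=1) for m in scores.columns}
        )
    return scores
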