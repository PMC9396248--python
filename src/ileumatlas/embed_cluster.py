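"""Normalization, PCA with a two-criteria significant-PC rule, SNN graph
clustering, cluster dendrograms, and pseudobulk MDS.

The significant-PC rule takes a vector of per-PC percent-variation values
and returns the smaller of (A) the highest PC showing a >0.1 point change
in variation to the next PC and (B) the smallest PC at which cumulative
variation reaches 90% while the PC itself carries <5%.  The pipeline feeds
it 100·sd_i/Σsd over the first 100 computed PCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "Embedding",
    "lognormalize",
    "highly_variable_genes",
    "pca_embedding",
    "significant_pcs",
    "build_snn",
    "cluster_graph",
    "cluster_tree",
    "pseudobulk_mds",
    "recluster",
]


@dataclass
class Embedding:
    coords: np.ndarray  # cells x n_pcs
    pct_var: np.ndarray  # per-PC percent of variation (here: of total sd)
    n_sig: int

    def __post_init__(self) -> None:
        if np.any(self.pct_var < 0):
            raise ValueError("pct_var entries must be non-negative")
        if not 1 <= self.n_sig <= self.coords.shape[1]:
            raise ValueError("n_sig out of range")

    @property
    def sig_coords(self) -> np.ndarray:
        return self.coords[:, : self.n_sig]


def lognormalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """ln(1 + scale_factor * count / libsize); zero counts stay zero."""
    x = adata.X.tocsr() if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    lib = np.asarray(x.sum(axis=1)).ravel()
    if np.any(lib == 0):
        raise ValueError("zero-libsize cell encountered; run QC first")
    norm = x.multiply(scale_factor / lib[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    out = adata.copy()
    out.X = norm
    return out


def highly_variable_genes(norm: ad.AnnData, n_top: int = 2000) -> np.ndarray:
    """Indices of the top genes by standardized dispersion on log data.

    Dispersion = variance/mean on the log-normalized values, standardized
    within 20 mean-expression bins (the conventional toolchain default).
    """
    x = norm.X.tocsc() if sp.issparse(norm.X) else sp.csc_matrix(norm.X)
    mean = np.asarray(x.mean(axis=0)).ravel()
    sq = x.copy()
    sq.data **= 2
    var = np.asarray(sq.mean(axis=0)).ravel() - mean**2
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    bins = pd.qcut(pd.Series(mean), q=min(20, max(2, len(mean) // 10)), duplicates="drop")
    df = pd.DataFrame({"disp": disp, "bin": bins})
    grp = df.groupby("bin", observed=True)["disp"]
    z = (df["disp"] - grp.transform("mean")) / grp.transform("std").replace(0, np.nan)
    z = z.fillna(0.0).to_numpy()
    n_top = min(n_top, len(z))
    return np.sort(np.argsort(z)[::-1][:n_top])


def pca_embedding(
    norm: ad.AnnData,
    n_pcs: int = 100,
    n_hvg: int = 2000,
    seed: int = 0,
) -> Embedding:
    """Scale HVG log data, compute the first ``n_pcs`` PCs, and select the
    significant count with :func:`significant_pcs`.

    pct_var is the percent of total PC standard deviation carried by each
    PC, so its cumulative sum reaches 100 at the last computed PC.
    """
    hvg = highly_variable_genes(norm, n_top=n_hvg)
    x = norm.X.tocsc()[:, hvg]
    dense = np.asarray(x.todense())
    mu = dense.mean(axis=0)
    sd = dense.std(axis=0)
    sd[sd == 0] = 1.0
    scaled = np.clip((dense - mu) / sd, -10, 10)
    k = min(n_pcs, scaled.shape[0] - 1, scaled.shape[1])
    model = PCA(n_components=k, svd_solver="randomized", random_state=int(seed) % (2**31))
    coords = model.fit_transform(scaled)
    sdev = np.sqrt(model.explained_variance_)
    pct = 100.0 * sdev / sdev.sum()
    return Embedding(coords=coords, pct_var=pct, n_sig=significant_pcs(pct))


def significant_pcs(pct_var: np.ndarray) -> int:
    """Two-criteria elbow rule on a per-PC percent-variation vector.

    A = largest 1-based index i with pct[i] − pct[i+1] > 0.1 (the change
    attributed to the earlier PC); B = smallest 1-based j with cumulative
    pct ≥ 90 and pct[j] < 5.  Returns min of the criteria that fire, or
    the vector length when neither does.
    """
    pct = np.asarray(pct_var, dtype=float)
    if pct.size == 0:
        raise ValueError("empty pct_var vector")
    if pct.size < 2:
        return 1
    diffs = pct[:-1] - pct[1:]
    a_hits = np.flatnonzero(diffs > 0.1)
    a = int(a_hits[-1]) + 1 if a_hits.size else None
    cum = np.cumsum(pct)
    b_hits = np.flatnonzero((cum >= 90.0) & (pct < 5.0))
    b = int(b_hits[0]) + 1 if b_hits.size else None
    candidates = [c for c in (a, b) if c is not None]
    return min(candidates) if candidates else int(pct.size)


def build_snn(
    embedding: Embedding, k: int = 20, prune: float = 1.0 / 15.0
) -> igraph.Graph:
    """Shared-nearest-neighbor graph on significant-PC coordinates.

    Edge weight = Jaccard overlap of the two cells' k-NN sets (self
    inclusive, as is conventional); edges below ``prune`` are dropped.
    """
    coords = embedding.sig_coords
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    _, idx = nn.kneighbors(coords)
    rows = np.repeat(np.arange(n), k)
    a = sp.csr_matrix((np.ones(n * k), (rows, idx.ravel())), shape=(n, n))
    inter = (a @ a.T).tocoo()
    jac = inter.data / (2.0 * k - inter.data)
    keep = (jac >= prune) & (inter.row < inter.col)
    edges = list(zip(inter.row[keep].tolist(), inter.col[keep].tolist()))
    g = igraph.Graph(n=n, edges=edges, edge_attrs={"weight": jac[keep].tolist()})
    return g


def cluster_graph(graph: igraph.Graph, resolution: float = 3.0, seed: int = 0) -> pd.Series:
    """Leiden community detection; labels 0..C−1 ordered by decreasing size."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if "weight" in graph.edge_attributes() else None,
        resolution_parameter=resolution,
        seed=int(seed) % (2**31),
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    sizes = pd.Series(raw).value_counts()
    # stable relabeling: by decreasing size, ties by original id
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    return pd.Series([remap[c] for c in raw], name="cluster")


def cluster_tree(embedding: Embedding, labels: pd.Series) -> tuple[np.ndarray, list[int]]:
    """Average-linkage dendrogram over cluster centroids in sig-PC space.

    Returns (scipy linkage matrix, leaf order as cluster ids).
    """
    labels = pd.Series(np.asarray(labels))
    ids = np.sort(labels.unique())
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters for a dendrogram")
    coords = embedding.sig_coords
    centroids = np.vstack([coords[labels.to_numpy() == c].mean(axis=0) for c in ids])
    z = average(pdist(centroids))
    leaves = [int(ids[i]) for i in leaves_list(z)]
    return z, leaves


def linkage_to_newick(z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    n = len(leaf_names)

    def node(i: int) -> str:
        if i < n:
            return leaf_names[i]
        left, right, dist, _ = z[i - n]
        return f"({node(int(left))},{node(int(right))}):{dist:.6g}"

    return node(2 * n - 2) + ";"


def pseudobulk_mds(
    norm: ad.AnnData,
    sample_labels: np.ndarray | pd.Series | None = None,
    n_top_genes: int = 500,
) -> pd.DataFrame:
    """Classical (Torgerson) MDS of per-sample mean normalized expression.

    Restricts to the ``n_top_genes`` genes with highest cross-sample
    variance, double-centers the squared Euclidean distance matrix and
    eigendecomposes it to 2 dimensions.  Output is determined up to
    sign/rotation; the pairwise distances are the contract.
    """
    if sample_labels is None:
        sample_labels = norm.obs["sample_id"]
    sample_labels = pd.Series(np.asarray(sample_labels, dtype=object))
    samples = sorted(sample_labels.unique())
    if len(samples) < 3:
        raise ValueError("pseudobulk MDS needs at least 3 samples")
    x = norm.X.tocsr() if sp.issparse(norm.X) else sp.csr_matrix(norm.X)
    profiles = np.vstack(
        [np.asarray(x[(sample_labels == s).to_numpy()].mean(axis=0)).ravel() for s in samples]
    )
    var = profiles.var(axis=0)
    top = np.argsort(var)[::-1][: min(n_top_genes, profiles.shape[1])]
    p = profiles[:, top]
    d2 = squareform(pdist(p)) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:2]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return pd.DataFrame(coords, index=pd.Index(samples, name="sample"), columns=["MDS1", "MDS2"])


def recluster(
    counts: ad.AnnData,
    resolution: float = 3.0,
    k: int = 20,
    n_pcs: int = 100,
    n_hvg: int = 2000,
    seed: int = 0,
) -> tuple[ad.AnnData, Embedding, pd.Series]:
    """The subset-and-recompute composite: drop subset-zero genes, then
    log-normalize → PCA → significant-PC rule → SNN → communities.

    Returns (log-normalized AnnData over retained genes, embedding, labels).
    """
    totals = np.asarray(counts.X.sum(axis=0)).ravel()
    counts = counts[:, totals > 0].copy()
    norm = lognormalize(counts)
    emb = pca_embedding(norm, n_pcs=n_pcs, n_hvg=n_hvg, seed=seed)
    graph = build_snn(emb, k=k)
    labels = cluster_graph(graph, resolution=resolution, seed=seed)
    labels.index = norm.obs_names
    return norm, emb, labels
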