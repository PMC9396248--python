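"""Simplified reference-based label transfer and mapping.

A reference model is built by log-normalizing the reference counts,
scaling each gene, and reducing to d dimensions (default 30) by PCA.
Query cells are projected through the stored scaling and loadings; each
cell's prediction probabilities come from Gaussian-kernel voting over its
k nearest reference cells, and its mapping score is the mean kernel
similarity exp(−dist/σ) to those neighbors — 0 means the query cell is
poorly represented by the reference, 1 well represented.  Lineage-level
probabilities are sums of member-type probabilities, so they conserve the
per-cell probability simplex.  Cross-species queries are first restricted
to one-to-one orthologs and renamed to reference gene names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .embed_cluster import lognormalize

__all__ = [
    "ReferenceModel",
    "MappingResult",
    "ortholog_filter",
    "fit_reference",
    "map_query",
    "group_mapping_summary",
]


@dataclass
class ReferenceModel:
    genes: list[str]
    mean: np.ndarray
    sd: np.ndarray
    loadings: np.ndarray  # genes x d, orthonormal columns
    embedding: np.ndarray  # reference cells x d
    labels: pd.Series  # cell type per reference cell
    lineages: pd.Series | None = None  # type -> lineage
    d: int = 30


@dataclass
class MappingResult:
    probabilities: pd.DataFrame  # query cells x reference types, rows sum to 1
    mapping_score: pd.Series  # query cells, in [0, 1]
    lineage_probabilities: pd.DataFrame | None = None
    sigma: float = field(default=np.nan)


def ortholog_filter(query: ad.AnnData, table: pd.DataFrame) -> ad.AnnData:
    """Restrict to one-to-one orthologs and rename to reference names.

    ``table`` columns: query_gene, reference_gene.  Only pairs in which
    both genes occur exactly once in the table are kept (the one-to-one
    rule); query genes are renamed to their reference partner.  Filtering
    is idempotent because the identity-renamed pairs remain one-to-one.
    """
    t = table[["query_gene", "reference_gene"]].astype(str)
    q_counts = t["query_gene"].value_counts()
    r_counts = t["reference_gene"].value_counts()
    ok = t[(t["query_gene"].map(q_counts) == 1) & (t["reference_gene"].map(r_counts) == 1)]
    mapping = dict(zip(ok["query_gene"], ok["reference_gene"]))
    present = [g for g in query.var_names if g in mapping]
    if not present:
        raise ValueError("no query genes survive the one-to-one ortholog filter")
    out = query[:, present].copy()
    out.var_names = [mapping[g] for g in present]
    return out


def fit_reference(
    reference: ad.AnnData,
    labels: pd.Series | np.ndarray,
    d: int = 30,
    lineages: dict[str, str] | pd.Series | None = None,
    seed: int = 0,
) -> ReferenceModel:
    """Log-normalize, per-gene scale, and PCA-reduce the reference."""
    norm = lognormalize(reference)
    x = np.asarray(norm.X.todense()) if sp.issparse(norm.X) else np.asarray(norm.X)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    scaled = (x - mean) / sd
    rank = min(scaled.shape[0] - 1, scaled.shape[1])
    if d > rank:
        warnings.warn(f"d={d} exceeds data rank {rank}; reduced")
        d = rank
    model = PCA(n_components=d, svd_solver="randomized", random_state=int(seed) % (2**31))
    emb = model.fit_transform(scaled)
    return ReferenceModel(
        genes=list(reference.var_names),
        mean=mean,
        sd=sd,
        loadings=model.components_.T,
        embedding=emb,
        labels=pd.Series(np.asarray(labels, dtype=object), index=reference.obs_names),
        lineages=pd.Series(lineages) if lineages is not None else None,
        d=d,
    )


def map_query(
    model: ReferenceModel,
    query: ad.AnnData,
    k: int = 30,
    kernel_sigma: float | None = None,
) -> MappingResult:
    """Project the query and vote over k nearest reference cells.

    Prediction probability for label L = sum of Gaussian kernel weights
    exp(−d²/2σ²) of neighbors with label L over the total neighbor
    weight; mapping score = mean over the k neighbors of exp(−d/σ).
    σ defaults to the median reference-to-its-kNN distance.
    """
    shared = [g for g in model.genes if g in set(query.var_names)]
    if not shared:
        raise ValueError("no genes shared between query and reference model")
    # align query onto the full model gene list; absent genes contribute 0 counts
    norm = lognormalize(query)
    x = np.asarray(norm.X.todense()) if sp.issparse(norm.X) else np.asarray(norm.X)
    qcols = {g: j for j, g in enumerate(norm.var_names)}
    aligned = np.zeros((query.n_obs, len(model.genes)))
    for j, g in enumerate(model.genes):
        if g in qcols:
            aligned[:, j] = x[:, qcols[g]]
    proj = ((aligned - model.mean) / model.sd) @ model.loadings

    nn = NearestNeighbors(n_neighbors=k).fit(model.embedding)
    if kernel_sigma is None:
        ref_d, _ = nn.kneighbors(model.embedding)
        kernel_sigma = float(np.median(ref_d[:, 1:]))
    sigma = max(float(kernel_sigma), 1e-12)
    dist, idx = nn.kneighbors(proj)

    weights = np.exp(-(dist**2) / (2.0 * sigma**2))
    labels = model.labels.to_numpy()
    types = sorted(pd.unique(labels))
    probs = np.zeros((query.n_obs, len(types)))
    col = {t: j for j, t in enumerate(types)}
    neigh_labels = labels[idx]
    for j, t in enumerate(types):
        probs[:, j] = np.where(neigh_labels == t, weights, 0.0).sum(axis=1)
    tot = probs.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    probs /= tot
    prob_df = pd.DataFrame(probs, index=query.obs_names, columns=types)
    score = pd.Series(
        np.exp(-dist / sigma).mean(axis=1), index=query.obs_names, name="mapping_score"
    )

    lineage_df = None
    if model.lineages is not None:
        lin_of = model.lineages.to_dict()
        lineages = sorted({lin_of.get(t, t) for t in types})
        lineage_df = pd.DataFrame(0.0, index=query.obs_names, columns=lineages)
        for t in types:
            lineage_df[lin_of.get(t, t)] += prob_df[t]
    return MappingResult(
        probabilities=prob_df,
        mapping_score=score,
        lineage_probabilities=lineage_df,
        sigma=sigma,
    )


def group_mapping_summary(
    result: MappingResult, query_labels: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Mean, median, quartiles and 5th/95th percentiles of the mapping
    score per query type (linear-interpolation quantiles)."""
    labels = pd.Series(np.asarray(query_labels, dtype=object), index=result.mapping_score.index)
    rows = []
    for t in sorted(labels.unique()):
        vals = result.mapping_score[(labels == t).to_numpy()].to_numpy()
        if len(vals) == 0:
            warnings.warn(f"query type {t!r} has no cells; omitted")
            continue
        rows.append(
            {
                "type": t,
                "n": len(vals),
                "mean": float(np.mean(vals)),
                "median": float(np.median(vals)),
                "q25": float(np.quantile(vals, 0.25)),
                "q75": float(np.quantile(vals, 0.75)),
                "p5": float(np.quantile(vals, 0.05)),
                "p95": float(np.quantile(vals, 0.95)),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["quantile_method"] = "linear interpolation (type 7)"
    return out
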