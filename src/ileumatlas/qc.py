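"""Gene/cell filtering and doublet removal with fixed thresholds.

Cells are removed when the mitochondrial read percentage exceeds 12.5, when
fewer than 550 genes or 1,250 UMIs are detected, or when the doublet score
exceeds 0.25 — all strict inequalities, so boundary values survive.  Genes
with zero counts across all cells of all samples are dropped.  The doublet
scorer is a transparent simulate-and-kNN procedure: simulated doublets
(sums of random cell pairs) are embedded jointly with the observed cells
and each cell is scored by the simulated fraction among its nearest
neighbors, rescaled by the simulated:observed ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "QCMetrics",
    "QCThresholds",
    "compute_qc_metrics",
    "filter_genes",
    "score_doublets",
    "filter_cells",
]


@dataclass
class QCThresholds:
    """Removal thresholds; defaults are the study's printed values."""

    max_pct_mito: float = 12.5
    min_genes: int = 550
    min_umis: int = 1250
    max_doublet_score: float = 0.25
    expected_doublet_rate: float = 0.07

    def __post_init__(self) -> None:
        if self.max_pct_mito < 0 or self.max_pct_mito > 100:
            raise ValueError("max_pct_mito must be in [0, 100]")
        if min(self.min_genes, self.min_umis, self.max_doublet_score) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class QCMetrics:
    """Per-cell QC quantities; a DataFrame view is available via .frame."""

    n_genes_detected: np.ndarray
    n_umis: np.ndarray
    pct_mito: np.ndarray
    doublet_score: np.ndarray | None
    invalid: np.ndarray  # zero-UMI cells: pct_mito reported 0 but flagged
    sample_id: pd.Series | None = None

    @property
    def frame(self) -> pd.DataFrame:
        d = {
            "n_genes_detected": self.n_genes_detected,
            "n_umis": self.n_umis,
            "pct_mito": self.pct_mito,
            "invalid": self.invalid,
        }
        if self.doublet_score is not None:
            d["doublet_score"] = self.doublet_score
        df = pd.DataFrame(d)
        if self.sample_id is not None:
            df["sample_id"] = np.asarray(self.sample_id)
        return df


def compute_qc_metrics(adata: ad.AnnData, mito_flags: np.ndarray | None = None) -> QCMetrics:
    """Per-cell detected genes, total UMIs and mitochondrial percentage.

    ``mito_flags`` defaults to ``adata.var['mito']``.  All-zero cells are
    flagged invalid; their pct_mito is reported as 0.
    """
    if mito_flags is None:
        mito_flags = adata.var["mito"].to_numpy()
    mito_flags = np.asarray(mito_flags, dtype=bool)
    if mito_flags.shape[0] != adata.n_vars:
        raise ValueError(
            f"mito_flags length {mito_flags.shape[0]} does not match {adata.n_vars} genes"
        )
    x = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    x = x.tocsr()
    n_umis = np.asarray(x.sum(axis=1)).ravel()
    n_genes = x.getnnz(axis=1)
    mito_umis = np.asarray(x[:, mito_flags].sum(axis=1)).ravel()
    invalid = n_umis == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(invalid, 0.0, 100.0 * mito_umis / np.where(invalid, 1, n_umis))
    sample = adata.obs["sample_id"] if "sample_id" in adata.obs else None
    return QCMetrics(
        n_genes_detected=n_genes.astype(int),
        n_umis=n_umis.astype(int),
        pct_mito=pct,
        doublet_score=None,
        invalid=invalid,
        sample_id=sample,
    )


def filter_genes(adata: ad.AnnData) -> ad.AnnData:
    """Keep exactly the genes with total count > 0 across all cells."""
    totals = np.asarray(adata.X.sum(axis=0)).ravel()
    return adata[:, totals > 0].copy()


def score_doublets(
    adata: ad.AnnData,
    expected_rate: float = 0.07,
    k_neighbors: int = 20,
    seed: int = 0,
    n_pcs: int = 30,
    n_hvg: int = 1000,
) -> np.ndarray:
    """Simulate-and-kNN doublet scores in [0, 1], deterministic given seed.

    ``round(expected_rate * n)`` artificial doublets (element-wise sums of
    random observed cell pairs) are appended, the joint set is
    log-normalized and embedded by PCA, and each observed cell's score is
    the simulated fraction among its ``k_neighbors`` nearest neighbors
    rescaled by ``expected_rate * n_obs / n_sim`` (identity when the
    simulated count equals ``expected_rate * n``), clipped to [0, 1].
    """
    n = adata.n_obs
    if n < 2 * k_neighbors:
        raise ValueError(f"need at least {2 * k_neighbors} cells, got {n}")
    rng = np.random.default_rng(seed)
    x = adata.X.tocsr() if sp.issparse(adata.X) else sp.csr_matrix(adata.X)

    n_sim = max(k_neighbors + 1, int(round(expected_rate * n)))
    pairs = rng.integers(0, n, size=(n_sim, 2))
    sim = x[pairs[:, 0]] + x[pairs[:, 1]]
    joint = sp.vstack([x, sim]).tocsr()

    # log-normalize; restrict to high-variance genes for the embedding
    lib = np.asarray(joint.sum(axis=1)).ravel()
    lib[lib == 0] = 1
    norm = joint.multiply(1e4 / lib[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    dense = np.asarray(norm.todense())
    var = dense.var(axis=0)
    top = np.argsort(var)[::-1][: min(n_hvg, dense.shape[1])]
    emb = PCA(
        n_components=min(n_pcs, len(top), joint.shape[0] - 1),
        svd_solver="randomized",
        random_state=int(seed) % (2**31),
    ).fit_transform(dense[:, top])

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n])
    neigh = idx[:, 1:]  # drop self
    frac_sim = (neigh >= n).mean(axis=1)
    score = frac_sim * (expected_rate * n / n_sim)
    return np.clip(score, 0.0, 1.0)


def filter_cells(
    metrics: QCMetrics, thresholds: QCThresholds | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Apply the four removal rules; returns (kept mask, per-sample report).

    A cell is removed iff pct_mito > max_pct_mito OR n_genes < min_genes OR
    n_umis < min_umis OR doublet_score > max_doublet_score.  Cells
    violating several criteria are attributed to every violated criterion
    in the report.
    """
    thresholds = thresholds or QCThresholds()
    bad_mito = metrics.pct_mito > thresholds.max_pct_mito
    bad_genes = metrics.n_genes_detected < thresholds.min_genes
    bad_umis = metrics.n_umis < thresholds.min_umis
    if metrics.doublet_score is not None:
        bad_doublet = metrics.doublet_score > thresholds.max_doublet_score
    else:
        bad_doublet = np.zeros_like(bad_mito)
    removed = bad_mito | bad_genes | bad_umis | bad_doublet | metrics.invalid
    kept = ~removed

    if metrics.sample_id is not None:
        samples = pd.Series(np.asarray(metrics.sample_id, dtype=object))
    else:
        samples = pd.Series(["all"] * len(kept), dtype=object)
    report = (
        pd.DataFrame(
            {
                "sample": samples,
                "n_input": 1,
                "n_removed_mito": bad_mito.astype(int),
                "n_removed_genes": bad_genes.astype(int),
                "n_removed_umis": bad_umis.astype(int),
                "n_removed_doublet": np.asarray(bad_doublet).astype(int),
                "n_kept": kept.astype(int),
            }
        )
        .groupby("sample", sort=True)
        .sum()
        .reset_index()
    )
    return kept, report
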