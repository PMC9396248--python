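"""Neighborhood-based differential abundance between two conditions.

Neighborhoods are index cells (a uniform sample of a configured
proportion of cells) together with their k nearest neighbors in
significant-PC space.  Per-neighborhood member counts per sample are
modeled as negative binomial with sample totals as offsets and a common
dispersion estimated across neighborhoods by method of moments; the
condition effect is a Wald test on the log proportion ratio with the
moderated dispersion entering the variance.  BH adjustment across
neighborhoods.  A neighborhood is annotated as a cell type when strictly
more than 70% of its members carry that one label, otherwise "mixed".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .embed_cluster import Embedding

__all__ = [
    "NeighborhoodSet",
    "make_neighborhoods",
    "test_da",
    "annotate_neighborhoods",
    "da_summary",
]


@dataclass
class NeighborhoodSet:
    index_cells: np.ndarray
    members: list[np.ndarray]
    sample_ids: pd.Series  # per cell
    counts: pd.DataFrame = field(default_factory=pd.DataFrame)  # nhoods x samples
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    assigned_type: pd.Series = field(default_factory=pd.Series)

    @property
    def n_neighborhoods(self) -> int:
        return len(self.index_cells)


def make_neighborhoods(
    embedding: Embedding,
    sample_ids: pd.Series | np.ndarray,
    prop: float = 0.2,
    k: int = 20,
    seed: int = 0,
) -> NeighborhoodSet:
    """Sample ⌈prop·n⌉ index cells and attach each one's k nearest
    neighbors (Euclidean in significant-PC space); deterministic given
    seed."""
    if not 0.0 < prop <= 1.0:
        raise ValueError("prop must lie in (0, 1]")
    coords = embedding.sig_coords
    n = coords.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} cells, got {n}")
    rng = np.random.default_rng(seed)
    n_index = int(np.ceil(prop * n))
    index_cells = np.sort(rng.choice(n, size=n_index, replace=False))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords[index_cells])
    members = []
    for i, cell in enumerate(index_cells):
        neigh = [j for j in idx[i] if j != cell][:k]
        members.append(np.array(sorted({cell, *neigh})))
    sample_ids = pd.Series(np.asarray(sample_ids, dtype=object))
    samples = sorted(sample_ids.unique())
    counts = np.zeros((n_index, len(samples)), dtype=int)
    col = {s: j for j, s in enumerate(samples)}
    sarr = sample_ids.to_numpy()
    for i, mem in enumerate(members):
        for cell in mem:
            counts[i, col[sarr[cell]]] += 1
    counts_df = pd.DataFrame(counts, columns=samples)
    counts_df.index.name = "neighborhood"
    return NeighborhoodSet(
        index_cells=index_cells, members=members, sample_ids=sample_ids, counts=counts_df
    )


def _common_dispersion(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments NB dispersion pooled over all observations:
    solves Var = mu + alpha·mu² in expectation."""
    ok = mu > 0
    num = ((y[ok] - mu[ok]) ** 2 - mu[ok]) / mu[ok] ** 2
    return float(max(np.mean(num), 0.0))


def test_da(
    nhoods: NeighborhoodSet,
    design: dict[str, str] | pd.Series,
    allow_unreplicated: bool = False,
) -> pd.DataFrame:
    """Per-neighborhood differential abundance between two conditions.

    ``design`` maps sample -> condition (exactly two conditions).  logFC
    is the natural log of the proportion ratio (second condition in sorted
    order over the first), with a 0.5 pseudo-count on zero counts
    (flagged).  Returns a table with logFC, p, p_adj and updates
    ``nhoods.stats`` in place.
    """
    design = pd.Series(dict(design) if isinstance(design, dict) else design)
    counts = nhoods.counts
    missing = set(counts.columns) - set(design.index)
    if missing:
        raise ValueError(f"design missing samples: {sorted(missing)}")
    conditions = sorted(design.unique())
    if len(conditions) != 2:
        raise ValueError(f"exactly two conditions required, got {conditions}")
    c0, c1 = conditions
    s0 = [s for s in counts.columns if design[s] == c0]
    s1 = [s for s in counts.columns if design[s] == c1]
    if min(len(s0), len(s1)) < 2 and not allow_unreplicated:
        raise ValueError(
            "a condition has a single sample; pass allow_unreplicated=True "
            "to fall back to an exact binomial test"
        )

    # sample totals (all cells of the dataset) as offsets
    totals = nhoods.sample_ids.value_counts()
    n0 = float(sum(totals[s] for s in s0))
    n1 = float(sum(totals[s] for s in s1))
    y = counts.to_numpy(dtype=float)
    y0 = counts[s0].sum(axis=1).to_numpy(dtype=float)
    y1 = counts[s1].sum(axis=1).to_numpy(dtype=float)

    # fitted means under the alternative (condition-specific proportions)
    mu = np.zeros_like(y)
    for j, s in enumerate(counts.columns):
        if design[s] == c0:
            mu[:, j] = y0 / n0 * totals[s]
        else:
            mu[:, j] = y1 / n1 * totals[s]
    alpha = _common_dispersion(y.ravel(), mu.ravel())

    zero_flag = (y0 == 0) | (y1 == 0)
    y0p = np.where(y0 == 0, 0.5, y0)
    y1p = np.where(y1 == 0, 0.5, y1)
    logfc = np.log((y1p / n1) / (y0p / n0))

    if min(len(s0), len(s1)) >= 2:
        # Wald on the log proportion ratio; NB variance with the common
        # dispersion, delta method on log of condition sums
        var0 = (y0p + alpha * np.array([np.sum(mu[i, [counts.columns.get_loc(s) for s in s0]] ** 2) for i in range(len(y0))])) / y0p**2
        var1 = (y1p + alpha * np.array([np.sum(mu[i, [counts.columns.get_loc(s) for s in s1]] ** 2) for i in range(len(y1))])) / y1p**2
        se = np.sqrt(var0 + var1)
        z = logfc / se
        p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        warnings.warn("unreplicated design: exact binomial test fallback")
        p = np.array(
            [
                stats.binomtest(int(a), int(a + b), n1 / (n0 + n1)).pvalue if a + b > 0 else 1.0
                for a, b in zip(y1, y0)
            ]
        )
    p_adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "logFC": logfc,
            "p_value": p,
            "p_adj": p_adj,
            "zero_in_one_condition": zero_flag,
        },
        index=counts.index,
    )
    out.attrs["conditions"] = (c0, c1)
    out.attrs["dispersion"] = alpha
    nhoods.stats = out
    return out


def annotate_neighborhoods(
    nhoods: NeighborhoodSet, cell_labels: pd.Series | np.ndarray, frac: float = 0.70
) -> pd.Series:
    """Assign each neighborhood the cell type covering strictly more than
    ``frac`` of its members, else "mixed"."""
    labels = np.asarray(cell_labels, dtype=object)
    out = []
    for mem in nhoods.members:
        vc = pd.Series(labels[mem]).value_counts()
        share = vc.iloc[0] / len(mem)
        out.append(vc.index[0] if share > frac else "mixed")
    assigned = pd.Series(out, index=nhoods.counts.index, name="assigned_type")
    nhoods.assigned_type = assigned
    return assigned


def da_summary(nhoods: NeighborhoodSet, alpha: float = 0.1) -> tuple[pd.DataFrame, float]:
    """Per-type counts of (up, none, down) neighborhoods at BH level
    ``alpha`` and the overall differentially-abundant fraction."""
    if nhoods.stats.empty:
        raise ValueError("run test_da first")
    stats_df = nhoods.stats
    sig = stats_df["p_adj"] < alpha
    direction = np.where(~sig, "none", np.where(stats_df["logFC"] > 0, "up", "down"))
    types = (
        nhoods.assigned_type
        if len(nhoods.assigned_type)
        else pd.Series(["all"] * len(stats_df), index=stats_df.index)
    )
    df = pd.DataFrame({"type": np.asarray(types), "direction": direction})
    table = (
        df.value_counts().unstack(fill_value=0).reindex(columns=["up", "none", "down"], fill_value=0)
    )
    frac = float(sig.mean())
    return table, frac
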