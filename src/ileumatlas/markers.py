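"""Dot-plot statistics, per-cluster DGE with fixed filters, canonical
marker lineage/subset rules, and composition summaries.

A gene is reported as differentially expressed for a cluster only when it
is detected in >10% of cells on at least one side of the comparison, has
|logFC| > 0.25 (natural-log units on expm1-reverted means with pseudocount
1), and a corrected P-value < 0.05 (Bonferroni by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MarkerStats",
    "LineageRule",
    "expression_summary",
    "cluster_markers",
    "top_markers",
    "assign_lineages",
    "default_lineage_rules",
    "t_subset_assign",
    "composition_summary",
]


@dataclass
class MarkerStats:
    """Per (gene, group) dot-plot statistics.

    pct_expr: fraction of group cells with count > 0.
    avg_expr_in_expressers: mean log-normalized value over expressing
    cells (0 with ``avg_flagged`` when no cell expresses).
    rel_avg: that mean z-scored per gene across groups.
    """

    pct_expr: pd.DataFrame  # groups x genes
    avg_expr_in_expressers: pd.DataFrame
    rel_avg: pd.DataFrame
    avg_flagged: pd.DataFrame  # True where pct_expr == 0


def expression_summary(
    norm: ad.AnnData, labels: pd.Series | np.ndarray, genes: list[str]
) -> MarkerStats:
    missing = [g for g in genes if g not in norm.var_names]
    if missing:
        raise KeyError(f"genes not found: {missing}")
    labels = pd.Series(np.asarray(labels))
    groups = sorted(labels.unique(), key=str)
    sub = norm[:, genes]
    x = sub.X.tocsc() if sp.issparse(sub.X) else sp.csc_matrix(sub.X)
    pct = np.zeros((len(groups), len(genes)))
    avg = np.zeros_like(pct)
    for i, grp in enumerate(groups):
        mask = (labels == grp).to_numpy()
        block = x[mask]
        n = mask.sum()
        nnz = block.getnnz(axis=0)
        pct[i] = nnz / n
        sums = np.asarray(block.sum(axis=0)).ravel()
        with np.errstate(invalid="ignore"):
            avg[i] = np.where(nnz > 0, sums / np.maximum(nnz, 1), 0.0)
    mu = avg.mean(axis=0)
    sd = avg.std(axis=0)
    rel = np.where(sd > 0, (avg - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    idx = pd.Index(groups, name="group")
    cols = pd.Index(genes, name="gene")
    return MarkerStats(
        pct_expr=pd.DataFrame(pct, index=idx, columns=cols),
        avg_expr_in_expressers=pd.DataFrame(avg, index=idx, columns=cols),
        rel_avg=pd.DataFrame(rel, index=idx, columns=cols),
        avg_flagged=pd.DataFrame(pct == 0, index=idx, columns=cols),
    )


def _wilcoxon_p(group_vals: np.ndarray, rest_vals: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum; exact when both sides are tiny and
    tie-free, asymptotic with continuity correction otherwise."""
    method = "auto"
    if len(group_vals) <= 8 and len(rest_vals) <= 8:
        method = "exact" if len(np.unique(np.r_[group_vals, rest_vals])) == len(group_vals) + len(rest_vals) else "asymptotic"
    else:
        method = "asymptotic"
    return float(mannwhitneyu(group_vals, rest_vals, alternative="two-sided", method=method).pvalue)


def cluster_markers(
    norm: ad.AnnData,
    labels: pd.Series | np.ndarray,
    min_pct: float = 0.10,
    min_logfc: float = 0.25,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Per-cluster DGE versus the rest of the dataset.

    Wilcoxon rank-sum per gene, logFC from expm1-reverted group means with
    pseudocount 1, multiplicity correction over genes within each group.
    Rows failing any of the three filters are dropped.  Single-cell groups
    are skipped.
    """
    labels = pd.Series(np.asarray(labels))
    groups = sorted(labels.unique(), key=str)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    x = norm.X.tocsc() if sp.issparse(norm.X) else sp.csc_matrix(norm.X)
    genes = np.asarray(norm.var_names)
    n_genes = x.shape[1]
    dense = np.asarray(x.todense())
    rows = []
    for grp in groups:
        mask = (labels == grp).to_numpy()
        n_g, n_r = int(mask.sum()), int((~mask).sum())
        if n_g < 2:
            import warnings

            warnings.warn(f"group {grp!r} has fewer than 2 cells; skipped")
            continue
        gvals, rvals = dense[mask], dense[~mask]
        pct_g = (gvals > 0).mean(axis=0)
        pct_r = (rvals > 0).mean(axis=0)
        mean_g = np.expm1(gvals).mean(axis=0)
        mean_r = np.expm1(rvals).mean(axis=0)
        logfc = np.log(mean_g + 1.0) - np.log(mean_r + 1.0)
        candidate = ((pct_g > min_pct) | (pct_r > min_pct)) & (np.abs(logfc) > min_logfc)
        pvals = np.ones(n_genes)
        if n_g <= 8 and n_r <= 8:
            for j in np.flatnonzero(candidate):
                pvals[j] = _wilcoxon_p(gvals[:, j], rvals[:, j])
        elif candidate.any():
            res = mannwhitneyu(
                gvals[:, candidate], rvals[:, candidate], alternative="two-sided", axis=0
            )
            pvals[candidate] = res.pvalue
        if correction == "bonferroni":
            padj = np.minimum(pvals * n_genes, 1.0)
        else:
            padj = multipletests(pvals, method="fdr_bh")[1]
        keep = candidate & (padj < alpha)
        for j in np.flatnonzero(keep):
            rows.append(
                {
                    "group": grp,
                    "gene": genes[j],
                    "logFC": logfc[j],
                    "p_value": pvals[j],
                    "p_adj": padj[j],
                    "pct_group": pct_g[j],
                    "pct_rest": pct_r[j],
                }
            )
    return pd.DataFrame(rows, columns=["group", "gene", "logFC", "p_value", "p_adj", "pct_group", "pct_rest"])


def top_markers(de: pd.DataFrame, n: int = 5) -> dict[object, list[str]]:
    """Up to ``n`` genes per group by descending positive logFC; ties by
    smaller p then lexicographic gene id."""
    out: dict[object, list[str]] = {}
    for grp, sub in de.groupby("group", sort=True):
        pos = sub[sub["logFC"] > 0].sort_values(
            by=["logFC", "p_value", "gene"], ascending=[False, True, True]
        )
        out[grp] = pos["gene"].head(n).tolist()
    return out


@dataclass
class LineageRule:
    """First-match-wins conjunction of (gene, comparator, threshold)."""

    label: str
    conditions: list[tuple[str, str, float]] = field(default_factory=list)

    _OPS = {
        ">": np.greater,
        ">=": np.greater_equal,
        "<": np.less,
        "<=": np.less_equal,
    }

    def matches(self, pct_row: pd.Series) -> bool:
        return all(self._OPS[op](pct_row[gene], thr) for gene, op, thr in self.conditions)


def default_lineage_rules() -> list[LineageRule]:
    """T cells: pan-T gene CD3E detected in >75% of the cluster.  ILCs:
    CD3E in at most half the cells but CD2 broadly detected, with B and
    myeloid markers near-absent."""
    return [
        LineageRule("T", [("CD3E", ">", 0.75)]),
        LineageRule(
            "ILC",
            [("CD3E", "<=", 0.50), ("CD2", ">=", 0.50), ("CD79A", "<", 0.10), ("SIRPA", "<", 0.10)],
        ),
    ]


def assign_lineages(
    stats: MarkerStats, rules: list[LineageRule] | None = None, fallback: str = "unassigned"
) -> pd.Series:
    """Apply an ordered rule list over per-cluster detection percentages."""
    rules = rules if rules is not None else default_lineage_rules()
    # identical conditions pointing at different labels are contradictory;
    # several rules sharing a label (alternative routes) are fine
    seen: dict[tuple, str] = {}
    for r in rules:
        key = tuple(r.conditions)
        if key in seen and seen[key] != r.label:
            raise ValueError(
                f"contradictory duplicate rules: {seen[key]!r} vs {r.label!r} share conditions"
            )
        seen[key] = r.label
    for r in rules:
        for gene, _, _ in r.conditions:
            if gene not in stats.pct_expr.columns:
                raise KeyError(f"rule gene {gene!r} absent from stats")
    out = {}
    for grp, row in stats.pct_expr.iterrows():
        label = fallback
        for r in rules:
            if r.matches(row):
                label = r.label
                break
        out[grp] = label
    return pd.Series(out, name="lineage")


def t_subset_assign(
    stats: MarkerStats,
    genes: tuple[str, str, str] = ("CD4", "CD8B", "TRDC"),
    threshold: float = 0.10,
) -> pd.Series:
    """T-subset call per cluster from detection of CD4 / CD8B / TRDC.

    Exactly one gene above threshold names the subset; the two recognized
    double-positive patterns are mixed clusters; anything else is
    unresolved.  Strict > at the threshold.
    """
    cd4, cd8b, trdc = genes
    for g in genes:
        if g not in stats.pct_expr.columns:
            raise KeyError(f"gene {g!r} absent from stats")
    single = {cd4: "CD4 ab T", cd8b: "CD8 ab T", trdc: "gd T"}
    out = {}
    for grp, row in stats.pct_expr.iterrows():
        pos = frozenset(g for g in genes if row[g] > threshold)
        if len(pos) == 1:
            out[grp] = single[next(iter(pos))]
        elif pos == frozenset({cd4, cd8b}):
            out[grp] = "mixed CD4/CD8"
        elif pos == frozenset({cd8b, trdc}):
            out[grp] = "mixed gd/CD8"
        else:
            out[grp] = "unresolved"
    return pd.Series(out, name="t_subset")


def composition_summary(
    labels: pd.Series | np.ndarray | dict[str, int],
    grouping: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Counts and percentages per label, optionally within grouping levels.

    Accepts either per-cell labels or a precomputed ``{label: count}``
    mapping.  Percentages are 100·count/total at full precision with a
    2-decimal ``pct_rounded`` report column.
    """
    if isinstance(labels, dict):
        counts = pd.Series(labels, dtype=int)
        frames = [("all", counts)]
    else:
        labels = pd.Series(np.asarray(labels, dtype=object))
        if grouping is None:
            frames = [("all", labels.value_counts())]
        else:
            grouping = pd.Series(np.asarray(grouping, dtype=object))
            frames = [
                (lvl, labels[(grouping == lvl).to_numpy()].value_counts())
                for lvl in sorted(grouping.unique())
            ]
    rows = []
    for level, counts in frames:
        total = int(counts.sum())
        for label, n in counts.sort_index().items():
            pct = 100.0 * n / total
            rows.append(
                {
                    "level": level,
                    "label": label,
                    "count": int(n),
                    "total": total,
                    "pct": pct,
                    "pct_rounded": round(pct, 2),
                }
            )
    return pd.DataFrame(rows)
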