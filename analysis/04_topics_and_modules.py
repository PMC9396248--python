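#!/usr/bin/env python
"""Topic modeling and embedding-aware differential detection on the
T/ILC lineage subset, followed by rule-based subtype calls.

The lineage subset is re-embedded and re-clustered; a K=3 grade-of-
membership topic model and a k=3 gene-module decomposition (top genes by
the KL detection statistic) provide the per-cell features consumed by
the threshold decision tree.
"""

import argparse
from pathlib import Path

import pandas as pd

from ileumatlas import classify_signatures as cs
from ileumatlas import embed_cluster as ec
from ileumatlas import io, pipeline
from ileumatlas import topics_modules as tm


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--topics-k", type=int, default=3)
    ap.add_argument("--modules-k", type=int, default=3)
    ap.add_argument("--n-perm", type=int, default=100)
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    out = Path(args.outdir)

    adata = io.read_mtx(out / "data" / "atlas_mtx")
    clusters = pd.read_csv(out / "clusters.tsv", sep="\t", index_col=0)
    adata = adata[adata.obs_names.isin(clusters.index)].copy()
    lineage = clusters.loc[adata.obs_names, "lineage"]

    norm, emb, sub_labels = pipeline.subset_recompute(
        adata, lineage, "T/ILC", resolution=1.0, seed=args.seed
    )
    print(f"T/ILC subset: {norm.n_obs} cells, {emb.n_sig} significant PCs, "
          f"{sub_labels.nunique()} clusters")

    fit = tm.fit_topics(
        adata[adata.obs_names.isin(norm.obs_names)].copy(),
        K=args.topics_k, seed=args.seed,
    )
    det, _ = tm.detection_matrix(norm)
    hay = tm.haystack_dge(
        det, emb, n_grid=min(100, norm.n_obs // 4), n_perm=args.n_perm,
        seed=args.seed, gene_names=list(norm.var_names),
    )
    modules = tm.build_modules(hay, det, k=args.modules_k, top_n=100)
    scores = tm.module_scores(det, modules, list(norm.var_names))

    features = pd.DataFrame(
        {f"t{t + 1}": fit.L[:, t] for t in range(fit.K)}, index=norm.obs_names
    )
    for m in scores.columns:
        features[f"m{m}"] = scores[m].to_numpy()
    features["cluster"] = sub_labels.to_numpy()
    subtype = cs.classify_cells(features, cs.RuleSet.builtin("cd4"))

    pd.DataFrame(fit.L, index=norm.obs_names).to_csv(out / "topic_weights.tsv", sep="\t")
    hay.table.to_csv(out / "haystack_stats.tsv", sep="\t")
    modules.to_csv(out / "gene_modules.tsv", sep="\t")
    scores.set_index(norm.obs_names).to_csv(out / "module_scores.tsv", sep="\t")
    pd.DataFrame({"subtype": subtype}).to_csv(out / "subset_subtypes.tsv", sep="\t")

    print(f"genes at the permutation floor: "
          f"{(hay.table['p_value'] <= 1.0 / (args.n_perm + 1) + 1e-12).sum()}")
    print("module sizes:", modules.value_counts().to_dict())
    print("subtype counts:", subtype.value_counts().to_dict())


if __name__ == "__main__":
    main()
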