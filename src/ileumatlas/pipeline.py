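"""End-to-end orchestration with manifests and subset-and-recompute.

``run_all`` executes simulate → QC → embedding/clustering → lineage
calls/composition → lineage-subset recompute with topics, differential
detection, modules and subtype classification → neighborhood differential
abundance → reference mapping → signature derivation, writing each
stage's outputs as TSV/JSON files under an output directory and
recording parameters, outputs, and significant-PC counts in a run
manifest.  Stage interfaces are files so every stage is independently
replayable.  Deterministic given (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify_signatures, embed_cluster, markers, neighborhoods_da
from . import qc as qc_mod
from . import reference_map, synthetic_data, topics_modules

__all__ = ["default_pipeline_config", "run_all", "subset_recompute"]


def default_pipeline_config() -> dict:
    return {
        "seed": 0,
        "simulate": {"n_cells_per_sample": 1300, "n_genes": 1500},
        "qc": {"max_pct_mito": 12.5, "min_genes": 550, "min_umis": 1250,
               "max_doublet_score": 0.25, "expected_doublet_rate": 0.07},
        "embed": {"n_pcs": 100, "n_hvg": 2000, "k_snn": 20, "resolution": 3.0},
        "subset": {"lineage": "T/ILC", "resolution": 1.0, "topics_k": 3,
                   "modules_k": 3, "n_grid": 100, "n_perm": 60, "top_n_genes": 100},
        "da": {"prop": 0.2, "k": 20, "alpha": 0.1,
               "condition_of": {"PP": "PP", "nonPP": "nonPP"}},
        "map": {"d": 30, "k": 30},
        "signature": {},
        "skip": [],
    }


def _merge(base: dict, override: dict | None) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base.get(k, {}), v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def subset_recompute(
    counts, labels, selector, min_cells: int = 50, resolution: float = 1.0, seed: int = 0,
    n_pcs: int = 100, n_hvg: int = 2000,
):
    """Re-run normalize → PCA → significant-PC rule → SNN → clustering on
    the cells matched by ``selector`` (a boolean mask or a label value
    over ``labels``); genes with zero counts in the subset are dropped."""
    labels = pd.Series(np.asarray(labels, dtype=object), index=counts.obs_names)
    if isinstance(selector, (str, int)):
        mask = (labels == selector).to_numpy()
    else:
        mask = np.asarray(selector, dtype=bool)
    if mask.sum() < min_cells:
        raise ValueError(f"selector matches {mask.sum()} cells, below the {min_cells} floor")
    sub = counts[mask].copy()
    return embed_cluster.recluster(
        sub, resolution=resolution, seed=seed, n_pcs=n_pcs, n_hvg=n_hvg
    )


def run_all(config: dict | None = None, outdir: str | os.PathLike = "pipeline_out") -> dict:
    """Run the full synthetic pipeline; returns the manifest dict."""
    cfg = _merge(default_pipeline_config(), config)
    seed = int(cfg["seed"])
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(cfg), "seed": seed, "stages": {}}
    skip = set(cfg.get("skip", []))

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info

    # ------------------------------------------------------------ simulate
    if "simulate" in skip:
        record("simulate", skipped=True)
        raise ValueError("run_all requires the simulate stage (no external input path wired)")
    sim_cfg = synthetic_data.ileum_default_config(
        n_cells_per_sample=cfg["simulate"]["n_cells_per_sample"],
        n_genes=cfg["simulate"]["n_genes"],
        seed=seed,
    )
    adata, truth = synthetic_data.generate_atlas(sim_cfg)
    truth.to_csv(out / "truth.tsv", sep="\t")
    record("simulate", skipped=False, n_cells=int(adata.n_obs), n_genes=int(adata.n_vars),
           outputs=["truth.tsv"])

    # ------------------------------------------------------------------ qc
    if "qc" in skip:
        kept = np.ones(adata.n_obs, dtype=bool)
        record("qc", skipped=True)
    else:
        adata = qc_mod.filter_genes(adata)
        metrics = qc_mod.compute_qc_metrics(adata)
        thr = qc_mod.QCThresholds(
            max_pct_mito=cfg["qc"]["max_pct_mito"], min_genes=cfg["qc"]["min_genes"],
            min_umis=cfg["qc"]["min_umis"], max_doublet_score=cfg["qc"]["max_doublet_score"],
            expected_doublet_rate=cfg["qc"]["expected_doublet_rate"],
        )
        # metric filters first, then doublet scoring on metric-passing cells
        kept1, _ = qc_mod.filter_cells(metrics, thr)
        passing = adata[kept1].copy()
        scores = qc_mod.score_doublets(
            passing, expected_rate=thr.expected_doublet_rate, seed=seed
        )
        m2 = qc_mod.compute_qc_metrics(passing)
        m2.doublet_score = scores
        kept2, report = qc_mod.filter_cells(m2, thr)
        report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        adata = passing[kept2].copy()
        kept = np.zeros(len(truth), dtype=bool)
        kept[truth.index.get_indexer(adata.obs_names)] = True
        record("qc", skipped=False, thresholds=vars(thr), n_kept=int(adata.n_obs),
               outputs=["qc_report.tsv"])
    truth_kept = truth.loc[adata.obs_names]

    # --------------------------------------------------------- embed/cluster
    norm = embed_cluster.lognormalize(adata)
    emb = embed_cluster.pca_embedding(
        norm, n_pcs=cfg["embed"]["n_pcs"], n_hvg=cfg["embed"]["n_hvg"], seed=seed
    )
    graph = embed_cluster.build_snn(emb, k=cfg["embed"]["k_snn"])
    labels = embed_cluster.cluster_graph(graph, resolution=cfg["embed"]["resolution"], seed=seed)
    labels.index = norm.obs_names
    pd.DataFrame({"cluster": labels}).to_csv(out / "clusters.tsv", sep="\t")
    record("embed_cluster", skipped=False, n_sig=int(emb.n_sig),
           n_clusters=int(labels.nunique()), outputs=["clusters.tsv"])

    # ------------------------------------------------- lineages/composition
    rule_genes = ["CD3E", "CD2", "CD79A", "JCHAIN", "SIRPA"]
    stats = markers.expression_summary(norm, labels, rule_genes)
    lineage_rules = [
        markers.LineageRule("T/ILC", [("CD3E", ">", 0.75)]),
        markers.LineageRule(
            "T/ILC", [("CD3E", "<=", 0.50), ("CD2", ">=", 0.50),
                      ("CD79A", "<", 0.10), ("SIRPA", "<", 0.10)],
        ),
        markers.LineageRule("B", [("CD79A", ">", 0.50)]),
        markers.LineageRule("B", [("JCHAIN", ">", 0.50)]),  # antibody-secreting cells
        markers.LineageRule("myeloid", [("SIRPA", ">", 0.50)]),
    ]
    cluster_lineage = markers.assign_lineages(stats, lineage_rules, fallback="non-leukocyte")
    cell_lineage = labels.map(cluster_lineage)
    comp = markers.composition_summary(cell_lineage)
    comp.to_csv(out / "composition.tsv", sep="\t", index=False)
    record("markers", skipped=False, outputs=["composition.tsv"],
           lineages=cluster_lineage.to_dict())

    # ------------------------------------------ lineage subset: topics etc.
    if "subset" in skip:
        record("subset", skipped=True)
    else:
        sub_lineage = cfg["subset"]["lineage"]
        sub_mask = (cell_lineage == sub_lineage).to_numpy()
        sub_norm, sub_emb, sub_labels = subset_recompute(
            adata, cell_lineage, sub_mask, resolution=cfg["subset"]["resolution"], seed=seed
        )
        fit = topics_modules.fit_topics(
            adata[sub_mask].copy(), K=cfg["subset"]["topics_k"], seed=seed
        )
        det, _ = topics_modules.detection_matrix(sub_norm)
        hay = topics_modules.haystack_dge(
            det, sub_emb, n_grid=min(cfg["subset"]["n_grid"], sub_norm.n_obs // 4),
            n_perm=cfg["subset"]["n_perm"], seed=seed,
            gene_names=list(sub_norm.var_names),
        )
        modules = topics_modules.build_modules(
            hay, det, k=cfg["subset"]["modules_k"], top_n=cfg["subset"]["top_n_genes"]
        )
        scores = topics_modules.module_scores(det, modules, list(sub_norm.var_names))
        features = pd.DataFrame(
            {f"t{t + 1}": fit.L[:, t] for t in range(fit.K)}, index=sub_norm.obs_names
        )
        for m in scores.columns:
            features[f"m{m}"] = scores[m].to_numpy()
        features["cluster"] = sub_labels.to_numpy()
        subtype = classify_signatures.classify_cells(
            features, classify_signatures.RuleSet.builtin("cd4")
        )
        pd.DataFrame({"subtype": subtype}).to_csv(out / "subset_subtypes.tsv", sep="\t")
        record("subset", skipped=False, lineage=sub_lineage, n_cells=int(sub_norm.n_obs),
               n_sig=int(sub_emb.n_sig), outputs=["subset_subtypes.tsv"])

    # ------------------------------------------------------------------ da
    if "da" in skip:
        record("da", skipped=True)
    else:
        cond_map = {}
        for s in adata.obs["sample_id"].unique():
            if s.endswith("_nonPP"):
                cond_map[s] = "nonPP"
            elif s.endswith("_PP"):
                cond_map[s] = "PP"
        da_mask = adata.obs["sample_id"].isin(cond_map).to_numpy()
        da_counts = adata[da_mask].copy()
        da_norm, da_emb, _ = embed_cluster.recluster(
            da_counts, resolution=cfg["embed"]["resolution"], seed=seed
        )
        nh = neighborhoods_da.make_neighborhoods(
            da_emb, da_counts.obs["sample_id"], prop=cfg["da"]["prop"],
            k=cfg["da"]["k"], seed=seed,
        )
        neighborhoods_da.test_da(nh, cond_map)
        neighborhoods_da.annotate_neighborhoods(
            nh, truth.loc[da_counts.obs_names, "true_type"].to_numpy()
        )
        table, frac = neighborhoods_da.da_summary(nh, alpha=cfg["da"]["alpha"])
        nh.stats.join(nh.assigned_type).to_csv(out / "da_neighborhoods.tsv", sep="\t")
        table.to_csv(out / "da_summary.tsv", sep="\t")
        record("da", skipped=False, da_fraction=frac, outputs=["da_neighborhoods.tsv", "da_summary.tsv"])

    # ----------------------------------------------------------------- map
    if "map" in skip:
        record("map", skipped=True)
    else:
        is_whole = adata.obs["sample_id"].str.endswith("_whole").to_numpy()
        ref = adata[is_whole].copy()
        query = adata[~is_whole].copy()
        model = reference_map.fit_reference(
            ref, truth.loc[ref.obs_names, "true_type"], d=cfg["map"]["d"], seed=seed,
            lineages=sim_cfg.type_lineage,
        )
        res = reference_map.map_query(model, query, k=cfg["map"]["k"])
        summary = reference_map.group_mapping_summary(
            res, truth.loc[query.obs_names, "true_type"]
        )
        summary.to_csv(out / "mapping_summary.tsv", sep="\t", index=False)
        record("map", skipped=False, sigma=res.sigma, outputs=["mapping_summary.tsv"])

    # ------------------------------------------------------------ signature
    if "signature" in skip:
        record("signature", skipped=True)
    else:
        ilc_markers = [g for g, p in zip(adata.var_names, adata.var["program"]) if p == "ILC"]
        spec = classify_signatures.SignatureSpec(
            candidate_genes=list(ilc_markers),
            target_subsets=["ILC"],
            nontarget_subsets=["CD4_T", "CD8_T", "gd_T", "B"],
        )
        sig, evidence = classify_signatures.derive_signature(
            norm, truth_kept["true_type"], spec
        )
        evidence.to_csv(out / "signature_evidence.tsv", sep="\t", index=False)
        record("signature", skipped=False, n_genes=len(sig), outputs=["signature_evidence.tsv"])

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
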