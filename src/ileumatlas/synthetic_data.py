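"""Synthetic scRNA-seq atlas generator with planted ground truth.

Generates multi-sample UMI count matrices carrying the structure the
downstream stages assume: per-type marker-gene programs, a cycling program
shared across lineages, mitochondrial genes, doublets at a configured rate,
low-quality cells with reduced library size and boosted mitochondrial
fraction, and sample-specific lineage compositions (emulating gut tissue
dissections with and without Peyer's patches, plus a peripheral-blood
tissue sharing some cell types with the gut but not others).

The generative model is deliberately the one the downstream topic model
fits: each cell has a simplex of program weights drawn from a Dirichlet
centred on its type's profile; its counts are multinomial with gene
probabilities given by the weight-mixture of program gene-probability
rows.  Doublets are element-wise sums of two uniformly chosen singlets;
low-quality cells have their mitochondrial probability multiplied by a
boost factor and their library size divided by 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

__all__ = [
    "ProgramSpec",
    "SampleSpec",
    "SimConfig",
    "generate_atlas",
    "generate_two_tissue",
    "ileum_default_config",
    "load_config",
    "save_config",
]

#: baseline weight of a marker gene outside its own program, as a fraction
#: of the uniform per-gene probability.  Keeps planted markers rare in
#: cells with no weight on their program (a few percent detection), as in
#: real data where cell-type markers are nearly absent elsewhere.
MARKER_BASELINE = 0.02


@dataclass
class ProgramSpec:
    """A latent expression program: a block of enriched marker genes."""

    marker_gene_count: int
    marker_enrichment: float  # fold over the uniform per-gene probability, >1


@dataclass
class SampleSpec:
    sample_id: str
    animal_id: str
    tissue_id: str
    composition: dict[str, float]  # cell type -> fraction, sums to 1


@dataclass
class SimConfig:
    n_cells_per_sample: int
    samples: list[SampleSpec]
    n_genes: int
    n_mito_genes: int
    programs: dict[str, ProgramSpec]
    type_profiles: dict[str, dict[str, float]]  # type -> program -> weight
    dirichlet_concentration: float = 8.0
    libsize_log_mean: float = float(np.log(2500.0))
    libsize_log_sd: float = 0.35
    doublet_rate: float = 0.07
    lowq_rate: float = 0.05
    lowq_mito_boost: float = 25.0
    seed: int = 0
    type_lineage: dict[str, str] = field(default_factory=dict)
    # optional canonical symbols for the first markers of a program, e.g.
    # {"T_common": ["CD3E"]} names that program's first marker gene CD3E
    marker_symbols: dict[str, list[str]] = field(default_factory=dict)

    def validate(self) -> None:
        if not 0.0 <= self.doublet_rate <= 1.0 or not 0.0 <= self.lowq_rate <= 1.0:
            raise ValueError("doublet_rate and lowq_rate must lie in [0, 1]")
        if self.doublet_rate + self.lowq_rate > 1.0:
            raise ValueError("doublet_rate + lowq_rate exceeds 1")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        for s in self.samples:
            total = sum(s.composition.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"sample {s.sample_id!r}: composition sums to {total}, not 1")
            missing = set(s.composition) - set(self.type_profiles)
            if missing:
                raise ValueError(
                    f"sample {s.sample_id!r} names types absent from type_profiles: {sorted(missing)}"
                )
        for t, prof in self.type_profiles.items():
            total = sum(prof.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"type_profile {t!r} sums to {total}, not 1")
            unknown = set(prof) - set(self.programs)
            if unknown:
                raise ValueError(f"type_profile {t!r} references unknown programs {sorted(unknown)}")
        marker_demand = sum(p.marker_gene_count for p in self.programs.values())
        if self.n_genes < marker_demand + self.n_mito_genes:
            raise ValueError(
                f"n_genes={self.n_genes} smaller than total marker demand "
                f"({marker_demand} markers + {self.n_mito_genes} mito genes)"
            )

    def lineage_of(self, cell_type: str) -> str:
        return self.type_lineage.get(cell_type, cell_type)


def _build_gene_universe(config: SimConfig) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Lay out the gene axis and return (var table, program -> marker index)."""
    names, symbols, mito, program_of = [], [], [], []
    marker_idx: dict[str, np.ndarray] = {}
    cursor = 0
    for prog_id in config.programs:
        n = config.programs[prog_id].marker_gene_count
        idx = np.arange(cursor, cursor + n)
        marker_idx[prog_id] = idx
        overrides = config.marker_symbols.get(prog_id, [])
        for j in range(n):
            names.append(f"G{cursor + j:05d}")
            symbols.append(overrides[j] if j < len(overrides) else f"{prog_id}.M{j}")
            mito.append(False)
            program_of.append(prog_id)
        cursor += n
    for j in range(config.n_mito_genes):
        names.append(f"G{cursor:05d}")
        symbols.append(f"MT.{j}")
        mito.append(True)
        program_of.append("")
        cursor += 1
    while cursor < config.n_genes:
        names.append(f"G{cursor:05d}")
        symbols.append(f"BG.{cursor}")
        mito.append(False)
        program_of.append("")
        cursor += 1
    # symbols are unique by construction and serve as the primary gene axis
    var = pd.DataFrame(
        {"gene_symbol": symbols, "mito": mito, "program": program_of},
        index=pd.Index(symbols),
    )
    return var, marker_idx


def _program_matrix(config: SimConfig, var: pd.DataFrame, marker_idx: dict[str, np.ndarray]) -> np.ndarray:
    """Rows of per-program gene probabilities (each row sums to 1)."""
    g = config.n_genes
    base = np.full(g, 1.0 / g)
    is_marker = (var["program"].to_numpy() != "")
    base[is_marker] *= MARKER_BASELINE
    rows = np.empty((len(config.programs), g))
    for i, prog_id in enumerate(config.programs):
        row = base.copy()
        row[marker_idx[prog_id]] = config.programs[prog_id].marker_enrichment / g
        rows[i] = row / row.sum()
    return rows


def _simulate_sample(
    config: SimConfig,
    sample: SampleSpec,
    f_programs: np.ndarray,
    mito_mask: np.ndarray,
    rng: np.random.Generator,
) -> tuple[sp.csr_matrix, pd.DataFrame, np.ndarray]:
    """Generate one sample; returns (counts, truth rows, program weights)."""
    prog_ids = list(config.programs)
    n = config.n_cells_per_sample
    types = list(sample.composition)
    fracs = np.array([sample.composition[t] for t in types])
    type_draw = rng.choice(len(types), size=n, p=fracs)

    # alpha vectors per type; zero-weight programs stay exactly zero
    alphas = {}
    for t in types:
        prof = np.array([config.type_profiles[t].get(p, 0.0) for p in prog_ids])
        alphas[t] = prof * config.dirichlet_concentration

    weights = np.zeros((n, len(prog_ids)))
    for i in range(n):
        a = alphas[types[type_draw[i]]]
        pos = a > 0
        w = np.zeros_like(a)
        w[pos] = rng.dirichlet(a[pos])
        weights[i] = w

    libsizes = np.maximum(
        1, np.round(rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, size=n))
    ).astype(int)

    # cell fate: doublet / low-quality / singlet (mutually exclusive)
    u = rng.random(n)
    is_doublet = u < config.doublet_rate
    is_lowq = (~is_doublet) & (u < config.doublet_rate + config.lowq_rate)

    counts = np.zeros((n, config.n_genes), dtype=np.int64)
    probs = weights @ f_programs
    for i in range(n):
        p = probs[i]
        lib = libsizes[i]
        if is_lowq[i]:
            p = p.copy()
            p[mito_mask] *= config.lowq_mito_boost
            p /= p.sum()
            lib = max(1, lib // 4)
        counts[i] = rng.multinomial(lib, p)

    singlet_pool = np.flatnonzero(~is_doublet & ~is_lowq)
    partner_type = np.array([""] * n, dtype=object)
    if is_doublet.any():
        if len(singlet_pool) < 2:
            raise ValueError("not enough singlets to form doublets")
        for i in np.flatnonzero(is_doublet):
            a, b = rng.choice(singlet_pool, size=2, replace=False)
            counts[i] = counts[a] + counts[b]
            weights[i] = 0.5 * (weights[a] + weights[b])
            type_draw[i] = type_draw[a]
            partner_type[i] = types[type_draw[b]]

    true_type = [types[j] for j in type_draw]
    truth = pd.DataFrame(
        {
            "true_type": true_type,
            "true_lineage": [config.lineage_of(t) for t in true_type],
            "is_doublet": is_doublet,
            "is_lowq": is_lowq,
            "doublet_partner_type": partner_type,
            "sample_id": sample.sample_id,
            "animal_id": sample.animal_id,
            "tissue_id": sample.tissue_id,
        }
    )
    return sp.csr_matrix(counts), truth, weights


def generate_atlas(config: SimConfig) -> tuple[ad.AnnData, pd.DataFrame]:
    """Generate a multi-sample atlas; returns (counts AnnData, truth table).

    Deterministic given ``config.seed``: the same config always yields the
    same counts and truth.  The AnnData carries sample/animal/tissue in
    ``.obs`` and mito/marker-program flags in ``.var``; the truth table
    additionally holds the per-cell program-weight simplex and the
    doublet/low-quality flags.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    var, marker_idx = _build_gene_universe(config)
    f_programs = _program_matrix(config, var, marker_idx)
    mito_mask = var["mito"].to_numpy()

    blocks, truths, weight_blocks = [], [], []
    for sample in config.samples:
        x, truth, w = _simulate_sample(config, sample, f_programs, mito_mask, rng)
        blocks.append(x)
        truths.append(truth)
        weight_blocks.append(w)

    counts = sp.vstack(blocks).tocsr()
    truth = pd.concat(truths, ignore_index=True)
    barcodes = [f"cell{i:06d}" for i in range(truth.shape[0])]
    truth.index = pd.Index(barcodes)
    weights = np.vstack(weight_blocks)
    for j, prog_id in enumerate(config.programs):
        truth[f"w_{prog_id}"] = weights[:, j]

    obs = truth[["sample_id", "animal_id", "tissue_id"]].copy()
    adata = ad.AnnData(X=counts, obs=obs, var=var.copy())
    adata.obs_names = barcodes
    return adata, truth


def generate_two_tissue(
    config: SimConfig,
    shared_types: list[str],
    exclusive_types: dict[str, list[str]],
    block_genes: int = 10,
    block_enrichment: float = 60.0,
    block_weight: float = 0.20,
) -> tuple[ad.AnnData, ad.AnnData, pd.DataFrame, pd.DataFrame]:
    """Generate two tissues over one gene universe with planted blocks.

    ``config.samples`` must span exactly two tissue_ids.  Shared types
    occur in both tissues but receive a tissue-specific marker block (extra
    program ``{type}@{tissue}`` of ``block_genes`` genes) so that
    tissue-specific gene signatures are derivable and recoverable.
    Tissue-exclusive types occur only in their own tissue's samples.
    """
    tissues = sorted({s.tissue_id for s in config.samples})
    if len(tissues) != 2:
        raise ValueError(f"config.samples must span exactly two tissues, got {tissues}")
    exclusive_all = [t for ts in exclusive_types.values() for t in ts]
    overlap = set(shared_types) & set(exclusive_all)
    if overlap:
        raise ValueError(f"types cannot be both shared and exclusive: {sorted(overlap)}")
    for tis, ts in exclusive_types.items():
        if tis not in tissues:
            raise ValueError(f"exclusive_types names unknown tissue {tis!r}")
        other = [t for t in tissues if t != tis][0]
        for s in config.samples:
            if s.tissue_id == other and any(t in s.composition for t in ts):
                raise ValueError(
                    f"sample {s.sample_id!r} in tissue {other!r} names "
                    f"tissue-{tis!r}-exclusive types"
                )

    # extend the program set with per-(shared type, tissue) blocks
    programs = dict(config.programs)
    for t in shared_types:
        for tis in tissues:
            programs[f"{t}@{tis}"] = ProgramSpec(block_genes, block_enrichment)

    profiles: dict[str, dict[str, float]] = {}
    for t, prof in config.type_profiles.items():
        profiles[t] = dict(prof)
    # per-tissue profile for shared types: shift block_weight onto the block
    for t in shared_types:
        for tis in tissues:
            shifted = {p: w * (1.0 - block_weight) for p, w in config.type_profiles[t].items()}
            shifted[f"{t}@{tis}"] = block_weight
            profiles[f"{t}@{tis}"] = shifted

    results = {}
    for k, tis in enumerate(tissues):
        samples = []
        for s in config.samples:
            if s.tissue_id != tis:
                continue
            comp = {
                (f"{t}@{tis}" if t in shared_types else t): f
                for t, f in s.composition.items()
            }
            samples.append(SampleSpec(s.sample_id, s.animal_id, s.tissue_id, comp))
        sub = SimConfig(
            n_cells_per_sample=config.n_cells_per_sample,
            samples=samples,
            n_genes=config.n_genes,
            n_mito_genes=config.n_mito_genes,
            programs=programs,
            type_profiles=profiles,
            dirichlet_concentration=config.dirichlet_concentration,
            libsize_log_mean=config.libsize_log_mean,
            libsize_log_sd=config.libsize_log_sd,
            doublet_rate=config.doublet_rate,
            lowq_rate=config.lowq_rate,
            lowq_mito_boost=config.lowq_mito_boost,
            seed=config.seed + k,
            type_lineage=config.type_lineage,
            marker_symbols=config.marker_symbols,
        )
        adata, truth = generate_atlas(sub)
        # report the underlying shared-type name in the truth table
        strip = {f"{t}@{tis}": t for t in shared_types}
        truth["true_type"] = truth["true_type"].map(lambda x: strip.get(x, x))
        truth["true_lineage"] = truth["true_type"].map(config.lineage_of)
        adata.obs_names = [f"{tis}_{b}" for b in adata.obs_names]
        truth.index = adata.obs_names
        results[tis] = (adata, truth)

    (a, ta), (b, tb) = results[tissues[0]], results[tissues[1]]
    return a, b, ta, tb


def ileum_default_config(
    n_cells_per_sample: int = 1300, n_genes: int = 1500, seed: int = 0
) -> SimConfig:
    """Default study conditions: six gut samples from two animals.

    Per animal, one sample containing only lymphoid-follicle regions (PP),
    one excluding them (nonPP) and one whole cross-section.  Lineage-level
    compositions follow the observed splits (PP/whole dominated by B
    lineage at ~64/59%, nonPP dominated by T/ILC at ~82%).
    """
    comp_pp = {
        "B": 0.52, "ASC": 0.12, "CD4_T": 0.12, "CD8_T": 0.09,
        "gd_T": 0.07, "ILC": 0.05, "myeloid": 0.01, "epithelial": 0.02,
    }
    comp_whole = {
        "B": 0.48, "ASC": 0.11, "CD4_T": 0.13, "CD8_T": 0.11,
        "gd_T": 0.09, "ILC": 0.05, "myeloid": 0.01, "epithelial": 0.02,
    }
    comp_nonpp = {
        "B": 0.09, "ASC": 0.025, "CD4_T": 0.17, "CD8_T": 0.28,
        "gd_T": 0.22, "ILC": 0.15, "myeloid": 0.015, "epithelial": 0.05,
    }
    samples = []
    for animal, comps in (("pig1", (comp_pp, comp_nonpp, comp_whole)),
                          ("pig2", (comp_pp, comp_nonpp, comp_whole))):
        for label, comp in zip(("PP", "nonPP", "whole"), comps):
            samples.append(SampleSpec(f"{animal}_{label}", animal, "ileum", dict(comp)))
    cell_types = list(comp_pp)
    programs = {t: ProgramSpec(30, 50.0) for t in cell_types}
    programs["T_common"] = ProgramSpec(5, 50.0)  # pan-T block incl. CD3E
    programs["CD2_block"] = ProgramSpec(3, 50.0)  # CD2 shared by T and ILC
    programs["cycling"] = ProgramSpec(25, 40.0)
    programs["housekeeping"] = ProgramSpec(0, 1.0)
    type_profiles: dict[str, dict[str, float]] = {}
    for t in cell_types:
        if t in ("CD4_T", "CD8_T", "gd_T"):
            type_profiles[t] = {
                t: 0.40, "T_common": 0.15, "CD2_block": 0.05,
                "housekeeping": 0.30, "cycling": 0.10,
            }
        elif t == "ILC":
            type_profiles[t] = {
                t: 0.45, "CD2_block": 0.15, "housekeeping": 0.30, "cycling": 0.10,
            }
        else:
            type_profiles[t] = {t: 0.60, "housekeeping": 0.30, "cycling": 0.10}
    marker_symbols = {
        "T_common": ["CD3E"],
        "CD2_block": ["CD2"],
        "B": ["CD79A"],
        "ASC": ["JCHAIN"],
        "CD4_T": ["CD4"],
        "CD8_T": ["CD8B"],
        "gd_T": ["TRDC"],
        "myeloid": ["SIRPA"],
        "epithelial": ["EPCAM"],
    }
    lineage = {
        "B": "B", "ASC": "B",
        "CD4_T": "T/ILC", "CD8_T": "T/ILC", "gd_T": "T/ILC", "ILC": "T/ILC",
        "myeloid": "myeloid", "epithelial": "non-leukocyte",
    }
    return SimConfig(
        n_cells_per_sample=n_cells_per_sample,
        samples=samples,
        n_genes=n_genes,
        n_mito_genes=13,
        programs=programs,
        type_profiles=type_profiles,
        seed=seed,
        type_lineage=lineage,
        marker_symbols=marker_symbols,
    )


def save_config(config: SimConfig, path: str) -> None:
    doc = {
        "n_cells_per_sample": config.n_cells_per_sample,
        "samples": [
            {
                "sample_id": s.sample_id,
                "animal_id": s.animal_id,
                "tissue_id": s.tissue_id,
                "composition": s.composition,
            }
            for s in config.samples
        ],
        "n_genes": config.n_genes,
        "n_mito_genes": config.n_mito_genes,
        "programs": {
            p: {"marker_gene_count": s.marker_gene_count, "marker_enrichment": s.marker_enrichment}
            for p, s in config.programs.items()
        },
        "type_profiles": config.type_profiles,
        "dirichlet_concentration": config.dirichlet_concentration,
        "libsize_log_mean": config.libsize_log_mean,
        "libsize_log_sd": config.libsize_log_sd,
        "doublet_rate": config.doublet_rate,
        "lowq_rate": config.lowq_rate,
        "lowq_mito_boost": config.lowq_mito_boost,
        "seed": config.seed,
        "type_lineage": config.type_lineage,
        "marker_symbols": config.marker_symbols,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path: str) -> SimConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SimConfig(
        n_cells_per_sample=doc["n_cells_per_sample"],
        samples=[
            SampleSpec(s["sample_id"], s["animal_id"], s["tissue_id"], s["composition"])
            for s in doc["samples"]
        ],
        n_genes=doc["n_genes"],
        n_mito_genes=doc["n_mito_genes"],
        programs={
            p: ProgramSpec(s["marker_gene_count"], s["marker_enrichment"])
            for p, s in doc["programs"].items()
        },
        type_profiles=doc["type_profiles"],
        dirichlet_concentration=doc["dirichlet_concentration"],
        libsize_log_mean=doc["libsize_log_mean"],
        libsize_log_sd=doc["libsize_log_sd"],
        doublet_rate=doc["doublet_rate"],
        lowq_rate=doc["lowq_rate"],
        lowq_mito_boost=doc["lowq_mito_boost"],
        seed=doc["seed"],
        type_lineage=doc.get("type_lineage", {}),
        marker_symbols=doc.get("marker_symbols", {}),
    )
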