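# Methods

`ileumatlas` re-implements, as a tested library plus a set of analysis
drivers, the multi-stage annotation workflow used for gut lymphocyte
scRNA-seq atlases: fixed-threshold QC, dimensionality reduction with an
explicit significant-PC rule, SNN graph clustering, canonical-marker
lineage calls, grade-of-membership topic modeling, embedding-aware
differential detection with gene modules, threshold decision trees for
subtype annotation, neighborhood differential abundance, simplified
reference label transfer, and pairwise-enrichment signature derivation.
Every stage is exercised against a synthetic generator that plants the
structure the stage assumes, so correctness claims are made against known
ground truth rather than against a reference implementation's numbers.

## Synthetic data model

Each cell carries a program-weight vector on the simplex, drawn from a
Dirichlet centred on its cell type's profile (`dirichlet_concentration`,
default 8; larger values give tighter types). Counts are multinomial:
library size is LogNormal (default median 2,500 UMIs, log-sd 0.35) and the
gene-probability vector is the weight-mixture of per-program gene
probability rows. A program is a block of marker genes enriched
`marker_enrichment`-fold (default 50) over the uniform per-gene
probability; outside their program, marker genes are down-weighted to 2%
of uniform so that planted markers are detected in only a few percent of
non-program cells, as for real cell-type markers. Mitochondrial genes
(default 13) are ordinary background genes flagged mito.

Doublets (rate 0.07) are element-wise sums of two uniformly chosen
singlets from the same sample and keep the first parent's type label with
the partner recorded separately. Low-quality cells (rate 0.05) have their
library size divided by 4 and their mitochondrial probability multiplied
by 25 before renormalization, so all three QC thresholds are exercised at
once. Generation is a pure function of (config, seed).

The default configuration emulates six gut samples from two animals —
per animal one lymphoid-follicle (PP) sample, one follicle-free (nonPP)
sample and one whole cross-section — with B-lineage-dominated
compositions in PP/whole (~64%/59% B lineage) and a T/ILC-dominated
nonPP (~82% T/ILC), the lineage splits such dissections show. Canonical marker symbols (CD3E, CD2, CD79A,
JCHAIN, SIRPA, CD4, CD8B, TRDC, EPCAM) name the first genes of the
corresponding programs so the shipped lineage rules operate verbatim.
The two-tissue generator adds, per shared type and tissue, a 10-gene
tissue-specific block program (20% of the type's profile weight), which
is the planted target for signature-derivation tests.

What the generator does **not** emulate: transcriptome-wide expression
distributions (gene baseline is uniform outside marker blocks), ambient
RNA, batch effects requiring integration, and library-level technical
covariates. Passing tests therefore demonstrate algorithmic correctness
and calibration under the stated generative model, not performance on
real tissue data.

## QC

Cells are removed iff pct_mito > 12.5, genes detected < 550, UMIs <
1,250, or doublet score > 0.25 — strict inequalities throughout, so
boundary values survive. Gene filtering keeps exactly the genes with
nonzero total count over all cells of all samples. Doublet scoring is a
transparent simulate-and-vote procedure: `round(0.07·n)` artificial
doublets (sums of random cell pairs) are embedded jointly with the
observed cells (log-normalize, top-1000 variable genes, 30 PCs), and a
cell's score is the simulated fraction among its 20 nearest neighbors
rescaled by `expected_rate·n_obs/n_sim` (the identity when the simulated
count equals the expected-rate count) and clipped to [0, 1]. Doublet
scoring runs on metric-passing cells; the stage order is configurable.
On the default generator the score ranks planted doublets above singlets
with AUC ≈ 0.9.

## Embedding and clustering

Log-normalization is ln(1 + 10⁴·count/libsize). The top 2,000 genes by
binned standardized dispersion are z-scored (clipped at ±10) and reduced
to 100 PCs. The significant-PC count feeds on the percent of total PC
standard deviation per component: criterion A is the largest PC showing a
>0.1-point drop to its successor (the change attributed to the earlier
PC); criterion B is the smallest PC at which the cumulative percentage
reaches 90 while the PC itself carries <5; the rule returns the smaller
of the two, ignoring a criterion that never fires. The cumulative
comparison is ≥90 so that a perfectly flat 100-PC spectrum selects PC 90.

The SNN graph connects cells whose 20-NN sets (self-inclusive) have
Jaccard overlap ≥ 1/15; communities come from Leiden RB-configuration
modularity at a configurable resolution (3.0 by default, a fine-grained
setting suited to atlas-style over-clustering before annotation; subset
analyses in the tests use 1.0) with labels
ordered by decreasing size. Cluster dendrograms are average-linkage on
cluster centroids in significant-PC space. Pseudobulk MDS is classical
(Torgerson) scaling of per-sample mean normalized expression restricted
to the 500 most variable genes across samples — implemented directly
because the defining primitive is the double-centered eigendecomposition,
which is exact in 2D for three samples; gene selection by overall
variance (rather than pairwise leading fold-change) is a deliberate
simplification.

## Marker statistics and lineage rules

Dot-plot statistics are the detection fraction (count > 0) and the mean
log-normalized expression over expressing cells, z-scored per gene across
groups. Cluster DGE is a two-sided Wilcoxon rank-sum of each group
against the rest (exact when both sides have ≤8 tie-free observations),
with logFC = ln(mean+1) ratios on expm1-reverted normalized means and
Bonferroni correction over genes (BH available); reported rows must have
>10% detection on one side, |logFC| > 0.25 and adjusted p < 0.05.

Lineage assignment is a first-match-wins list of per-cluster conjunctions
over detection fractions: pan-T (CD3E > 75%), ILC (CD3E ≤ 50%, CD2 ≥ 50%,
CD79A and SIRPA < 10%); the 75% pan-T cutoff is the established value,
while the CD2/CD79A/SIRPA cutoffs are this package's quantitative
defaults for criteria that are usually applied by eye. T subsets use strict >10% detection of CD4/CD8B/TRDC with
the two recognized double-positive patterns called mixed and everything
else unresolved. Composition summaries carry full precision internally
and 2-decimal rounding in reports.

## Topics and differential detection

The topic model is the multinomial grade of membership model
(cells×topics weights L, topics×genes probabilities F, both row-simplex)
fit by EM on the nonzero count entries, Dirichlet(1) initialization,
3 restarts keeping the best log-likelihood, stopping at a relative
log-likelihood change below 1e-6 or 200 iterations. The trace is
monotone by construction and asserted in tests. Per-topic enrichment is
ln F ratios against the usage-weighted mean of the other topics, capped
at ln(1e6) for genes absent elsewhere.

"Detection" is expression strictly above the gene's dataset-wide median
(equivalently nonzero detection for majority-zero genes). The
differential-detection statistic places a grid of k-means centroids
(default 100) in significant-PC space; each cell contributes Gaussian
kernel weight exp(−d²/2σ²) with σ the median cell-to-nearest-centroid
distance. For gene g, P is the normalized grid weight of detecting cells
and Q of all cells; the statistic is KL(P‖Q) with 1e-9 additive
smoothing. Significance comes from permuting detection across cells
within deciles of per-cell total detection (preserving per-cell
detection propensity), default 200 permutations, so the p-value floor is
1/201; BH adjustment across genes. Spline-modeled randomization nulls
used by some implementations of this statistic are deliberately replaced
by this fully specified permutation scheme, and the statistic is
verified against a brute-force double-loop oracle. Because the
permutation floor cannot reach a 1e-10 module cutoff, module building
supports rank-based
selection (top N by KL) alongside the p-value cutoff; genes are
clustered by 1−Pearson correlation of their grid profiles, average
linkage, cut into k modules numbered in dendrogram leaf order. Module
detection scores are the fraction of a module's genes detected per cell
(range [0, 1], so absolute thresholds in decision rules stay
meaningful), with optional kNN smoothing off by default.

## Subtype decision trees and signatures

Rule sets are data (YAML): an ordered list of (label, boolean expression)
steps over module scores, topic weights, cluster ids and gene ratios,
plus one fallback label. Expressions use a restricted grammar (and/or,
comparisons incl. `in` over literal tuples, arithmetic) compiled to
vectorized closures; "and/or" in the encoded captions is inclusive OR and
all thresholds are strict. Four trees ship built-in (helper-T,
γδ/cytotoxic-T, ILC, B) with cluster pre-assignments evaluated before
score rules. Two documented ambiguities in the annotation scheme these trees encode:
the B tree's resting clusters are shipped as {9, 13, 30} (an alternative
reading gives {9, 13, 20}), and the ILC activation rule is parsed as
"t3<0.05 AND (m2>0.4 OR t2>0.9)" rather than
"(t3<0.05 AND m2>0.4) OR t2>0.9"; both are overridable in user YAML.
The γδ-vs-CD8 gene-ratio classifier assigns the first label only for a
ratio strictly above 1, with 0/0 falling to the second label.

Signature derivation keeps a candidate gene iff detected in >10% of
every target subset, and for every (target, nontarget) pair either the
detection fraction is ≥2× the nontarget's, or it is larger but <2× and
the mean log-normalized expression (over all subset cells; an
expressers-only switch exists) is ≥2×. The evidence table records the
satisfied branch per pair. The filter is monotone in both fold
parameters, which the tests assert.

## Neighborhood differential abundance

Neighborhoods are ⌈0.2·n⌉ uniformly sampled index cells plus their k=20
nearest neighbors in significant-PC space. Counts per sample are modeled
as negative binomial with the dataset's per-sample cell totals as
offsets; a single common dispersion is estimated across all neighborhoods
by method of moments (2v2 replication cannot support per-neighborhood
dispersion). The condition effect is a Wald test on the log proportion
ratio with the NB variance propagated by the delta method; zero counts in
a condition get a 0.5 pseudo-count and are flagged. BH adjustment is
plain — graph-overlap spatial FDR corrections are deliberately out of
scope; calibration is verified by a null 2v2 simulation
rather than assumed. Unreplicated designs require an explicit opt-in and
fall back to an exact binomial test. A neighborhood is annotated as a
cell type when strictly more than 70% of its members share that label,
else "mixed". The power simulation in the tests uses k=60 neighborhoods
over 2,000-cell samples so that per-condition counts (≈45 vs 15 under a
3× shift) can support the 2v2 comparison; at k=20 with ~20-cell
neighborhoods the same shift is detectable but not reliably after
multiplicity adjustment — a real constraint of the method at small
neighborhood sizes, documented rather than hidden.

## Reference mapping

The reference model is log-normalize → per-gene z-scale → PCA to d=30
dimensions; anchor-based transfer machinery is replaced by
project-then-vote, preserving the reported contracts (probability
simplex, 0–1 score, per-type box summaries) without claiming numeric
equality with anchor-based tools. Query cells are projected through the stored
scaling and loadings; prediction probabilities are Gaussian-kernel votes
over the k=30 nearest reference cells (σ = median reference-to-own-kNN
distance unless given), so they are non-negative and sum to one per
cell; lineage probabilities are sums over member types and conserve the
simplex. The mapping score is the mean kernel similarity exp(−d/σ) to
the k neighbors: near 1 for query cells sitting in dense reference
regions, lower for populations absent from the reference. Cross-species
queries first pass a one-to-one ortholog filter (both genes must occur
exactly once in the mapping table) and are renamed to reference names.
Per-type score summaries use linear-interpolation quantiles (type 7),
recorded in the output metadata.

## Orchestration and problem sizes

`pipeline.run_all` executes simulate → QC → embed/cluster → lineage
calls → T/ILC-subset topics/modules/classification → PP-vs-nonPP DA →
whole-section-reference mapping → signature derivation, writing
TSV/JSON artifacts and a manifest (config hash, seeds, per-stage
parameters, significant-PC counts) under one output directory; stages
are individually skippable and the run is deterministic given (config,
seed). The analysis drivers under `analysis/` run the same stages as a
narrative sequence over a shared `results/` directory.

Default problem sizes were chosen as the smallest at which each
behavior under test is stably expressed: 6×250–650 cells for QC and
composition checks, 450 tight cells for exact type recovery by
clustering, 2,000 cells for topic recovery and detection calibration
(200 genes, 200 permutations), 2,600 cells/520 neighborhoods for DA
calibration and 8,000 cells/1,600 neighborhoods for DA power, and
~800 cells per tissue for signature and mapping checks.

## Known limitations

- All calibration and recovery claims are relative to the generator's
  multinomial model; heavy-tailed technical noise, ambient RNA and batch
  structure are out of scope.
- Leiden on kNN-derived graphs fragments large diffuse clusters at high
  resolution; exact type recovery requires the neighborhood size to be
  matched to cluster size (documented in the clustering tests).
- The doublet scorer's rescaling is heuristic; only the ranking (AUC) and
  the threshold semantics are contractual.
- Topic-model K and module k are configuration values; no automatic
  model selection is provided.
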