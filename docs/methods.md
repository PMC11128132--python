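# Methods

`stquant` quantifies regional, cell-type/state-specific expression changes
across multi-slide Visium studies of the mouse brain. This note documents
the models and procedures it implements, the defaults and why, what the
synthetic generator does and does not emulate, and the numerical choices
made where the design was open.

## Data model

A *spot* is the capture unit of barcode-based spatial transcriptomics
(~55 µm in Visium, a mixture of roughly 2–10 cells); a *slide* is one
capture area holding one tissue section from one mouse. Counts are stored
sparsely as (spot, gene); on disk the standard 10x triplet (genes × spots
MatrixMarket, barcodes, features) plus the Space Ranger spot-geometry table
is used, accepting both the headerless (`tissue_positions_list.csv`) and
headered (`tissue_positions.csv`) dialects and writing the headerless one.
Studies are assembled on the gene intersection across slides (a `union`
policy with zero-fill is available); out-of-tissue spots are dropped at
assembly, since only in-tissue spots carry expression to analyze.

## Normalization and feature selection

Counts are log-normalized per spot: `log1p(count / total × 10,000)`.
Spots with zero total stay all-zero and are flagged; they are excluded from
embedding and clustering. The `expm1` row sums of a normalized spot
reconstruct the scale factor exactly, which the test suite asserts to
1e-8.

Highly variable genes use the variance-stabilizing-transform criterion:
per-gene raw-count mean and variance on log10 scale, a lowess trend
(`frac = 0.3`, locally linear — the trend only needs to be smooth) fitted
over genes with nonzero variance, counts standardized by the trend-expected
sd with an upper clip at `sqrt(n_spots)`, and the variance of the clipped
standardized values as the ranking score. Integration features combine
per-slide HVG lists: genes sorted by the number of slides calling them
variable, ties broken by ascending median variability rank, then gene
order. Defaults: 2,000 HVGs per slide, 2,000 integration features.

Before embedding, each gene is regressed on the spot total count (ordinary
least squares — the data are already log scale), residuals centered,
scaled to unit variance (sample variance, ddof = 1) and clipped at ±10.
PCA keeps 30 components by default with a deterministic sign convention
(the largest-magnitude loading of each component is positive).

## Reciprocal-PCA integration

Slides from the reference condition (wild-type mice by default) are pooled
and never altered; every non-reference slide is corrected toward them.
For one query slide:

1. reference and query feature blocks are standardized per slide, then
   projected into each other's PCA space (reciprocal projection);
2. mutual nearest neighbors within `k_anchor = 5` in either projection are
   candidate anchor pairs, scored by shared-neighborhood overlap
   (`k_score = 30` neighbor lists, overlap fraction averaged over the two
   sides, in [0, 1]);
3. each anchored query spot retains its single closest pair (summed
   distance over both projections; ties to the lowest reference index).
   This makes the procedure an exact no-op on identical inputs — every
   retained anchor pairs equal-expression spots — which we treat as a
   correctness contract for a correction step;
4. each query spot's correction is the Gaussian-kernel weighted mean
   (bandwidth one third of the distance to its `k_weight = 100`-th nearest
   anchor, weights multiplied by anchor score) of its nearest anchors'
   (reference − query) differences in log-normalized feature space.

Queries are corrected independently against the pooled reference, in input
order. On a two-slide study with gene-wise log-normal batch factors
(sd 0.5) the correction removes ≈95% of the mean per-gene between-batch
difference on the features while clustering recovery of the planted
regions improves (the batch shift itself otherwise splits regions by
slide).

## Spot clustering and region naming

Clustering is shared-nearest-neighbor + Louvain: a kNN graph
(`k = 20`, self included) in PC space, Jaccard edge weights
`|N(i) ∩ N(j)| / |N(i) ∪ N(j)|` pruned below 1/15, and seeded Louvain
modularity optimization at resolution 0.15 — the granularity at which spot
clusters correspond to anatomical structures. Labels are relabeled by
descending cluster size. Cluster → region naming is explicit
configuration (many-to-one allowed, e.g. one cluster covering amygdala and
septal territory); unmapped clusters become `unassigned`. On synthetic
studies a majority-vote helper derives the map from ground truth, and
planted 9-region layouts are recovered with ARI ≥ 0.95.

## Marker panels

For a target cluster, candidates are ranked by one-vs-rest random-forest
importance (1,000 trees by default; experiments here use 100, which ranks
a planted marker first just as reliably at these sizes), the top 15
re-ranked by a binary specificity score
`1 − mean_c min(1, median_c / median_target)`, and every combination of
1..6 candidates evaluated as a conjunction of per-gene decision-stump
thresholds; the smallest combination within 1e-9 of the best F-beta
(β = 0.5, precision-weighted) wins, ties broken by candidate rank. The
exact scoring internals of published minimal-marker selectors differ
between releases; the definitions above are fixed as this package's
contract and are exercised against an exhaustive-search oracle.

Curation is configuration, replacing visual curation with reproducible
rules: blocklist patterns (`Rpl*`, `Rps*` — ribosomal genes mimic
lymphoid signatures in mixed-cell spots), explicit cross-expression maps
(e.g. removing microglial `Cx3cr1`/`Tyrobp` from a T/ILC panel), removal
of genes absent from the dataset, per-cell-type manual lists, and flagging
(not removal) of genes detected in more than half of all spots, whose
ubiquity suggests a non-specific distribution. Every removal keeps its
reason. Marker selection is intended for reference expression profiles
(cell-type-labeled scRNAseq-like data) where marker expression is close to
on/off per type; the recovery experiments therefore plant markers at fold
30 with NB size 10. At Visium-spot noise levels (size 2) single-spot
threshold classification caps F-beta near 0.9 for any selector — a
property of spot mixtures, not of the search.

## Signature scores and group comparison

The signature score of a gene set in a spot is the mean log-normalized
expression of the set minus the mean of pooled control genes: all genes are
split into 24 equal-frequency bins by dataset-wide mean expression and each
set gene draws 100 controls from its bin (without replacement; with, if the
bin is smaller), seeded. The score has expectation zero for a random set
and rises with the planted effect, monotonically in the effect size.

The statistical unit is the mouse: spot scores are averaged per
(mouse, region), groups compared per region with the two-sided Wilcoxon
rank-sum test — exact null distribution when `n_A + n_B ≤ 10` without
ties, normal approximation with tie correction otherwise — and Bonferroni
correction over the declared family (default: the regions tested per
signature; an explicit integer family is accepted and recorded). Exactness
is verified against full enumeration of rank assignments.

## Differential expression and overrepresentation

Per region, genes are modelled with a two-part hurdle on pooled spots:
logistic regression of detection (y > 0) and a Gaussian linear model of the
detected values, both on (group, centered CDR) where CDR is the fraction of
genes detected in the spot. The group effect is tested by a joint
likelihood-ratio chi-square, df = number of parts where the group term is
estimable (a part is degenerate when detection is constant, positives are
confined to one group, or fewer than 3 spots are positive). Separation in
the logistic part falls back to a ridge-stabilized fit (penalty 1e-4).
No empirical-Bayes variance shrinkage is applied by default. On null
synthetic data (200 spots, 2,000 genes) the LRT type-I error at 0.05 sits
near 0.055 and p-values pass a Kolmogorov–Smirnov uniformity check at the
1% level.

A gene is a DEG when FDR-adjusted p < 0.05 (Benjamini–Hochberg within
region), |logFC| > 0.25 on the natural-log normalized scale, and — the
abundance criterion — its detection fraction reaches 0.1 in at least one
group; mean raw counts per group are reported alongside. The abundance
rule is deliberately a simple detection-fraction guard: spot-level logFC
alone is unstable for barely-detected genes.

Overrepresentation of a gene set among DEGs uses the upper-tail
hypergeometric p with BH correction across terms, and reports the count
ratio (the term's proportion among DEGs over its proportion in the
universe) plus overlap genes, matching the dot-plot quantities
(overlap count, count ratio, adjusted p). Gene-set collections are
user-supplied GMT files; no ontology snapshot is bundled, since term
contents depend on database versions.

## Synthetic studies

The generator plants everything downstream stages must recover. Counts are
negative-binomial (gamma–Poisson, size r = 2 — Visium spot counts are
overdispersed cell mixtures) with mean
`L_spot × w / Σw`, `w = p_gene × θ_marker(region) × θ_effect(region, group)
× B(slide)`, so a spot's expected total equals its log-normal library size.
The region layout is deterministic given the spec — one "white matter"
strip plus equal-size concentric bands on a square lattice — so truth
labels are reproducible and recovery is measurable. Batch factors are
gene-wise log-normal per slide (sd 0.1 by default), applied before
sampling. Default conditions: 6 slides (= mice) per group × {WT, TG},
10 markers per region at fold 8, and one planted TG "reactive glia"
signature (10 genes, fold 4) in white matter. Scales: `tiny` (300
spots/slide, 500 genes, 4 regions), `small` (1,000 spots, 2,000 genes,
9 regions), `paper_like` (3,025 spots, 15,000 genes, 14 regions).

What the generator does not emulate: hexagonal spot geometry and boundary
bleed (segmentation is expression-driven, so lattice geometry is
immaterial), cell-level mixtures within spots, spatially smooth
within-region gradients, mitochondrial/ribosomal count structure, and
section-plane differences. Passing recovery tests therefore shows the
algorithms are correct and calibrated under the stated noise model, not
that real tissue yields these effect sizes.

## Experiment designs that isolate one stage

Two validation experiments deliberately deviate from the generator
defaults, for identifiability rather than convenience. The DE recovery
experiment plants no batch effect: per-slide batch shifts are genuine
spot-level expression differences confounded with group in a two-group
design, so with batch on, "false positives" would measure the design
confound rather than the test's error rate — batch removal is
integration's job, and DE consumes counts, not corrected features. The
marker recovery experiment uses reference-profile-like noise (fold 30,
size 10) as argued above.

## Pipeline and determinism

The pipeline (simulate/ingest → normalize → integrate → cluster → score →
compare, optionally → DE → ORA) runs from one YAML config with one seed,
expanded into per-stage seeds by SHA-256 of `"{seed}:{stage}"` (mod 2^31),
so stages are independently reproducible. Unknown config keys fail
validation before any computation. Every artifact gets a JSON sidecar with
parameters, stage seed and SHA-256 checksum; identical config + seed
reproduces identical checksums, which the suite asserts. Stage outputs are
never mutated by later stages. Caching of disabled stages is not
implemented; DE/ORA are optional stages toggled by their config blocks.

Problem sizes in the test suite and `scripts/acceptance.py` (tiny/small
scales, 20–100 replicate seeds, 100-tree forests) are the package's chosen
desk-scale defaults; all are parameters, and `paper_like` scale is
generated on demand.

## Known limitations

- The hurdle LRT relies on chi-square asymptotics; with very few positive
  spots per gene the continuous part is skipped rather than corrected.
- Anchor correction assumes shared region composition between reference
  and query; a query with regions absent from the reference will be pulled
  toward its nearest reference regions.
- Bonferroni families must be declared; pooling coronal and sagittal
  sections into one family is the caller's choice and is recorded, not
  inferred.
- Region naming against a real atlas is out of scope; the package takes a
  cluster → name map as configuration.
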