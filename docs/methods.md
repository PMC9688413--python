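# Methods

This note documents the models, statistics and numerical choices behind
`sclc_taxonomy`, a re-usable implementation of a small-cell lung cancer
(SCLC) molecular-subtyping workflow: unsupervised subtype discovery by
consensus non-negative matrix factorization (NMF), subtype characterisation
by single-sample gene-set scores and co-expression regulons, supervised
cross-cohort classification, four-cell-type deconvolution with
tumor-intrinsic mesenchymal/inflamed (M/I) scores, neuroendocrine (NE) →
non-NE trajectory analysis, and survival / immunohistochemistry (IHC)
statistics. Everything is exercised end-to-end on synthetic cohorts with
known ground truth; what the tests demonstrate is therefore parameter
*recovery* under the generator's assumptions, not performance on real
tumors.

## The synthetic cohort generator

`synthetic.generate_cohort` emulates a bulk RNA-seq cohort of six SCLC
subtypes — SCLC-M (mesenchymal, YAP/TAZ-driven EMT), SCLC-I (inflamed),
SCLC-A/-P/-N (ASCL1-, POU2F3-, NEUROD1-driven) and SCLC-H (hypoxic) — with
default prevalences (6, 20, 28, 16, 23, 7)%, matching the minority-M /
common-A pattern of published primary cohorts.

Each sample is a four-cell-type mixture (epithelial, fibroblast,
endothelial, immune). Mixing fractions are Dirichlet with subtype-specific
parameters: the inflamed subtype carries the largest immune prior, the
mesenchymal and inflamed subtypes share the same fibroblast prior (stromal
content comparable between M and I is a deliberate feature: M must be
separable from I by tumor-intrinsic EMT, not by fibroblast content), and
concentration parameters are large (sums ≈ 150) so that tumors are
high-purity with modest compositional spread.

Tumor epithelial expression (log2 scale) is built from:

- a per-gene baseline shared across cell types (Normal(3, 1.2));
- a 40-gene subtype program elevated by `program_effect` (default 3 log2
  units ≈ 8-fold) in that subtype's epithelial cells;
- a continuous NE→non-NE axis: a 40-gene NE program whose expression falls,
  and a 40-gene non-NE program plus the EMT program whose expression rises,
  along a latent position in [0, 1] (`ne_effect`, default 1.5). Samples sit
  near subtype-typical anchors (A 0.15, N 0.30, I/H 0.50, P 0.70, M 0.85)
  with a small jitter (sd 0.015);
- a weak epithelial-intrinsic immune program in inflamed tumors
  (`epi_immune_effect`, 1 log2 unit) on top of the strong immune-cell
  contribution — the inflamed phenotype is carried by both the
  microenvironment and a tumor-cell component;
- six subtype-independent background co-expression modules (25 housekeeping
  genes each, per-sample activity sd 0.2) emulating pathway heterogeneity;
- small per-program activity jitter (sd 0.05) and per-gene/sample biological
  noise (sd 0.15).

Counts are negative-binomial around the length-weighted mixture expectation
(dispersion size 40, i.e. mild overdispersion typical of well-powered bulk
RNA-seq; `noise_dispersion=inf` gives the Poisson limit) with lognormal
library sizes (mean 2M reads, CV 0.2). Survival is exponential with
subtype hazards — mesenchymal 1/5 and hypoxic 1/6 events per month against
1/14–1/20 for the other subtypes — under independent uniform(12, 60)-month
censoring; the contrast is calibrated so the planted "worse outcome for
M/H" property is detectable by a six-group log-rank test at n = 200 with
power ≥ 0.9, mirroring the pronounced survival separation the subtyping is
supposed to reveal. IHC records couple vimentin positivity (95% in M, 50%
in I, 8% elsewhere) and CD8+ TIL field counts (Poisson means 5 / 30 / 12
for M / I / others) to the subtype.

The generator returns the full ground truth (labels, fractions, NE
positions, program gene sets, noise-free expectations) so every downstream
method can be tested as a recovery experiment. Features of real data that
are *not* modelled: batch effects, gene-length biases beyond the TPM
formula, isoform structure, doublets/ambient RNA in the single-cell arm,
and any spatial organisation.

The mouse-like time course (`generate_mouse_timecourse`) draws cells at six
culture ages (days 4–21) whose latent positions advance stochastically with
the day label (anchor + Normal(0, 0.12) jitter). Over the genes shared with
the human cohort, NE-program means decrease and non-NE/EMT-program means
increase linearly in latent time with amplitude `gradient_sharpness`
(default 2 log2 units); UMI counts are Poisson draws at ~5k per cell. Both
species therefore express the same NE→non-NE axis over the same gene sets,
which is what the cross-species concordance analysis assumes.

## Normalisation

Counts are converted to transcripts per million using per-gene lengths
(`TPM_g = 1e6·(c_g/l_g)/Σ(c/l)`; scale-invariant in the length unit) and
log2(TPM + 1) transformed. The pseudocount of one keeps the matrix
non-negative, as NMF requires, and maps zero counts to exactly zero.
Unsupervised feature selection retains the genes with largest median
absolute deviation across samples, ties broken by gene id.

## Consensus NMF and rank selection

The factorization V ≈ WH minimises the generalized Kullback–Leibler
divergence by multiplicative updates. Each fit starts from a
k-means-seeded initialisation — W seeded with the cluster means of the
sample partition found by k-means (single k-means++ start) on
gene-standardised profiles, H with the corresponding soft memberships — an
established NMF initialisation that places the updates in a partition-shaped
basin; the remaining restarts (3 total by default) are random, and the best
final objective is kept. Purely random multiplicative updates on these data
frequently stall in local minima that split one subtype and merge two
others; the k-means seeding removes that failure mode while the per-run
randomness (one k-means++ start per subsample) preserves the run-to-run
variability that consensus clustering measures. W columns are rescaled to
unit L1 with compensation in H; labels are the argmax metagene per sample.

Cluster stability at each K is measured by consensus over random *gene*
subsamples (all samples retained, so the consensus is over a fixed sample
set). The subsample fraction defaults to 0.65: with larger fractions the
gene subsets overlap so heavily that alternative merge/split configurations
at the wrong rank stop varying between runs, and the stability curve loses
its ability to discriminate rank; 0.65 restores that contrast at this
matrix size while leaving the true-rank partition untouched.

The cophenetic correlation coefficient of each consensus matrix (Pearson
correlation between the consensus dissimilarities 1 − C and the cophenetic
distances of their average-linkage dendrogram) summarises how tree-like the
consensus is. A permutation null — every gene's values shuffled
independently across samples, which preserves gene marginals but destroys
sample structure — is re-run through the same consensus machinery (10
subsamples and one restart per permutation; the null needs the location of
the cophenetic distribution, not a high-precision consensus) to give a
5th–95th percentile band per K.

Rank selection takes the largest K whose cophenetic score clears the null
95th percentile and is followed by a drop of at least 0.02 (the default
operationalisation of a "substantial drop"); when no K qualifies — on
cohorts this size the curve saturates near 1 and per-K differences are in
the third decimal — the rule falls back to the argmax of the curve. On the
default cohort the planted K = 6 is the unique argmax because only the
true partition is reproduced essentially perfectly across subsamples.
Metagene gene lists z-score each gene's W row across the K metagenes and
rank by the target column's z, so ubiquitously abundant genes do not
crowd out subtype-specific ones.

## Single-sample scores

ssGSEA follows the rank-weighted running-sum form: genes ranked by
expression (average ranks on ties), score = Σ over the ranked list of the
difference between the rank^α-weighted in-set ECDF and the unweighted
out-set ECDF, α = 0.25, with no cross-sample normalisation. Being
rank-based, scores are invariant under strictly increasing transforms of a
profile. Marker-mean scores (used for MCPcounter-style abundances) are
plain means over present markers. The NE score of a sample is
(r_NE − r_nonNE)/2, the contrast of Pearson correlations between the
sample's signature-gene vector and NE / non-NE prototype vectors; prototypes
are computed as mean expression of labelled NE-like and non-NE-like groups
(a config hook accepts externally supplied prototypes or gene lists).

## Regulons

A deliberately simplified ARACNe-style procedure (the original adaptive
partitioning and bootstrap consensus are not re-implemented): mutual
information between each candidate regulator and every gene by a plug-in
estimator on equal-frequency bins (floor(sqrt(n/5)) bins clamped to
[2, 10]); a permutation null of shuffled pairs sets the retention threshold
at the (1 − q) quantile (q = 0.05); the data-processing inequality then
removes the weakest edge of any MI triangle (tolerance 0, evaluated on the
input graph, hence idempotent). Subtype association of a regulon is the
one-sided Fisher exact test (hypergeometric upper tail) of the overlap
between the subtype's top-100 metagene genes and the regulon's targets,
reported as −log10 p. No activation/repression signing is attempted.

## Classifier

Nearest-shrunken-centroids: standardised class-centroid deviations
d_ik = (x̄_ik − x̄_i)/(m_k(s_i + s0)) with m_k = sqrt(1/n_k − 1/n) and
s0 = median(s_i), soft-thresholded by Δ; Δ is chosen by stratified
cross-validation (up to 10 folds, bounded by the smallest class; 30-point
grid from 0 to max|d|), ties resolved toward the largest Δ (fewest genes).
Prediction minimises δ_k(x) = Σ_i (x_i − c̄'_ik)²/(s_i + s0)² − 2 log π_k
with uniform priors by default (cohort prevalences differ between cohorts);
softmax(−δ/2) gives soft calls. Cross-cohort application median-shifts each
gene onto the training scale — a minimal harmonisation; no further batch
correction is attempted. Missing model genes are imputed at the overall
centroid and an error is raised when more than half are missing.

## Deconvolution and tumor-intrinsic scores

All mixture arithmetic is done on linear TPM, where cell-type mixing is
additive; logs are taken only after purification. Per-sample fractions are
non-negative least squares of the bulk profile on the four signature
columns over signature genes, renormalised to the simplex. Per-group
cell-type profiles solve, gene by gene, NNLS of across-sample bulk values
on the samples × 4 fraction design (constant fraction columns are dropped
with a warning). The per-sample epithelial profile uses residual
attribution, ê_gs = max(0, P_g,epi + w_s·r_gs) with w_s = f_epi/Σ_c f_c² —
a documented approximation chosen because downstream trajectory analysis
only needs a per-sample estimate that preserves expression gradients;
samples with epithelial fraction < 0.05 are flagged low-confidence.

Differential expression between deconvoluted epithelial groups uses Welch's
t with Benjamini–Hochberg FDR; the classifier lists are the top 50 genes up
in each direction (100 total). M and I scores are mean log2 expression over
the respective lists (raw, not z-scored; a config toggle switches) and the
differential score is exactly M − I. Gene–score association uses Pearson r
with a two-sided t-based p. Gene-set enrichment of a ranked statistic
vector uses the classic weighted Kolmogorov–Smirnov running sum with a
gene-set-permutation p-value (add-one estimate, two-sided on |ES|).

## Trajectory and cross-species concordance

Pseudotime: genes standardised, units embedded by PCA (3 components), and a
principal curve fitted by projection-index iteration — running-mean
smoothing of the embedding along the current ordering (window 30% of the
units) alternated with re-projection onto the smoothed polyline, to
convergence of the ordering (≤ 10 iterations). Pseudotime is the
normalised rank of arc-length position; the orientation is flipped whenever
it correlates positively with the NE score, so the NE→non-NE transition
always runs forward. Only the ordering is consumed downstream; no branch
structure is modelled.

Cross-species concordance restricts both matrices to ortholog-shared genes
(explicit two-column map; ≥ 50 shared genes required), standardises each
unit's vector, and reports all pairwise Pearson correlations with both axes
sorted by pseudotime. Mouse matrices are depth-normalised (counts per 10k,
log1p) first. Subtype occurrence along pseudotime is a per-bin frequency
table plus per-subtype median pseudotime; marker trends are centred
running averages of marker-set means along pseudotime (full-window =
global mean), summarised by Spearman rho.

## Clinical statistics

Kaplan–Meier estimation and the k-group log-rank test are delegated to
lifelines (validated in the tests against hand product-limit computation
and a hand-computed observed-vs-expected table). The H-score is percent
positive tumor cells × staining intensity (0–300); the CD8+ TIL score is
the mean of five high-power-field counts. Mann–Whitney U uses midrank
ties, exact enumeration when the combined n ≤ 12 without ties and the
tie-corrected normal approximation otherwise. The IHC call: any vimentin
positivity (H-score > 0) makes a tumor vimentin-positive; among
vimentin-positive tumors, CD8 below the cutoff calls SCLC-M and at/above
calls SCLC-I; vimentin-negative tumors are "other". The default cutoff is
the median CD8 score of vimentin-positive tumors (no clinical constant is
invented; an absolute count can be supplied), and it is an error when all
vimentin-positive scores are identical.

## Problem sizes and determinism

The packaged analyses run at desk scale: the default cohort is 1000 genes ×
120 samples, consensus uses 50 subsamples per K and a 20-permutation null,
the time course 360–600 cells — sizes chosen so a full rank scan completes
in about a minute on one core while leaving every recovery contract
detectable. All randomness flows from integer seeds through hierarchical
`numpy` seed sequences, so every result in the test suite and the
acceptance script is bit-reproducible. One caveat is inherent to the
stability statistic at this scale: cophenetic scores live within a few
thousandths of 1.0 at every candidate rank, so rank selection effectively
resolves through the argmax fallback; the planted rank is recovered
reliably on the default cohort, but cohorts drawn at other generator seeds
occasionally hand the argmax to a neighbouring rank.
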