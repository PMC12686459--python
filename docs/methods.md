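# Methods

This note documents the models implemented in `myeloniche`, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical decisions made where the design was open.

## Quality control and normalization

Cells are removed when they express fewer than 150 genes or when more than
25% of their counts map to mitochondrial genes (symbol prefixes `MT-` /
`mt-`; the prefix convention is configurable). Genes detected in fewer than
3 cells are removed. Spots are removed when their total counts fall below
2,500 or above 75,000. All thresholds use strict inequalities: a value
exactly at a threshold is retained. Filters run cells-first, then genes,
so gene detection counts reflect the retained cells; both filters are
idempotent.

Normalization scales each cell to a common total (default: the median of
per-cell totals) and applies natural log1p; zeros stay zero and within-cell
expression ranks are preserved. Highly variable genes are selected on the
exponentiated values: per-gene dispersion (variance/mean) is z-scored
inside 20 mean-quantile bins, and genes inside an open mean window with
normalized dispersion above 0.5 are kept. These cutoffs are free
parameters — there is no single canonical value — and the defaults are the
common ones for this binned-dispersion procedure. Normalization and HVG
selection are delegated to scanpy's `normalize_total`/`log1p` and
seurat-flavor `highly_variable_genes`, wrapped behind this module's
contracts.

## Marker discovery and ranking

Per subtype, every gene is tested one-vs-rest with a two-sided Wilcoxon
rank-sum test on log-normalized values (normal approximation with tie
correction, no continuity correction); constant genes get p = 1 and zero
fold change. The fold change is

    log2FC = log2((expm1(mean_in) + 1e-9) / (expm1(mean_out) + 1e-9)),

with means on the log scale — the convention of the single-cell DE
ecosystem this mirrors. Benjamini–Hochberg correction runs across all
tested genes. Candidates are filtered by symbol prefix (`RPS`, `RPL`,
`MRPS`, `MRPL`, `MT-`) and by within-cluster detection below 10% (strictly
below), then ranked by

    ranking = (−ln p_adj) × log2FC.

Natural log is used (the base is a convention; it rescales all rankings
monotonically) and `p_adj` is floored at 1e-300 to keep the score finite
when the test underflows. Ties break by smaller adjusted p, then gene
symbol, so the ordering is deterministic. Signatures are the top-n genes
(n = 30 for subtype validation signatures, n = 10 for survival
signatures).

One-vs-rest testing is assumed throughout; pairwise designs are out of
scope.

## Gene-set scoring

**Rank-AUC.** For each cell, all G genes are ranked by expression,
descending, with ties broken by a random permutation drawn once per run
from the seed (index-order tie-breaking would systematically favor early
genes in sparse data). With L = ceil(top_frac · G), the recovery curve at
rank r counts the gene-set members among the top r genes; the score is the
rectangle-rule area of that curve over r = 1..L divided by the maximal
area, achieved when all members occupy the top ranks. Scores therefore lie
in [0, 1], depend only on ranks (invariant to monotone transforms of a
cell's values), and equal 1/0 in the saturated/empty cases. `top_frac`
defaults to 0.05; the appropriate fraction depends on how many informative
genes the matrix carries, so it is exposed as a parameter, as is the gene
universe (full matrix vs HVG-restricted).

**Bin-matched control.** Genes are binned into 25 bins by average
expression; each set gene draws 50 control genes from its bin without
replacement (with replacement, and a warning, only when the set exhausts a
bin). The score is mean set expression minus mean control expression per
cell, so a random set scores ≈ 0.

**Maturation score.** Late-program rank-AUC minus early-program rank-AUC
per cell, in [−1, 1]; group-level summaries report per-subtype means and
their cross-subtype mean as the reference level. On a simulated 1,000-cell
gradient with fold-8 marker programs this score tracks true pseudotime at
Spearman ρ ≈ 0.96.

## Deconvolution

The reference is the per-subtype mean of expm1 log-normalized expression
(subtypes × genes); subtypes need at least 2 cells. Restricting the
reference to the union of top marker sets is supported and recommended to
reduce collinearity between subtype profiles. An optional prefilter drops
genes detected in fewer than 50 cells.

Each sample is decomposed by nonnegative least squares: genes intersected,
sample and reference profiles scaled to unit totals for conditioning, NNLS
solved, coefficients divided by the profile scale factors, clipped at zero
and normalized to sum one. The unscaling step is what makes the estimates
cell-type proportions in the mixture model `bulk = Σ p_k · profile_k` even
when profiles differ in total mRNA content; without it the estimates would
be mRNA-mass fractions. The per-sample residual is the relative L2 misfit.
Estimates are invariant to positive scaling of the sample and equivariant
under permutation of reference rows. This estimator is a transparent
least-squares surrogate for heavier probabilistic deconvolution models: it
preserves the scientific object — a proportions matrix feeding
stratification and niche calling — without their hierarchical noise
models. Failed rows (all-zero, no shared genes) are dropped with a
warning, and a presence filter excludes samples whose estimated abundance
of the analyzed lineage is zero before stratification.

Under the packaged simulation (5 subtypes, 200 genes, Dirichlet(1)
mixtures, 5% multiplicative noise) the mean absolute proportion error is
≈ 0.004, and recovery is exact (≤ 1e-6) at zero noise.

## Spatial niche analysis

Colocalization is the Pearson correlation of subtype proportions across
spots, with two-sided p-values; constant columns are reported missing.

The abundance–signature rule requires two significances at α = 0.05: the
correlation p, and the spot-level signature p. The phrase "both p < 0.05"
admits two readings; the default here restricts the correlation to spots
where the signature itself is significant and then requires that restricted
correlation's p < 0.05, with an alternative mode (`restrict_spots=False`)
that correlates over all spots and demands every spot pass the signature
gate. Fewer than 3 qualifying spots marks the pair "insufficient", never
significant.

Region clustering is k-means (10 restarts, seeded) on the spot-proportion
rows. k-means was chosen over graph clustering because it is deterministic
given the seed and has no neighbor-graph hyperparameters; the number of
regions k is the analyst's choice. Pooling spots across slides is the
default; per-slide clustering is a matter of slicing the input.

Niche calling is relative: each cluster's mean of each target subtype
abundance and target signature is z-scored across clusters (population SD),
and clusters where every target reaches z ≥ z_min are returned. z_min
defaults to 1.0 — a niche is defined by being high in *all* its components
relative to other regions, not by an absolute abundance. The comparison
uses a 1e-9 floating guard because with k = 2 the high cluster's z is
exactly ±1 up to rounding.

The ligand–receptor score is the CellPhoneDB-style mean-product: mean
expm1 ligand expression in the sender subtype times mean expm1 receptor
expression in the receiver, with a label-permutation null and the add-one
permutation p-value `(1 + #{perm ≥ obs}) / (1 + n_perm)`. This is a
deliberately simple co-expression surrogate for mass-action interaction
models; it captures enrichment, not signaling-pathway aggregation.

## Cohort stratification and survival

Patients are correlated on their composition rows (Pearson by default,
Spearman available) and clustered agglomeratively on distance 1 − r with
complete linkage, cut at k strata. Median splits label a sample "high"
only when strictly above the median, so median-tied samples go "low" and
the split is deterministic. Signature splits sum the signature genes per
sample and cut at the median by default; the score histogram is returned
so an analyst can choose a numeric cutoff in a bimodal distribution.

Kaplan–Meier curves and the log-rank test are delegated to lifelines; KM
curves are reported as right-continuous steps at event times only. The
two-group Cox model is fit by Newton–Raphson on the Breslow partial
likelihood (single binary covariate), with Wald 95% CI and p-value.
Breslow ties were chosen as the simplest well-defined partial likelihood;
with continuous simulated times ties have measure zero and the Efron
difference is negligible (the test suite cross-checks against lifelines on
tie-free data). Non-convergence within 100 iterations and monotone
likelihood (|β| > 50, complete separation) raise errors rather than
returning unstable estimates. Across 200 simulated cohorts with true
HR = 2 (exponential event times, n = 500/group, light censoring), the point
estimate stays within [1.6, 2.5] and the 95% CI covers 2 in ≈ 95% of
replicates.

## Cross-species mapping

Ortholog translation expands many-to-many table entries and deduplicates
mouse symbols; unmapped genes are reported. Signatures are the top-30
ranked markers translated to mouse symbols and scored with the bin-control
method. For joint clustering, HVGs are computed per species, only
orthologous genes variable in both are kept, per-subtype average (expm1)
expression matrices are concatenated on the human-symbol axis (mouse
expression averaged over duplicated targets), each gene column is divided
by its median across subtypes — zero-median genes dropped, so retained
medians are exactly 1 — then log2(x+1) is applied and both axes are
clustered with correlation distance and average linkage. The median is
taken across subtype averages (not across cells) because the clustered
object is the average-expression matrix. The log base only rescales
distances monotonically.

## Synthetic data

The generators are pure functions of their configuration, including the
seed, and return ground truth alongside the data.

**Single cell.** Gene baselines are log-normal(0, 1) in mean counts;
counts are negative binomial via a gamma–Poisson mixture with a single
shared dispersion (default 0.4, variance = μ + 0.4μ²), per-cell library
factors log-normal(0, 0.3). Subtypes multiply their marker genes' means by
`marker_fold`; lineage cells with pseudotime t ~ U(0, 1) scale early
markers by 1 + (f−1)(1−t) and late markers by 1 + (f−1)t, so the programs
cross at t = 0.5. These defaults give per-gene mean counts of order 1 and
moderate overdispersion, typical of droplet scRNA-seq at shallow depth.
Planted effects use fold 8 throughout the recovery scenarios.

**Bulk.** Proportions are Dirichlet; expected expression is
`proportions @ reference` rescaled to the target depth with multiplicative
log-normal noise of the stated coefficient of variation (mean-one
correction applied). Counts are rounded to integers when noise is present;
at zero noise the exact expectation is returned so that linear recovery is
testable to machine precision.

**Spatial.** Spot compositions are Dirichlet with concentration 10 per
subtype in the background; inside a planted block the enriched subtypes'
weights are multiplied by the enrichment fold before sampling, and the
block's marker genes are additionally multiplied by the fold in expected
expression. Counts are Poisson given composition (spot-level aggregation
dilutes overdispersion). The background concentration of 10 per subtype
encodes moderate spot-to-spot composition variability (SD of a
combined two-subtype proportion ≈ 0.07): concentrated enough that a
planted block at fold 6 is a composition-distinct region — the structure
region clustering presumes — while still leaving the deconvolution and
clustering a nontrivial noise floor. At much looser concentrations the
background overlaps the niche composition and the planted "region" stops
being a region even in ground truth.

**Survival.** Event times are exponential with group-specific rates,
censoring exponential and independent; observed time is the minimum.

**Orthologs.** Mouse symbols are title-cased human symbols by default,
with configurable dropout (unmapped genes) and 2:1 duplications.

What the generators do *not* emulate: batch effects, doublets, ambient
RNA, gene–gene correlation beyond the subtype/lineage programs,
platform-specific spatial artifacts, non-proportional hazards, and
informative censoring. Passing recovery tests therefore demonstrates the
correctness and calibration of the algorithms under their assumed noise
models, not robustness to the full messiness of real tissue data.

## Problem sizes

The packaged tests and the acceptance script run at desk scale: simulations
of 600–1,000 cells × 1,000 genes, 100 bulk samples, a 32×32 spot grid and
200 survival replicates of 1,000 subjects. These sizes were chosen so every
recovery target has comfortable statistical margin while the whole suite
completes in seconds; all generators scale to larger configurations through
their config objects.

## Known limitations

- The Wilcoxon test uses the normal approximation; exact p-values at very
  small group sizes are out of scope (≥ 2 cells per side are required,
  ≥ 20/20 recommended).
- The deconvolution surrogate assumes a linear mixture on the reference's
  linear scale; it does not model subject-level variance or spatial priors.
- The Cox model covers exactly two groups with a binary covariate;
  multivariable and continuous-covariate models are out of scope.
- Niche calling is relative to the clustered regions; with k = 2 any
  two-sided difference yields |z| = 1, so the caller should be used with
  the k the analysis actually needs, not the minimal one.
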