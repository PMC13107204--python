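# Methods

This note describes the statistical models and procedures implemented in
`scisoqtl`, the choices made where the design was genuinely open, and what
the synthetic-data studies do and do not demonstrate.

## The problem

Single-cell long-read RNA-seq resolves full-length transcript isoforms per
cell, which makes it possible to map *isoform-level* cis-QTLs (isoQTLs):
variants associated with the expression of a specific isoform in a specific
cell type, rather than with a gene's total expression. The pipeline covers
the downstream analysis chain of such a study: transcript structural
annotation, pseudo-bulk aggregation, negative-binomial cis-QTL mapping with
permutation calibration, cross-cell-type effect harmonization,
colocalization with a second trait, and functional enrichment — all driven
by a synthetic cohort generator so every stage is testable without any
restricted data.

## Count model and cis scan

Pseudo-bulk counts (per-individual sums over a cell type's cells) are
modelled as NB2: y_i ~ NB(mu_i, alpha) with Var(y) = mu + alpha mu^2 and

    log mu_i = x_i' gamma + g_i beta + log L_i

where L_i is the individual's library size (row sum), x_i the covariates
(genotype PCs, elbow-selected expression PCs, one-hot batch, age) and g_i
the variant dosage in [0, 2]. Fitting alternates IRLS for the coefficients
with bounded maximum-likelihood updates of alpha; alpha is floored at 1e-8,
the Poisson limit. The fit agrees with a Poisson GLM oracle to < 1e-2 on
Poisson data and with `statsmodels`' NB GLM (at the fitted alpha) to 1e-4.

The cis scan tests every variant within +/- 1 Mb of the isoform's
strand-aware TSS (window inclusive at both ends; variants pre-filtered at
MAF >= 0.05 and imputation R2 >= 0.3). Each variant is scored with the
efficient score test against the covariate-only null fit — one NB fit per
isoform regardless of the variant count — and the lead (minimum-p) variant
is refit by Wald for its reported beta and SE. Score and Wald p agree
within an order of magnitude on moderately powered fits; in the far tail
they diverge, as expected for the two statistics.

## Permutation calibration and FDR

Isoform-level multiplicity over cis variants is corrected with the beta
approximation: the linkage between the genotype rows and the
(phenotype, covariate) rows is permuted jointly — preserving cis-LD among
variants and the covariate-phenotype structure — and the minimum nominal p
per permutation is recorded (1,000 permutations by default). A Beta(k, n)
distribution is fit to the minimum-p sample by maximum likelihood
(`scipy.stats.beta.fit` with location/scale pinned; method-of-moments
fallback), and the adjusted p is the Beta CDF at the observed minimum.
Because the null fit is invariant under the joint permutation, the permuted
scans reuse cached score-state vectors and run as a handful of matrix
products per isoform.

Genome-wide FDR uses the Storey q-value procedure: pi0 from the lambda-grid
estimator with a cubic trend evaluated at lambda = 0.95 (single-lambda 0.5
below 100 tests), q-values by the usual step-up. Per-isoform nominal
thresholds invert each isoform's Beta CDF at the adjusted p whose q-value
is closest to the FDR level.

Two audits accompany the scan. The type-I audit shuffles each isoform's
counts across individuals independently, reruns scan + calibration, and
reports pi0 and the fraction of isoforms with adjusted p < 1e-5. The
one-locus oracle check compares the Beta-adjusted p with the direct
empirical permutation p, both at 10,000 permutations; the gap is measured
in SEs of the *difference* (binomial SE of the empirical estimate plus the
delta-method SE of the Beta-MLE CDF), since both sides are Monte-Carlo
estimates of the same quantity.

## Differential isoform expression

One-vs-rest DE treats each (individual, cell type) pseudo-bulk vector as a
sample and fits, per isoform, the same NB engine with a group indicator and
log library-size offset; log2FC = beta / ln 2, Wald p, BH across isoforms,
and a DEI requires log2FC > 1 (strict) and adjusted p < 0.05. No fold-change
shrinkage is applied. The permutation audit shuffles cell-type labels,
recomputes significance (adjusted p < 0.05, no fold gate) 1,000 times, and
flags isoforms significant in strictly more than 50 permutations. For speed
the audit uses the NB score test against each isoform's label-free null
fit, which is permutation-invariant and asymptotically equivalent to the
Wald test used for reporting.

Because the offset is the raw library sum, a large planted fraction of
DE isoforms induces composition bias (the offset absorbs part of the fold
change); the DE recovery study therefore plants 4-fold changes on ~5% of
isoforms, keeping the bias below 0.2 on the log2 scale.

## Cross-cell-type sharing

Lead-pair effects are harmonized on the z-score scale (the EZ
parameterization): z = b + e, e ~ N(0, V) with V the null correlation among
cell types, estimated from a random (mostly null) set of pairs restricted
to max |z| < 2 and shrunk 10% toward the identity. The prior on b is a
mixture of zero-mean normals over a canonical covariance set — identity,
per-cell-type singletons, equal-effects — on the scale grid
{0.25, 0.5, 1, 2, 4, 8}, plus a point mass at zero; mixture weights are fit
by EM (weights only; component shapes fixed). The data-driven covariance
step of the full multivariate adaptive shrinkage machinery is deliberately
omitted: the canonical set keeps the model testable at desk scale and the
reported quantity — the sharing classification — has the same form.
Untested (isoform, cell type) entries are imputed as z = 0 with SE 1 and
masked.

Posterior means and the local false sign rate (lfsr) follow from the
conjugate component posteriors; point-mass coordinates contribute their
responsibility to both sign tails, so a fully null posterior has lfsr near
1 (a z = 0 row under a purely continuous symmetric component has lfsr
exactly 0.5). Posterior effects on the beta scale are posterior z times the
reported SE. Sharing at an lfsr cut of 0.05: the top cell type has the
largest |posterior effect| among significant entries; a cell type is shared
by magnitude if significant, same sign as top, and within a factor of two;
shared by sign if significant and same sign; a pair is cell-type-specific
when exactly one cell type is shared by magnitude. The pairwise sharing
matrix counts, among pairs significant in at least one of two cell types,
those with same sign and effect ratio within the fold factor.

## Colocalization

Per variant, the Wakefield log approximate Bayes factor is
lABF = 1/2 log(1-r) + r z^2 / 2 with r = W/(V+W), V = SE^2 and prior effect
SD 0.15 for quantitative traits (0.2 on the log-odds scale for case-control
inputs) — the cited method's conventional defaults. When a summary table
carries only p, allele frequency f and sample size N, the sampling variance
is reconstructed as V ~ 1/(2 N f (1-f)) and z from the two-sided p. Locus
posteriors over H0..H4 use the standard configuration sums with priors
p1 = p2 = 1e-4, p12 = 1e-5, accumulated in log space; the implementation
matches brute-force enumeration of causal configurations to 1e-10.
Allele alignment intersects on (chrom, pos), flips strand-unambiguous
swaps, and drops A/T and C/G ambiguous variants.

## Annotation

Structural categories compare ordered intron chains: FSM (chain equals a
reference chain), ISM (contiguous sub-chain), NNC (any donor or acceptor
absent from the gene's reference site sets), NIC otherwise. Mono-exon
candidates are FSM when contained in a mono-exon reference, else "other";
the finer mono-exon taxonomy plays no role in the analyses and is omitted.
NMD sensitivity uses the 50-nt rule in spliced coordinates: the distance
from the last base of the stop codon to the first base 3' of the last
junction must be at least 50 (the rule's boundary is tested at 49 vs 50).
Whether the distance should exclude the stop codon itself is not fixed by
the rule's usual statements; measuring from the stop's last base is the
convention adopted here. AS events between isoform pairs are geometric
calls (SE, RI, A3, A5, AF, AL, MX) with A5/A3 distinguished from AF/AL by
whether the alternative flanking exons overlap. Splice-junction-site
windows are the first and last 2 bp of every distinct intron. Canonical
junction dinucleotides (GT-AG, GC-AG, AT-AC) are annotated only when a
genome sequence is supplied; otherwise the field stays null and no
canonical filter applies.

## Cell calling and pseudo-bulking

Cell calling takes the P-th percentile (linear interpolation; the
interpolation rule is not fixed by the procedure's usual description) of
per-barcode UMI totals divided by 10 as the cutoff; the percentile is
calibrated per batch against an external expected cell count by choosing
the candidate in 95..99 whose called count is the smallest one exceeding
the reference (falling back, with a warning, to the maximum count when none
exceeds). Pseudo-bulking keeps individuals with strictly more than 5 cells
of the type and isoforms expressed by strictly more than 20% of retained
individuals (so 31 individuals require at least 7 expressing). Expression
covariates are PCs of the log1p count-per-median-library standardized
matrix, with K chosen by the scree elbow (maximum perpendicular distance to
the chord from first to last eigenvalue) and additionally capped at one
tenth of the cohort size: on desk-scale cohorts a flat scree can push the
elbow to K comparable to n, which destabilizes the NB fits and absorbs
genotype effects.

## The synthetic cohort generator

Genotypes are Hardy-Weinberg draws in LD blocks (block members copy the
founder haplotype, resampling each copy with a flip probability, so
r^2 ~ (1 - flip)^2; flip 0 gives r^2 = 1). Transcript models are multi-exon
canonical forms plus designed variants (exon skipping, 5' truncation,
shifted donors, intron retention, alternative first exons) whose structural
category is known by construction, with CDS placed to hit a configurable
NMD-sensitive fraction. Cells draw NB counts with mean
s_c * b_batch * mu_(g,t) * w_(iso,t) * exp(beta * dosage): lognormal cell
size factors (sigma 0.3), multiplicative lognormal batch effects shared
across isoforms (sigma 0.2 — batch magnitude is a free choice, exposed in
the design), Dirichlet usage weights per cell type, common simulation
dispersion 0.5 (overdispersed but estimable at pseudo-bulk depth), ~20
cells per individual per type, batches of 6 individuals. Planted effects
are cell-type-specific, shared, or reciprocal (the partner isoform's usage
moves oppositely with the pair's total mean preserved — the mechanism
behind multi-isoform splice-site QTLs). One causal variant per planted
effect matches the single-causal-variant assumption of the colocalization
model.

What the generator does not emulate: read-level errors, ambient RNA,
doublets, cell-type misassignment, zero-inflation beyond NB sampling, and
realistic LD beyond block structure. Passing recovery and calibration
studies therefore demonstrate correctness of the statistical machinery
under the stated generative model, not robustness to those artefacts.

## Benchmark studies and problem sizes

The studies in `scisoqtl.studies` fix desk-scale conditions: the null
calibration cohort has 50 individuals, 200 isoforms and 500 cis variants
with 1,000 permutations per isoform; planted recovery uses 100 individuals,
causal MAF ~0.3 and |beta| = 0.8 with alternating sign; colocalization
simulates 20 shared and 20 distinct-causal loci of 80 variants at 100
individuals per trait with variance-standardized phenotypes; sharing
classification draws 200 lead pairs over 5 cell types at |beta| = 0.8 and
lead SE 0.15 (the z magnitudes the recovery study produces), simulating
z-tables directly since that is the harmonization's input surface; DE
recovery plants 4-fold isoforms in a 30-individual, two-cell-type cohort
and audits a matched null cohort. `scripts/acceptance.py` reruns all of
them from scratch and writes the headline numbers as JSON.

## Known limitations

- The score test can be anti-conservative on very sparse isoforms; the
  beta calibration absorbs this into the adjusted p (the type-I audit
  verifies it), at some cost in power. A consequence is that the
  permutation-calibrated linear mode — whose min-p permutation tail is
  lighter — is a strong baseline: nothing in this machinery guarantees the
  NB mode a higher discovery yield, only a better-specified count model
  for effect sizes and offsets.
- No conditional/stepwise secondary-signal mapping, trans-QTLs or
  allele-specific analyses.
- The EZ mixture's canonical covariances cannot represent arbitrary
  cell-type effect correlations; lineage-structured sharing is captured
  only through the null correlation V and the equal-effects component.
- Coloc assumes a single causal variant per locus per trait; multi-causal
  fine-mapping is out of scope.
- The DE engine uses raw library-size offsets, not median-of-ratios size
  factors, so strong compositional shifts bias fold changes.
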