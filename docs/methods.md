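# Methods

This note records the statistical models implemented in eqtlkit, the
assumptions behind them, the defaults that matter, what the synthetic data
does and does not emulate, and the design choices made where more than one
reasonable implementation existed.

## Association and meta-analysis

Per cohort, a variant–gene pair is scored by Spearman correlation on
pairwise-complete (dosage, expression) observations; ties receive average
ranks. The two-sided p-value comes from the t approximation with n−2
degrees of freedom, and is mapped to a signed standard-normal z, capped at
|z| ≤ 40 to avoid infinite quantiles (the cap is recorded as a constant,
`meta.Z_CAP`). Cohorts below 30 usable samples, or with a constant vector,
are skipped for that pair.

Cohorts combine by the sample-size-weighted z-score:
z_meta = Σ √nᵢ zᵢ / √(Σ nᵢ). The summation is performed over a canonically
sorted cohort list with compensated (fsum) arithmetic, so permuting the
cohort order is exactly neutral. Rank-based per-cohort scoring makes the
meta-analysis insensitive to cohort-specific expression scale and monotone
batch distortions; it does not model between-cohort effect heterogeneity
(no random-effects variant is provided — a deliberate non-goal).

The z → (β, SE) reconstruction assumes a standardized phenotype and
Hardy–Weinberg-proportioned genotype variance 2f(1−f): d = √(2f(1−f)(n+z²)),
β = z/d, SE = 1/d. These are approximations for downstream consumers
(R_b, MR) rather than re-estimated regression coefficients.

Variant QC: joint MAF (sample-size-weighted mean of cohort MAFs) must
exceed 1%, the worst-cohort exact Hardy–Weinberg p must exceed 1e-4, and
worst-cohort missingness must not exceed the configured cap. The HWE test
is the exact conditional test (probabilities of heterozygote configurations
no more probable than observed, conditional on allele counts) computed in
exact integer arithmetic with a cached recurrence, so tie handling is exact
rather than float-rounded.

Cis pairs are variant–TSS distances ≤ 1 Mb on the same chromosome,
restricted to protein-coding genes by default, with signed distance
(negative = upstream on the gene's strand). Trans pairs are restricted to a
variant shortlist and require > 5 Mb distance or different chromosomes.

## Multiple testing

Gene-level cis significance follows the permutation/beta scheme: expression
sample labels are shuffled *within* each cohort (preserving
genotype-covariate structure; cross-cohort shuffles would break the
meta-analysis null), one permutation is shared across all of a gene's
variants, and the per-permutation minimum p is recorded. A Beta(a, b) is
fitted to the minima by maximum likelihood (method-of-moments start,
parameters clipped to a ∈ [0.1, 10], b ∈ [0.5, 10m]); the nominal top p is
adjusted through the fitted CDF, and Storey q-values (π₀ from a λ-grid with
a cubic-smoother extrapolation, BH-equivalent fallback below 20 genes) call
significance at q < 0.05.

Numerical choices worth knowing:

* Inside the permutation engine, missing dosages are mean-imputed per
  cohort once per gene, so the real and permuted scans see an identical
  design and the null is exactly exchangeable. The headline `run_scan`
  statistics remain pairwise-complete; the small discrepancy only matters
  at high missingness.
* Per-gene permutation streams are seeded from the master seed plus a CRC32
  hash of the gene id, making results independent of evaluation order.
* The default permutation depth is 100 (desk scale); 1,000 is the
  full-study setting and a direct argument everywhere.
* Calibration: across 1,000 null genes the adjusted p-values are uniform
  (KS p ≈ 0.36 in the test suite) with fitted shapes centered on (a = 1,
  b = m) for m independent variants. With 100 permutations the beta
  extrapolation below the permutation resolution is mildly anti-conservative
  (observed ~1.5–2× the nominal mass below p = 0.01); at 1,000 permutations
  this shrinks accordingly. A consequence spelled out in the test suite: with
  50 genes the probability that at least one null gene reaches q < 0.05 is
  about 5% per run even for a perfectly calibrated pipeline, so "zero
  significant genes" holds in roughly 19 of 20 runs, not always.

Trans significance uses the empirical permutation FDR over ten genome-wide
permutations of the identical pair set: FDR(t) = mean permuted discoveries
at p ≤ t over real discoveries, made monotone per record by taking the
minimum over thresholds at or above the record's p (q-value convention).

## Conditional mapping

Round 1 is the standard scan plus permutation MTC. Each later round
regresses all prior lead dosages (mean-imputed within cohort, collinear
leads at r² > 0.95 dropped) out of expression per cohort by OLS, re-scans,
and re-runs the permutation null on the residualized expression; a gene
stops once its within-round q ≥ 0.05 or the maximum rank (default 5) is
reached.

Design choice (an open point in the procedure): before each rescan the
candidate set drops variants with pooled r² > 0.2 to any prior lead. The
pruning exists to prevent cross-cohort missingness artifacts at variants in
LD with the conditioned leads; pruning the candidate set *against itself*
instead would remove good tags of genuinely independent secondary signals
and structurally cost power, so the lead-anchored form is used. A greedy
position-ordered `ld_prune` over an arbitrary variant set is also provided
and tested as a standalone tool. The lead-anchored pruning plus the
conditioning itself enforce that a rank-2 lead has r² < 0.2 with rank-1.

## Agreement metrics

Between a discovery and a replication summary set, after allele
harmonization (swapped ref/alt flips β; irreconcilable pairs are dropped
and counted):

* AC — % of both-significant records with matching effect sign (50% for
  unrelated effects).
* π₁ — Storey 1−π₀ over replication p-values of discovery-significant
  records; direction-blind and sample-size dependent.
* R_b — correlation of the underlying slopes corrected for estimation
  noise: var_true = var(β) − mean(SE²), cov_true = cov(β₁, β₂) −
  ρ_overlap·mean(SE₁·SE₂); SE by leave-one-out jackknife. ρ_overlap
  defaults to 0 (non-overlapping cohorts). When noise exceeds the slope
  variance the estimate is undefined and flagged rather than clipped.
* caFC — Pearson correlation of per-eQTL log₂ allelic fold changes. The
  aFC estimator is the homozygote-contrast approximation (mean log₂
  expression of alt- minus ref-homozygotes; slope-based fallback 2×slope
  when a homozygote class has < 3 samples; capped at |log₂ 100|). Exact
  nonlinear aFC model fitting is out of scope and every report carries that
  flag.

Both the discovery-significant and both-significant record sets are exposed
for R_b, since published comparisons are ambiguous about which is used.

## Deconvolution and interaction eQTLs

Proportions come from per-sample NNLS of the prepared expression on the
marker-gene signature, normalized to sum to one; subtype columns can be
summed into major types through a merge map, and map entries set to None
discard a signature column (e.g. developmental subtypes) with row
renormalization. Expression preparation is log₂(TPM+1), OLS removal of
technical covariates, rescaling of the residuals back to each gene's
original mean/SD (preserving the between-gene expression differences the
deconvolution relies on), and clamping of negatives to zero. Samples with a
per-cell-type proportion z-score > 4 are excluded before interaction
testing.

The interaction model for one eQTL is
y = Σ_c β_c P_c + Σ_c γ_c P_c G*_c with all coefficients ≥ 0, where G*_c is
either the dosage G or 2−G per cell type; the flip is how negative
interactions are expressed under the non-negativity constraint, and since
Σ_c P_c = 1 the main-effect terms absorb the intercept. Each cell type is
tested by a one-sided F-test of the full model against the model without
its interaction term, on (1, n − 2C) degrees of freedom.

Two choices stabilize this test:

* Expression is inverse-normal transformed per gene (Blom offsets,
  (rank−3/8)/(n+1/4)) and then mapped back to the gene's original mean and
  SD. A plain INT is mean-zero, which is degenerate under an
  all-non-negative model that must reproduce the gene's positive mean; the
  rescaled form keeps normality, positivity and the model well posed.
* The genotype is first oriented so that its correlation with expression is
  non-negative, making the fit exactly invariant to ref/alt relabeling; a
  greedy per-cell-type encoding pass then minimizes the full-model RSS, and
  the tested cell type's encoding is re-chosen at test time with the others
  fixed (ties keep G). Without the re-choice, large cell types sit at the
  γ = 0 boundary under the null and the p-value distribution develops an
  atom at 1; with it, the null p-values are uniform (verified per cell type
  in the suite) and, when no constraint is active, the F equals the
  unconstrained OLS ANOVA statistic to 1e-6.

Reported interaction effects are signed relative to the caller's dosage
allele. FDR over pooled (eQTL × cell type) tests is Benjamini–Hochberg by
default, with a permutation alternative that shuffles genotype against the
joint (expression, proportions).

## MR and colocalization

Instruments are cis associations at p < 5e-8, greedily LD-clumped by
ascending p (10,000 kb window, r² ≤ 0.001 against a reference dosage
panel). Instruments absent from the outcome GWAS may be replaced by their
best panel proxy at r² ≥ 0.8, with the eQTL effect re-read at the proxy.
Harmonization assumes forward-stranded GWAS records: swapped alleles negate
the GWAS β, strand complements are resolved, palindromic variants are
retained without frequency-based reorientation, and irreconcilable pairs
are dropped.

The Wald ratio is β_GWAS/β_eQTL with first-order delta SE |SE_GWAS/β_eQTL|
(the standard single-SNP MR practice; a second-order option adds the
exposure-error term). Instruments with exposure |β/SE| < 2 are flagged
weak. Reporting thresholds default to suggestive p < 5e-5 and Bonferroni
0.05 over the number of ratios actually tested; both are parameters because
the published thresholds for such analyses are not always exact Bonferroni
quotients.

Colocalization computes Wakefield log-ABFs per variant (prior effect SD
0.15 for quantitative traits, 0.2 for case-control) and the standard
five-hypothesis posterior in log space (log-sum-exp; safe beyond |z| = 50).
It runs under both the default priors (p1 = p2 = 1e-4, p12 = 1e-5) and
region-size priors (p1 = p2 = 1/Q, p12 = p1/10 for Q shared variants); a
locus colocalizes when either run gives PP4 > 0.7. Fewer than 10 shared
variants is flagged, zero is an error.

## Expression harmonization

TMM normalization is implemented directly: per-sample factors from the
doubly trimmed (30% on M, 5% on A), precision-weighted mean of log-ratios
against the highest-depth column, rescaled to geometric mean one; values are
reported per effective million. Technical covariates are ranked by their
maximum |Pearson r| against the first 10 expression PCs and the top 20
(configurable) are jointly regressed out per gene, dropping collinear
columns.

Two PCA flavors coexist deliberately. Sample *representation* (region
classification, outlier flagging) uses the eigendecomposition of the
sample×sample correlation matrix, with a deterministic sign convention and
iterative 4-SD outlier flagging on the first 4 PCs. Expression *correction*
(`pc_correct_expression`) regresses out PCs of the gene-centered expression
matrix (SVD, samples as observations): the correlation-matrix eigenvectors
are a saturating transform of any strong latent factor and leave a shared
nonlinear remainder across genes, whereas the centered-SVD PCs remove a
linear factor exactly. Region labels come from a k-nearest-neighbor vote
(k = 7) on the first two correlation-PCA scores, with ties broken by summed
inverse distance and then lexicographically. The number of PCs to remove
can be fixed or selected on a user-supplied objective over a grid
(0/25/50/100 by default).

## Synthetic data: what it emulates, and what it does not

Genotypes follow a haplotype-copy chain: within an LD block each haplotype
copies the previous variant's allele with probability 1−s, else redraws
from the block MAF, giving adjacent-variant r² ≈ (1−s)² and geometric decay
within blocks; blocks restart at chromosome boundaries. The toy genome is
two chromosomes at 50 kb per variant by default, so the 1 Mb cis window and
the 5 Mb trans rule are both exercised. Cohorts draw independently from a
shared panel (differing realized MAF), with per-cohort missingness and
random ref/alt bookkeeping swaps that a correct harmonization must undo.
GWAS populations are resampled from the same chain, so panel LD matches
GWAS LD exactly.

Expression is a non-negative signature mixture on marker genes
(proportions ~ Dirichlet), plus planted cis/trans slopes (`slope × dosage`),
interaction terms (`slope × dosage × proportion`), a per-cohort batch
covariate with per-gene loadings, and Gaussian noise. Defaults model three
cohorts of 300/200/100 samples, five brain cell types, and unit-SD noise.
Secondary planted variants are rejection-sampled to pooled r² < 0.05 with
the primary. Effect magnitudes are drawn around the configured SD but
bounded away from zero (at 30% of the SD), so "planted" never means
"undetectable in principle"; recovery fixtures in the acceptance tests plant
at fixed slopes and common MAF (0.2–0.5), because stated recovery rates for
a 0.3 slope at n = 600 presuppose a common allele (meta z ≈ 4.5 at MAF 0.4
versus ≈ 3 at MAF 0.1).

Not emulated: population structure and relatedness, imputation dosage
uncertainty, read-level count noise (expression is Gaussian around the
signal), multi-tissue sampling of the same donors, and sample swaps.
Passing tests therefore demonstrate the statistical machinery under clean
exchangeability assumptions; they do not certify behavior under stratified
or contaminated real data.

## Problem sizes used in the checks

The test suite runs desk-scale configurations chosen to keep every stage's
statistical claim measurable: 50-gene × 50-variant null batteries with 100
permutations across 20 seeds for MTC calibration, 600-sample two-cohort
studies for conditional recovery, n = 1,000 for interaction detection,
20-seed trans-FDR batteries, 10+10 shared/distinct loci for MR/coloc, and
the complete Hardy–Weinberg table enumeration to n = 200. The full suite
completes in a few minutes on one CPU.

## Known limitations

* Fixed-effects (weighted-z) combination only; heterogeneous cohort effects
  are averaged, not modeled.
* The β/SE reconstruction from z is approximate and inherits the
  standardized-phenotype assumption.
* The aFC estimator is a homozygote contrast, not the full nonlinear fit.
* Beta-adjusted p-values below the permutation resolution are
  extrapolations; at 100 permutations their far tail is mildly
  anti-conservative (quantified above).
* Decon-QTL-style interaction βs are attenuated by proportion collinearity
  and should be read as detection statistics, not unbiased effect sizes.
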