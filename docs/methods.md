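# Methods

`ricegs` implements a genomic-selection analysis pipeline for inbred,
structured diversity panels of the kind used in rice breeding: marker
selection (neutral LD-based and trait-specific GWAS-based), adjustment of
field-trial phenotypes, kernel-based genomic prediction in single and
multiple environments, and CV1/CV2 cross-validation with a Fisher-Z ANOVA of
predictive abilities.  This note records the models, the defaults and the
design choices that were genuinely open.

## Synthetic panel generator

The generator (`ricegs.simdata`) produces genotypes and phenotypes with the
statistical features the analysis relies on; it is first-class, tested code,
not a fixture.

**Genotypes.** Each of `n_subpops` (default 5) subpopulations owns a pool of
`pool_size` (default 6) ancestral haplotypes.  Subpopulation allele
frequencies drift from shared ancestral frequencies by a Balding–Nichols
model with Fst fixed at 0.1, which yields PCA-detectable structure comparable
to *indica*/*aus* subgroups.  An accession's haplotype is a Markov mosaic: at
each locus it keeps copying the same ancestral haplotype with probability
`ld_copy_prob` (default 0.95) and otherwise re-draws an ancestor according to
its admixture proportions (Dirichlet with concentration `admixture_conc`,
default 0.3).  Adjacent-locus r² therefore decays geometrically with
distance; the r² plateau at short range scales like the reciprocal of the
effective ancestor-pool size.  With the default 20 kb locus spacing the mean
r² halves over roughly 200–250 kb — decay over hundreds of kb at a low
absolute level, the regime of a low-LD rice panel at ~14 kb marker density.
A mosaic model was chosen over a coalescent simulation because the analysis
only needs tunable r² structure, not genealogies.

Accessions are fully inbred (one haplotype, dosage 0/2); residual
heterozygosity (default 1%) and missing calls (default 4%) are injected
completely at random — missingness can be uninformative because imputation
downstream is per-locus anyway.  Ancestral minor-allele frequencies follow a
low-skewed Beta rescaled to start 0.10 above `maf_floor`; the margin absorbs
drift and pool-sampling noise so that ≥95% of realized MAFs stay above the
floor (QC filtering handles the rest).  A consequence of that guard band is
that the simulated MAF spectrum is somewhat less rare-allele-heavy than a
real resequencing panel.

**Phenotypes.** `n_qtl` loci (default 100) receive additive effects drawn
from a multivariate normal across environments whose correlation matrix is
`genetic_corr`; this encodes G×E directly, and the realized correlation of
true genetic values matches the parameter up to effect-sampling error.  The
default matrix (0.71 / 0.68 / 0.58 between three environments) follows the
flowering-time pattern of a non-stress trial and two drought trials; a
yield-like trait is obtained by passing near-zero off-diagonals.  Plot values
add a block effect (variance = `block_var_ratio` × genetic variance, default
0.2) and a residual scaled so the plot-level H² matches `h2_target`.  Two
layouts are supported: an augmented design (test entries unreplicated,
checks in every block) and an alpha-lattice with two replications.  Checks
are fixed genotypes with their own true values and are not part of the
prediction set.

What the generator does **not** emulate: linkage between QTL effect size and
allele frequency, dominance/epistasis (except in dedicated test
constructions), spatial field trends, informative missingness, and real
haplotype sharing between subpopulations.  Passing tests therefore show that
the estimators behave correctly under the stated statistical structure, not
that any particular real dataset would give the same numbers.

## Genotype QC and imputation

Loci are filtered at missing rate ≤ 20%, MAF ≥ 2% and per-locus
heterozygosity ≤ 5% (all boundaries inclusive); later stages re-invoke the
same filter at stricter MAF where needed (e.g. 5% before GWAS).  Missing
dosages are imputed per locus by the observed mean (default; fractional
dosages) or mode (integer).  Haplotype-based imputation is deliberately out
of scope: at these marker densities and for kernel methods, per-locus
imputation is standard and removes an external-tool dependency.

## LD, pruning and decay

r² between unphased dosage columns is the squared Pearson correlation (the
composite estimator for unphased data); monomorphic columns are defined to
have r² = 0.  LD is computed within chromosomes only.  Pruning builds, per
chromosome, the graph with an edge wherever r² > `r2_max`; clusters are its
connected components.  This is the only reading of "single loci or clusters
of loci" under which keeping singletons plus one representative per cluster
guarantees every retained pair sits at or below the threshold — a guarantee
the test suite asserts directly.  The representative is the member with the
fewest pre-imputation missing calls, ties broken by highest MAF, remaining
ties uniformly at random under a seed.  A final MAF screen is applied to the
representatives.  Note that connected components percolate: once the r²
threshold drops near the panel's background LD, whole chromosomes collapse
into a handful of clusters and the kept set shrinks sharply, which mirrors
how a real 215k panel collapses to a few thousand SNPs at r² ≤ 0.25.

The decay curve bins within-chromosome pairs by physical distance and
reports mean and SD of r² per bin plus the distance at which the mean first
falls below half its first-bin value.

## Phenotype adjustment

Plot values are modeled as `Y = mu + C_j + beta_k + N_i * alpha_i + eps`
with fixed mean and check effects, random block and accession effects, and
`N_i` an indicator that is 1 for test entries and 0 for check plots, so
blocks are calibrated by the replicated checks.  The accession effect is a
main effect: with one plot per accession within a block, an
accession-within-block effect would be confounded with the residual.
Variance components are estimated by EM-REML (monotone in the restricted
log-likelihood; convergence at |Δ logL| < 1e-8, max 1000 iterations;
negative iterates floored at 1e-10).  EM approaches a zero-variance boundary
only geometrically, so noise-free inputs yield components that are small
rather than exactly zero.

The adjusted phenotype is `mu_hat + BLUP(alpha_i)` by default; a
block-corrected raw mean is available (`method="block_corrected"`) because
"the adjusted value of a genotype" does not by itself distinguish the two.
BLUP was chosen for consistency with the mixed model.  Broad-sense
heritability is `H² = sigma2_g / (sigma2_g + sigma2_e)` on a plot basis.
Published tables of this model family occasionally print H² values that
differ slightly from that ratio of their own printed components (apparently
including fixed-effect variance in the denominator); the stated formula is
what this package computes, and only the internally consistent rows are used
as worked examples.

## Kinship, structure and GWAS

The genomic relationship matrix is either the raw cross-product `M Mᵀ` or
the VanRaden form (columns centered by 2p̂, scaled by Σ2p̂(1−p̂); default),
symmetrized and diagonally jittered by 1e-8.  Structure covariates are the
first K−1 principal components of the centered dosage matrix — the standard
replacement for ancestry-coefficient matrices; five subpopulations map to
four components.

The association scan is a mixed linear model with kinship K and covariates
[1, Q].  Variance components are estimated once under the marker-free null
by REML on the eigendecomposition of K, then held fixed while each marker is
tested by generalized least squares (the P3D/EMMAX approximation, which is
what standard MLM implementations do and is orders of magnitude faster than
per-marker REML).  The residual *scale* is re-estimated per marker from the
whitened residuals, with the variance ratio fixed, and the marker
coefficient is tested by a two-sided t statistic; with K = I this reduces
exactly to per-marker ordinary least squares.  Markers collinear with the
covariates are flagged with p = 1.  Top-k selection takes the k smallest
p-values, ties broken by genomic position.  Inside cross-validation, GWAS is
always re-run on the training fold only, so marker selection never sees
validation accessions.

## Prediction models

*Single environment.*  GBLUP fits `y = mu + u + e`, `u ~ N(0, sigma2_u K)`
with the linear GRM; RKHS is the same machinery with a Gaussian kernel
`K_ij = exp(-h d²_ij)`, `d²` the squared Euclidean distance between dosage
rows divided by the locus count.  The default bandwidth is the reciprocal of
the median off-diagonal `d²`, a common single-kernel default; multi-kernel
averaging is out of scope.  Both are fitted by EM-REML in the eigenbasis of
the training kernel; genetic values of unphenotyped accessions are the
conditional-expectation extension `K_target,train V⁻¹ (y − mu)`.  GBLUP with
the raw cross-product kernel is algebraically a ridge regression on centered
markers with λ = σ²e/σ²u, and the test suite checks the two agree to 1e-6.

*Multi-environment.*  The marker-by-environment (M×E) decomposition models
the stacked records as environment intercepts plus a genetic main effect
`u0 ~ N(0, σ²0 K)` shared by all environments plus environment-specific
deviations `u_j ~ N(0, σ²j K)`.  The implied genetic correlation between any
two environments is σ²0/(σ²0+σ²j) under equal deviation variances.  With the
linear GRM this is M×E GBLUP; with the Gaussian kernel it is the G×E RKHS
model (a single shared bandwidth).  Sampling is Gibbs in the scaled
eigenbasis of K, with scaled-inverse-χ² priors (df 5, scales from the sample
variance with an R² split of 0.5, divided equally among the genetic terms —
the convention of the standard Bayesian regression packages in this field).
The Kronecker multi-trait model instead samples an unstructured environment
covariance Σ_G with genetic covariance Σ_G ⊗ K (inverse-Wishart prior,
df J+2, scale set to half the per-environment phenotypic variances on the
diagonal), diagonal per-environment residual variances, and data
augmentation for missing cells.  Residual covariance across environments is
fixed diagonal: the trials are physically separate experiments, and CV2's
information transfer should flow through genetics only.  Chains default to
25,000 iterations after 5,000 burn-in and are bit-reproducible under a seed;
tests and the acceptance checks use shorter chains (5,000/1,000 for
parameter recovery, 1,000/200 inside replicated cross-validation) — chosen
as the smallest lengths at which posterior summaries are stable across
seeds for problems of a few hundred accessions.

One caveat of the diagonal-residual assumption: in any single dataset, chance
cross-environment correlation of the residuals is attributed to Σ_G, so
genetic-correlation estimates are unbiased only on average over datasets.

## Cross-validation and comparison machinery

Partitions are uniform 80/20 splits (|train| = round(0.8 n): 224/56 at
n = 280, 163/41 at n = 204), derived replicate-by-replicate from a master
seed so the identical plan can be reused across traits, models and marker
modes.  Under CV1 the validation accessions contribute no phenotype from any
environment; under CV2 their helper-environment records are appended to the
training data (for two helpers, both are appended).  Replicates default to
100 for the fixed LD-derived marker set and 20 when GWAS reselection runs
inside each replicate; both are configurable.  Predictive ability is the
Pearson correlation between GEBVs and observed adjusted phenotypes over the
validation accessions of the target environment; replicates with fewer than
three phenotyped validation accessions are skipped with a warning.

Replicate-level comparisons use Z = arctanh(r).  The ANOVA of Z is a
fixed-effects least-squares fit with sequential (Type I) sums of squares in
the caller's factor order — with balanced factors the main-effect sums of
squares are identical with and without first-order interactions, which the
tests assert.  Summaries report both the raw mean predictive ability and the
back-transformed mean of Z, since which of the two a study reports is often
unstated.

## Problem sizes used in the shipped checks

The acceptance-style checks run on synthetic panels of 200–300 accessions
and 400–3,000 markers with 20 replicates, Gibbs chains as above.  The
directional marker-selection experiment simulates a dense panel (2 kb
spacing, `ld_copy_prob` 0.995, `pool_size` 2, 20 QTL, h² 0.5): trait-specific
selection can only beat a neutral subset when LD pruning is materially
reductive, as it is in a real 215k-SNP panel where r² ≤ 0.25 retains ~1% of
markers; in a panel with no LD both "subsets" are the whole panel and the
comparison is vacuous.  The LD baseline uses the grid point r² ≤ 0.25 with
MAF ≥ 5%, and the GWAS mode selects the same number of markers within each
training fold.  The multi-environment experiment uses two environments with
genetic correlation 0.9 and h² 0.5 per environment.

## Known limitations

- The M×E/G×E samplers share a single residual variance across environments;
  the Kronecker model relaxes this to per-environment residuals.
- No spatial (row–column) adjustment, multi-year repeatability, or
  multi-trait REML in the phenotype-adjustment stage.
- No Bayesian-alphabet marker-effect models, weighted-GRM variants, or
  pedigree/single-step models.
- The Gaussian-kernel models use one bandwidth; no kernel averaging.
- GWAS is single-locus; no multi-locus or inflation-corrected variants.
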