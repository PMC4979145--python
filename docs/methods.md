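# Methods

## Trait construction

Body weight during a rapid-growth window is modelled per bird as a line
in the day of test, `BW = μ + a·DOT + e`, fit by ordinary least squares.
DOT is coded 1..40 (a 40-day test), so the mid-test day is 21 and
MBW = μ̂ + 21·â; MMBW = MBW^0.75 is the metabolic-weight scaling used
for maintenance requirements. Birds whose growth line explains less
than 80 % of their weight variance are flagged (`low_fit_flag`) but
kept — a low R² marks an unreliable ADG/MMBW estimate, not an invalid
bird. ADFI is the mean of the available daily feed records (missing
days tolerated and counted). FCR is defined per bird as ADFI/ADG; the
ratio is undefined (NaN, with a warning) for non-positive ADG.

RFI is the residual of the cohort-level OLS of ADFI on (1, MMBW, ADG).
OLS guarantees exact zero mean and exact orthogonality to both
regressors — properties the test suite asserts at 1e-10.

Fixed effects are screened by one-way F-tests of RFI on sex and on pen;
a factor significant at p < 0.01 has its level means subtracted (sex
first, then pen; under the balanced round-robin design this equals
LS-means adjustment) and the result is re-centred. The adjustment is
idempotent. Pens are nested in sex (three male pens, then three female
pens), so in a model with both factors the sex column is collinear with
the pen dummies; design matrices drop collinear columns greedily.

Normality is assessed with the Anderson–Darling A² using estimated mean
and SD, the small-sample correction `A²* = A²(1 + 0.75/n + 2.25/n²)`,
and the standard piecewise-exponential p-value approximation for the
estimated-parameter case. The Johnson transformation is fit by the
Slifker–Shapiro percentile method: for each selection constant z₀ in
0.25..1.25 (step 0.01) the four sample quantiles at ±z₀, ±3z₀ pick the
family (SU/SB/SL via the m·n/p² discriminant) and its closed-form
parameters; infeasible fits (support not covering the sample, δ ≤ 0)
are discarded and the candidate maximizing the post-transform
Anderson–Darling p-value is returned. All accepted transforms are
strictly monotone, so RFI rankings survive transformation. If no
candidate is feasible the identity is returned with a warning.

The divergent-group contrast takes ⌊0.10·n⌋ birds from each tail of the
RFI ranking (ties broken by bird id for determinism) and reports
mean ± SE per group and a Welch two-sample t-test per trait. Welch was
chosen over the pooled-variance t because group variances need not be
equal in the tails.

## Variance components

The genomic kinship is the VanRaden frequency-weighted form
`Φ_ij = (1/m) Σ_k (g_ik − 2p_k)(g_jk − 2p_k) / (2p_k(1−p_k))` with
per-SNP mean imputation of missing calls; monomorphic SNPs must be
removed by QC first. A pedigree numerator relationship matrix (tabular
method, topological sort, cycle detection) is available when only a
pedigree exists. A ridge of 1e-8 is added before eigendecomposition.

Univariate REML exploits the eigendecomposition of K: after rotating
data by the eigenvectors, the restricted likelihood is profiled down to
a one-dimensional function of the log variance ratio, maximized by
bounded scalar search (tolerance 1e-10, bounds e^±15) with explicit
boundary checks. The SE of h² comes from the numeric observed
information in (σ²_A, σ²_E) and the delta method. Bivariate REML uses
the same rotation: the likelihood factors into n independent 2×2 blocks
`V_i = G·d_i + R`; G and R are parametrized by log-Cholesky factors
(guaranteeing positive semi-definiteness) and maximized by Nelder–Mead
started from the univariate fits, with restarts because a genetic
correlation of ±1 lies on the PSD boundary, which log-Cholesky reaches
only asymptotically. EBVs are standard BLUPs under the fitted
components.

## GWAS

QC removes, in order: SNPs with call rate < 0.95, individuals with call
rate < 0.95, SNPs with MAF < 0.01, and SNPs failing the Hardy–Weinberg
exact test (Wigginton recursion) at p < 1e-6. The thresholds are
conventional chip-QC defaults and configurable.

The scan is two-step (EMMAX-style): null variance components estimated
once by REML, then each SNP tested by a GLS Wald test of its dosage
under the fixed null covariance. Dosages are oriented to the minor
allele so effect signs refer to the rarer allele; fixed effects may be
omitted when the phenotype has been pre-adjusted (the transformed RFI);
an intercept is always included. Genomic control divides the χ²
statistics by λ = median(χ²)/0.4549364; the genome-wide significance
threshold is p < 10⁻⁴ after correction. FDR is the step-up `m·P(i)/i`
with the reverse cumulative minimum, computed within each chromosome
(m = SNPs on that chromosome after QC; a genome-wide switch exists),
with tier flags at 5 % and 10 %.

Per-SNP variance explained fits `y = μ + SNP + e` with genotype as a
class factor (up to 2 df) and reports 100·R²; the additive-variance
share uses BLUP breeding values as the response. For a *set* of SNPs
two aggregations are reported side by side: the naive sum of per-SNP
shares (which double-counts SNPs in LD and can exceed 100 %) and the
joint multiple-regression R² (which attributes shared signal once).
Neither is asserted as "the" answer; they bracket it.

## Linkage disequilibrium

Two-locus haplotype frequencies come from the standard EM over the
double-heterozygote phase ambiguity (frequency-change tolerance 1e-12;
the EM log-likelihood is asserted non-decreasing every iteration). D′
confidence bounds follow the Gabriel procedure: the genotype-table
likelihood is profiled over |D′| ∈ 0..1 (step 0.001, allele frequencies
fixed at their MLEs, D keeping its estimated sign), normalized to unit
mass, and the 5th/95th percentiles taken as one-sided bounds. A pair is
in strong LD when the upper bound ≥ 0.98 and the lower ≥ 0.70. Blocks
are maximal runs in which more than 95 % of informative pairs
(MAF ≥ 0.05 at both SNPs, EM converged) are strong, resolved greedily
longest-span-first with overlaps skipped; pairwise comparisons are
limited to a 500-kb window. Block haplotype frequencies use the same EM
generalized over multilocus phase configurations, capped at 12 SNPs
(the state space doubles per heterozygous site); frequencies below 1 %
are pruned from reports. The LD-decay profile uses the squared
genotype-dosage correlation (the composite r², equal to the haplotype
r² under HWE), averaged in 20-kb distance bins.

## Differential expression

Expression is RPKM = 10⁹·C/(N·L). With two libraries per group, counts
are pooled within group and each gene is tested by an exact conditional
binomial test of the pooled counts against the pooled library totals
(the two-proportion exact test; equivalent conditioning to Fisher's
2×2, numerically robust at ~10⁷-read libraries). q-values are
Benjamini–Hochberg; a gene is DE when q < 0.05 and |log₂FC| ≥ 1, with
log₂FC computed from pooled RPKM after adding a pseudocount of 0.5 to
the pooled counts. Genes with zero pooled counts in exactly one group
and RPKM ≥ 1 in the other are reported as group-specific rather than
with a numeric fold change. Pooling (rather than per-replicate
dispersion modelling) matches the group-mean comparison this design
implies at n = 2 per group; it is anticonservative in principle for
overdispersed counts, which is why the fold-change gate matters — the
null false-positive rate is verified ≤ 5 % by simulation in the test
suite. miRNA–target consistency marks a (miRNA, target) pair as
consistent with negative regulation when both are DE in opposite
directions.

## Positional integration

Gene models are 1-based inclusive, read from GFF3. Relation labels use
the precedence UTR-3/UTR-5 > exon > intron inside a gene span;
otherwise upstream/downstream when the SNP is within 5 kb (default,
configurable) of the strand-oriented TSS/TES; otherwise intergenic with
the nearest gene named; ties break toward the lexicographically smaller
gene id. Flank capture intersects the closed interval
[pos − flank, pos + flank] with gene spans; the 50-kb capture set is a
subset of the 500-kb set by construction. The GWAS–DEG overlap is an
inner join of captured genes with DE calls, one row per (gene, SNP).

## The synthetic cohort

The generator defines the study conditions; its defaults describe a
40-day feeding trial on a slow-growing layer-type line: 426 genotyped
birds, six pens nested in sex, start weights 794/760 g (male/female,
SD 100), ADG 28 ± 3 g/day, day-level weight noise 25 g, feed noise
10 g/day, RFI SD 8.36 g/day with h² = 0.35 from 20 QTLs, heritable
growth (ADG h² = 0.32, start weight h² = 0.56 — which is what keeps the
emergent genetic correlation between RFI and ADFI below 1, around
0.75–0.85), pen effects of ±3 g/day and no direct sex effect on intake
beyond body size. Koch coefficients default to b0 = 5 g/day,
b1 = 0.3 g/day per g^0.75, b2 = 1.25, chosen to reproduce the observed
trait scale (ADFI ≈ 105 g/day at MMBW ≈ 220, ADG ≈ 28).

Genotypes: per-SNP coded-allele frequencies are drawn from a chip-like
rare-skewed spectrum 0.02 + 0.48·Beta(0.5, 1). Haplotypes threshold a
latent stationary Gaussian Markov (Ornstein–Uhlenbeck) field with
correlation exp(−d/L) over d bp, so marginals are exactly Bernoulli(p),
genotypes (sums of two independent haplotypes) are in HWE by
construction, and LD decays monotonically with physical distance
independent of marker density. L = 240 kb was calibrated once, by grid
search against the target decay pattern (mean r² ≈ 0.3 at short range,
≈ 0.2 at 40–60 kb, ≤ 0.15 at 80–100 kb on the 1.8-kb-spaced desk map),
and is not revisited; short-range D′ stays near 1, so Gabriel blocks
form on dense segments. Trait simulation rescales genetic and
(orthogonalized) environmental components so the *in-sample* variance
ratio equals the configured h² exactly — recovery tests are judged
against the variance actually planted, not its expectation. The
bivariate generator likewise colors the genetic and environmental
blocks to hit the target covariance matrices exactly in-sample.

RNA-seq counts are Gamma–Poisson (negative binomial, var = μ + φμ²)
with φ = 0.05 — typical for biological replicates within a closed
line — library sizes ≈ 2.3·10⁷ reads (CV 0.1), lognormal gene lengths
(median ≈ 1.8 kb) and abundances; DE genes receive a configured fold
change in the low-RFI group, half up, half down.

What the generator does *not* emulate: coalescent site-frequency
structure, sequencing reads (counts only), genotyping batch effects,
selection or family structure beyond what the marker LD induces, gene
architecture realism (the toy GFF3 is plumbing for the integration
stage), and transcript-level quantification. Passing tests therefore
demonstrate correctness of the estimators under the stated statistical
model, not robustness to every artefact of real data.

## Problem sizes used in tests

Desk-scale analyses run at n = 426 birds and 5,000 SNPs on five 1.8-Mb
chromosomes. Variance-component recovery runs at n = 1000, m = 5000
(10 replicates). The null-scan calibration uses 10,000 SNPs spread over
five 100-Mb chromosomes: with the desk map, the 240-kb LD scale leaves
too few effectively independent markers for a stable genomic-control λ,
whereas the sparse genome-scale map mirrors a real chip where the
median χ² is tight around its null value. DEG error rates use 2,000
genes × 20 replicates. These sizes were chosen so the whole suite runs
comfortably on a single CPU while keeping Monte-Carlo error well inside
the asserted tolerances.

## Known limitations

- The bivariate REML reports a unit-mass SE fallback when the genetic
  covariance is near-singular; profile-likelihood intervals would be
  better calibrated there.
- The DEG test ignores biological dispersion (see above); with more
  replicates a negative-binomial GLM is preferable and the module's
  config hook (`variant`) is the place it would plug in.
- The Johnson selection-constant grid trades exactness for speed; an
  adaptive refinement around the best z₀ would sharpen borderline fits.
- Genomic-control λ on the desk-scale map is noisy (few independent
  loci); interpret per-run λ there qualitatively.
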