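# Methods

`episcan` re-creates, at desk scale, a genome-wide SNP–SNP interaction
analysis of a case-control disease phenotype (the motivating application is
inherited susceptibility to multiple myeloma) together with its downstream
inference stages: two-cohort meta-analysis, cis-eQTL/SMR causal screening,
liability-scale heritability, and pathway enrichment.  This note records
the statistical models, the defaults and why they were chosen, the design
decisions taken where several defensible options existed, and what the
synthetic data can and cannot establish.

## Genotype model and quality control

Genotypes are allele1 dosages in {0, 1, 2} with a missing sentinel; all
statistics use pairwise-complete observations.  Coordinates are 1-based
inclusive throughout (the PLINK `.bim` convention), and every window rule
below is stated against that convention.  Dosages count copies of the first
allele in the variant map; orientation to the minor allele is not enforced
genome-wide, so effect signs must be read against the map, which the output
headers carry.

QC mirrors array-GWAS practice: per-sample call rate ≥ 0.95; relatedness
removal at pairwise identity-by-state (IBS) ≥ 0.80, where IBS is the mean
shared-allele proportion `(2 − |g₁ − g₂|)/2` over shared non-missing loci
and the lower-call-rate member of a flagged pair is dropped (ties break to
the later sample index — the choice is arbitrary but deterministic);
per-SNP MAF ≥ 0.01 and call rate ≥ 0.95; and a Hardy–Weinberg exact test in
controls at P ≥ 1e-5.  The HWE test is the exact conditional test on
heterozygote counts given allele totals, computed by the stable ratio
recurrence and verified against full enumeration to 1e-12 for tables up to
200 alleles.  Each removed entity records exactly one primary reason
(checked maf → callrate → hwe), which keeps filters idempotent.
Covariate PCA is plain eigen-analysis of column-standardized dosages with
mean imputation of missing calls; no external reference panel is used.

## Interaction scan

The per-pair statistic contrasts the Pearson correlation of two SNPs'
dosages between cases (r_A) and controls (r_N):

    T = (r_A − r_N)² / (Var(r_A) + Var(r_N)),   Var(r) = (1 − r²)²/(n − 3),

referred to χ²₁.  The delta-method variance of the sample correlation is
the one modelling choice in the statistic; it is isolated in a single
function (`correlation_variance`) so alternatives can be swapped in, and
its adequacy is established empirically rather than asserted: under the
null (independent HWE SNPs, labels carrying no signal, n = 1000 per group)
the measured type-I error at α = 0.05 falls inside [0.040, 0.060] and the
p-value distribution passes a Kolmogorov–Smirnov test against Uniform(0,1)
at the 1% level over 10,000 pairs.

Pairs are formed only among SNPs passing a Cochran–Armitage trend
pre-filter (additive scores, P ≤ 1e-3, applied within each cohort
separately), which deflates the scan space the way the full-scale analysis
does.  Group sizes below 5 or zero-variance dosages skip the pair with a
recorded reason.  The interaction odds ratio comes from an unconditional
logistic model with a dosage-product term,
logit P(case) = b₀ + b₁x_i + b₂x_j + b₃x_ix_j, fit by Newton/IRLS
(statsmodels) with a 50-iteration budget; non-convergence and separation
(|b₃| > 15 or non-finite standard error) are flagged rather than reported.

## Meta-analysis

Per-cohort correlation-contrast p-values are combined with Fisher's
statistic X = −2Σln p against χ² with 2k degrees of freedom — four for two
cohorts — equivalently a Gamma(k, 2) upper tail.  Non-unit weights are
accepted and handled by a moment-matched gamma reference; unit weights are
the default since no weighting scheme is reported for the reference
analysis.  Only pairs tested (unskipped) in both cohorts enter; the
genome-wide flag defaults to P < 5e-10.  Odds ratios are pooled by
fixed-effect inverse variance, with per-cohort standard errors recovered
from the 95% Wald limits as (ln hi − ln lo)/(2·1.96).  Pooling the two
cohorts' published interaction ORs for the strongest pair, 1.20
(1.08–1.33) and 1.24 (1.09–1.41), reproduces 1.22 (1.12–1.32) at
two-decimal rounding.  The combination operates on the correlation-test
p-values; the logistic p-values feed only the OR route.  No heterogeneity
statistic is computed.

## cis-eQTL mapping and SMR

Probes are dropped when log2 expression is below 3.5 in at least 95% of
samples, or when non-autosomal.  A SNP–probe pair is cis when on the same
chromosome within 1 Mb of the probe's single representative coordinate,
boundary inclusive (the anchor-point convention is ours; a gene-body anchor
would shift the boundary by at most the gene length).

The eQTL effect is estimated by iteratively reweighted least squares with
Huber weights w(e) = min(1, c·ŝ/|e|), c = 1.345 (95% efficiency at the
normal), scale ŝ = 1.4826 × median|residual| refreshed every iteration,
convergence at 1e-8 or 50 iterations.  The standard error is the
M-estimator asymptotic one (ψ-based, with Huber's small-sample correction
factor): a plain weighted-least-squares covariance was measured to inflate
the type-I error to ~0.09 at nominal 0.05 because downweighted residuals
understate the dispersion, so it was rejected in favour of the estimator
whose measured type-I error is calibrated.  P-values use the normal
reference (group sizes in scope are large).  LD pruning is a greedy scan
in map order dropping any SNP with dosage r² > 0.9 against a retained SNP
within 1 Mb.

Family-wise control uses the Šidák per-test level 1 − (1 − α)^(1/m) with m
the number of tested probes, applied single-step at that fixed cutoff (a
step-down variant would only be less conservative; the single fixed cutoff
matches how the reference analysis reports it).

The SMR stage treats the SNP as an instrument: β_XY = β_ZY/β_ZX with
T = z²_ZY·z²_ZX/(z²_ZY + z²_ZX) against χ²₁, where β_ZY is the per-allele
log-odds from a single-SNP logistic fit.  Because T ≤ min(z²_ZY, z²_ZX),
the SMR p-value can never beat either input association — an algebraic
invariant asserted over random inputs and over 26 published operating
points.  No HEIDI-type heterogeneity test is attempted: the design goal is
the pleiotropy/causality screen, not distinguishing linkage from
pleiotropy.

## Heritability

The genetic relationship matrix over the chosen SNP subset is the
standardized-dosage covariance A_jk = (1/M)Σᵢ(x_ij − 2pᵢ)(x_ik − 2pᵢ)/(2pᵢ(1 − pᵢ))
with sample allele frequencies and mean imputation.  Observed-scale
heritability is the Haseman–Elston slope of phenotype cross-products on
off-diagonal relatedness, after residualizing the 0/1 phenotype on
covariates (optionally including genotype PCs) and standardizing; the
standard error is a block jackknife over individuals.  Haseman–Elston was
chosen over REML deliberately: it is a desk-scale, dependency-free
estimator of the same estimand, at the cost of larger sampling variance —
the recovery bands in the validation suite absorb that.

Conversion to the liability scale uses the ascertainment-corrected factor
K²(1 − K)²/(z(t)²·P(1 − P)) with K the population lifetime risk (default
0.007, the UK figure; 0.006 is the German one), P the sample case
proportion, t the upper-K normal quantile and z the density there.  The
transform is exactly linear in the observed-scale estimate.

The module has its own liability-threshold simulator: genetic value = sum
of population-standardized causal dosages times a weight vector rescaled
so the genetic variance is exactly h², environmental noise N(0, 1 − h²),
case iff liability exceeds the upper-K quantile, cases oversampled to
quota.  At h² = 0.2, K = 0.01, 500+500 samples and 2,000 causal-tagging
SNPs, the mean liability-scale estimate over 50 replicates lands near the
truth (see the reproduction script's `h2_liability_mean`).

## Pathway enrichment

SNP p-values map to genes within ±20 kb of the gene interval (boundary
inclusive).  Genes that share at least one pathway *and* are physically
adjacent (overlapping flanked intervals or a shared assigned SNP) fuse into
one unit by transitive closure; requiring adjacency is a deliberate
narrowing of "fuse genes affecting the same pathway", since without it any
two same-pathway genes genome-wide would merge, contradicting the flanking
rationale — the check is flag-switchable.  A unit's score is the sum of
its member SNPs' χ²₁ quantiles with df = member count; a pathway's score
sums its units' quantiles with df = unit count.  Both reduce to the
identity for singletons.  This independence-df scheme is valid on LD-free
synthetic data; on real data with LD, `ld_prune` must be applied first or
gene scores will be anticonservative — a documented limitation (no
LD-aware correction is implemented).

Per-source pathway p-values (e.g. two cohorts plus their meta-analysis)
are combined with Brown's method: X = −2Σln p referred to a scaled χ² with
V = 4k + 2Σρ(3.263 + 0.710ρ + 0.027ρ²), the inter-source correlation
estimated empirically from the −2 ln p vectors across pathways (a supplied
matrix overrides).  With identity correlation this is exactly Fisher's
method (asserted to 1e-12); with fewer than 3 shared pathways the
empirical correlation is undefined and independence is assumed.  The
global reporting threshold (0.0025 in the motivating analysis) is a flag,
not hard-coded.

## Synthetic cohorts

The disease model is logistic in dosages with optional product terms;
the intercept is solved by 1-D root finding on the exact population
prevalence equation (enumerating the joint HWE distribution of
effect-bearing SNPs), reducing to logit(K) with no effects.  Cohorts are
ascertained case-control by rejection sampling on the logistic model; the
rejection operates on effect-SNP genotypes only, with null SNPs filled
from their HWE distribution afterwards — distributionally identical and
fast enough to ascertain at the default lifetime risk K = 0.007.  SNPs are
LD-free by default (keeping the analytic nulls exact), with a latent
Gaussian-copula block generator available for pruning tests.  Missingness
is uniform at random.  Default study sizes (500 cases + 500 controls,
1,000 SNPs, MAF ~ U(0.05, 0.5)) are the desk-scale stand-in for cohorts of
thousands; the planted-pair design uses γ = ln(3) with per-allele marginals
β = ln(1.5) on both members — strong enough that the pair reliably survives
the P ≤ 1e-3 marginal pre-filter, which is a precondition of the scan
design, while ln(1.3) marginals were measured to slip below the filter in
roughly 1 in 20 cohort draws at these sizes.

Expression data follow y = μ + b·g + ε with symmetric outlier
contamination (fraction π of residuals scale-inflated), emulating the
moderately contaminated arrays that motivate Huber regression; planted
probes sit at their SNP's coordinate, and one decoy probe is placed on
another chromosome so the cis filter is always exercised.  What the
synthetic data do **not** emulate: realistic allele-frequency spectra, LD
maps, batch/intensity artifacts, population structure (except in the
dedicated PCA fixture), or trans-regulation.  Passing tests therefore
establish correctness and calibration of the statistics under their own
assumptions, not robustness to real-data pathologies.

## Numerical choices and degenerate inputs

Logistic fits: 50 Newton iterations, separation flagged at |b₃| > 15.
Huber IRLS: coefficient tolerance 1e-8; zero MAD scale short-circuits.
HWE: probabilities by ratio recurrence from the modal heterozygote count;
the "≤ observed probability" sum uses a 1 + 1e-10 relative slack against
floating-point ties.  Monomorphic SNPs yield trend p = 1 with a flag and
are skipped (with reason) in pair tests; all-missing columns count as
MAF-failures.  Fisher combination rejects p outside (0, 1]; Brown requires
a unit-diagonal correlation.  Problem sizes in the validation suite
(10,000 null pairs; 20 planted studies; 200 OR and Huber replicates; 50
heritability replicates) were chosen so each study delivers stable
Monte-Carlo estimates at desk scale.

## Known limitations

- Haseman–Elston has larger variance than REML; single-component only.
- No covariate-adjusted interaction test; no case-only or joint-effects
  epistasis statistics.
- Gene/pathway scoring assumes independent SNP statistics (prune first).
- No VCF or PLINK 2 input; no genotype imputation; no external annotation
  retrieval (gene tables and GMT collections are user-supplied or
  simulated).
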