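# Methods

`pleiomap` implements a sequence-level, multi-trait GWAS fine-mapping
workflow for a livestock-style cohort: mixed-model association per trait,
permutation-calibrated multiple-testing thresholds, grouping of signals
into QTL regions across traits, credible-set construction by LD and by a
sum-of-single-effects model, pleiotropy diagnostics, conditional mapping,
and a coding-variant enrichment test. Because the motivating cohorts
(genomic-selection reference populations of intensively selected beef
cattle) are under restricted licenses, the package carries a first-class
synthetic cohort generator whose output has the statistical structure the
analysis assumes; every stage is validated against that generator.

## Association model

For trait deviations `y` (one record per individual) and marker `i`:

    y = 1·mu + x_i·b_i + g + e,  g ~ N(0, sg2·G),  e ~ N(0, se2·I)

`x_i` holds alternate-allele dosages in [0, 2], `G` is the genomic
relationship matrix from VanRaden's first method,
`G = W W' / (2 Σ p_k (1 − p_k))` with `W` the dosage matrix centered by
twice the allele frequency. Monomorphic markers are excluded; missing
dosages are mean-imputed for relationship estimation only.

`G = U Λ U'` is computed once. In the rotated basis the covariance is
diagonal, so the null variance components are estimated by REML with a
one-dimensional bounded search over `log(sg2/se2)` (the scale is profiled
out analytically). The per-variant test then keeps the variance *ratio*
fixed at its null estimate and re-estimates the residual scale per
variant, i.e. weighted least squares on whitened data with
`t = b̂/SE, df = n − #fixed − 1`. Two consequences worth knowing:

- when `sg2 → 0` the scan is algebraically ordinary least squares
  (checked to 1e−8 in the tests);
- the test is a two-step approximation, not exact per-variant REML. At
  the effect sizes relevant here the difference is negligible, and type-I
  error is calibrated (null fraction of p < 0.05 within 0.05 ± 0.007 at
  10,000 null variants; Kolmogorov–Smirnov uniformity p > 0.01).

Conditioning variants enter as additional fixed-effect columns. A tested
variant collinear with the covariates (r² = 1, e.g. conditioning on
itself) is reported with NaN statistics and a reason code rather than a
number.

The multivariate model stacks T ≤ 10 traits with genetic covariance `Vg`
and residual covariance `Ve`. `(Vg, Ve)` are estimated by an EM algorithm
on the rotated likelihood (tolerance 1e−6 on the log-likelihood, at most
500 iterations; `Ve` kept positive definite by eigenvalue flooring at
1e−6 of its trace). Each variant's T-vector of effects is estimated by
GLS with the components fixed and tested with a chi-square Wald statistic
(df = T). Near `Vg ≈ 0` the EM is slow and the Wald test mildly
conservative; with a genuine polygenic background — the situation the
model is for — it is calibrated (checked in the tests). Missing
phenotypes are dropped per trait (single-trait) or listwise within a
trait group (multivariate); the GRM is re-decomposed on the subset.

## Multiple testing

The effective number of independent tests follows the permutation
procedure: repeated simple-regression genome scans on permuted phenotypes
record the best p-value per scan; for a grid of nominal values `p` the
corrected value `p_c(p)` is the fraction of permutation best-p ≤ p, and
the Sidak relation `p_c = 1 − (1 − p)^meff` is inverted pointwise. The
published account stops at "comparison of the uncorrected and corrected
p-values"; the aggregation here — the median of pointwise estimates over
grid points with `p_c` in [0.01, 0.5] — is this package's choice, made
because tail grid points are Monte-Carlo-noisy and the central range is
stable (coefficient of variation < 0.3 across the grid in simulations).
The default grid is a set of empirical quantiles of the permutation
best-p distribution; the default 10,000 permutations (2,000 in the
bundled analyses) keep desk-scale runtimes, with larger counts available
by argument. Permutations shuffle whole phenotype vectors, preserving
nothing but sample size.

The effective number of traits uses the Galwey estimator on the trait
correlation matrix, `meff = (Σ √λ'_k)² / Σ λ'_k` with eigenvalues floored
at zero; both the raw value and its floored integer are reported, the
integer being what enters the threshold. The final genome-wide threshold
is `alpha / (meff_tests × meff_traits)`. At the study's scale
(500,000 × 7 at alpha 0.05) this gives 1.43e−8 (−log10 = 7.84); at a
10-Mb regional scale with ~20,000 effective tests, 2.5e−6 (−log10 = 5.6);
at ~2,500 tests for a second conditional round, 2e−5. A suggestive level
of 1e−7 marks traits with evidence short of genome-wide significance.

## QTL regions

Per trait, QTL are greedy peaks: the most significant variant absorbs all
significant variants within 1 Mb, repeatedly; ties on p break toward the
lower position. Across traits, QTL whose leads are ≤ 1 Mb apart merge
into a QTL region by single linkage. Single linkage can chain leads more
than 1 Mb apart transitively; this reading was chosen because observed
regions can contain two distinct, distant peaks. Within a region, traits
whose best p is below the suggestive level but not genome-wide
significant are listed as suggestive. Regions are labelled
`chrom:Mb-of-best-lead`. Regulatory-catalogue overlap is a coordinate
test only: a BED interval `[start, end)` (0-based, half-open) covers
1-based positions `start+1 .. end`.

## Credible sets

LD-based credible sets take every variant with `r² ≥ 0.90` (or 0.80) to
the lead, with r² the squared Pearson correlation of dosages over
non-missing individuals; the 0.90 set is nested in the 0.80 set by
construction. The LD window used in the bundled analyses is ±2.5 Mb
around the region (the chromosomes simulated are far smaller than real
ones; on real data a ±5 Mb window would cover a 10-Mb conditional
region).

IBSS fine-mapping fits a sum of L single effects to summary statistics:
z-scores are mapped to sufficient statistics of a standardized regression
(`X'X = (n−1)R`, `X'y = √(n−1)·z`, `y'y = n−1`, residual variance fixed
at 1, with R the in-sample LD), and each effect is refitted in turn by a
Bayesian single-effect regression on residual statistics until the
inclusion probabilities change by less than 1e−8 (at most 200 sweeps).
Per effect the prior effect variance is selected on a geometric grid
(1e−4 to 1 times the phenotypic variance, 13 points) by maximizing the
single-effect marginal likelihood; the grid extends below 1e−2 because at
n ~ 10³ the optimum for realistic z-scores falls there. Per effect, the
95% credible set is the smallest inclusion-ordered set reaching the
coverage; sets whose minimum absolute pairwise correlation is below 0.5
(purity), duplicate sets, and catch-all sets spreading over more than
half the region are discarded. A non-positive-definite LD matrix is
regularized by adding 1e−4 to the diagonal. With L = 1 the posterior
matches brute-force single-effect enumeration to 1e−6 (test oracle:
numerical quadrature over the effect size); with one simulated causal
variant the 95% sets cover it in ≥ 90% of regions.

Multi-trait credible sets follow the qualification-and-merge rule: a
six-trait group's multivariate scan is used in a region only if at least
one member trait reaches the suggestive level in its own scan there; each
qualifying group contributes an LD credible set around its multivariate
lead, and if both groups qualify the union is reported as the merged
multi-trait set. The merged set's lead is the qualifying lead with the
smaller multivariate Wald p.

## Pleiotropy

For a trait pair in a region, all variants within 1 Mb of the lead of the
stronger trait are taken, variants with p > 0.05 in both traits are
excluded (no effect sharing is expected for unassociated variants), and
the Pearson correlations of t-values (primary) and of signed −log10 p
(secondary) are reported. Fewer than three retained variants flags the
result unreliable. An antagonistic pleiotropic variant — raising size
traits, lowering muscling — produces strongly negative t-correlations
(below −0.7 in ≥ 80% of simulated replicates).

## Conditional mapping

Per region, one candidate is chosen: a coding member of the multi-trait
credible set when one exists, else the lead. Candidates enter the LMM as
fixed covariates; only traits with prior evidence (suggestive level in
the first scan) are rescanned, within a 10-Mb window centered on the
candidate. Variance components are re-estimated with the covariates in
the model (cheap at region scale). New leads above the round threshold
are appended — each variant at most once — and the scan repeats until
nothing new appears or a round limit is hit. In simulation, conditioning
on the true causal removes all region significance in ≥ 90% of
replicates, and a second independent causal survives conditioning in
≥ 80%.

## Coding-variant enrichment and variance explained

Annotation tables are VEP-style; "coding" means predicted impact MODERATE
or HIGH (missense, splice-site, frameshift, premature stop). Under the
null each credible-set member is coding independently with the
genome-wide coding rate (0.34% in the motivating data). The observed
total coding count is tested against the Binomial(Σ sizes, rate) upper
tail; the count of credible sets containing at least one coding variant
against the Poisson-binomial upper tail over per-set probabilities
`1 − (1 − rate)^size`, computed exactly by a dynamic-programming
convolution (verified against complete 2^k enumeration for k ≤ 15). A
Monte-Carlo sampler (default 1e6 repetitions, 1e8 available) reproduces
both tails within sampling error. The per-member Bernoulli null was
chosen over repositioning credible sets on an annotated genome because it
is the model consistent with testing "the proportion of coding variants
and the size of each CS"; with the published set sizes (11 sets, 330
members) it reproduces the printed expectation of 1.1 coding variants
and tail p ≈ 0.001 for ≥ 6 observed, p ≈ 1.3e−4 for the relaxed r² ≥ 0.80
scenario (11 sets averaging 73 members, 11 observed), and p ≈ 2e−10 for
≥ 5 of 11 coding lead variants. A lead-variant version uses the plain
binomial tail.

Candidate effects are also estimated jointly (all candidates as
simultaneous fixed effects in the LMM; candidates with pairwise r² ≥ 0.99
are rejected as collinear). The share of genetic variance per candidate
is `2p(1−p)·b̂² / sg2`, with `sg2` from the candidate-free null fit, and
is cross-checked against the relative reduction of the polygenic variance
when the candidates are in the model; the two agree within simulation
error on synthetic cohorts.

## Synthetic cohort generator

Genotypes are diploid mosaics of founder haplotypes: each of the 2n
haplotypes copies a founder and switches to a random founder with
probability `switch_rate` per variant. Founder alleles are generated by
rank-thresholding a latent Gaussian that evolves along the chromosome
with AR(1) step correlation `exp(−switch_rate)`, and target frequencies
follow a locally correlated U(0.05, 0.95) spectrum — together these
produce high-r² LD blocks whose r² decays with physical distance. A
fraction of variants (`proxy_rate`, default 0.15) exactly or almost
exactly duplicates the previous founder column, supplying the
perfect-proxy pairs (r² ≈ 1) that sequence panels contain and that LD
credible sets rely on. Variant spacing is
`block_length_bp × switch_rate`, so the expected physical block length is
`block_length_bp`. Realized MAF below the floor triggers re-thresholding
at a safer frequency, then removal. Coordinates are 1-based as in VCF;
genotypes are hard calls, with fractional dosages available by adding
clipped Gaussian noise (exercising dosage-aware code paths).

Phenotypes invert the association model: `Y = Σ QTL + g + e`. The
polygenic term is a centered-marker score over designated background
variants scaled so its covariance matches `Vg` — deliberately the same
markers the GRM is built from, which makes heritability recovery a
testable property (ĥ² for h² = 0.5 lands in [0.4, 0.6] at n = 2,000). A
`background_chroms` option restricts the background to chosen
chromosomes so leave-one-chromosome-out analyses stay internally
consistent. QTL contribute per allele dose; an optional
`recessive_penalty` is added to homozygous-alternate phenotypes, modeling
recessive deleterious alleles held at elevated frequency by favorable
additive effects (heterozygote advantage). Annotations flag variants
coding i.i.d. at `coding_rate` (default 0.0034), with designated truth
variants forceable to coding.

The default cohort (`default_cohort_config`) has 1,500 individuals, three
chromosomes × 700 variants (14 Mb each at 20-kb spacing), and 11 traits —
six body-size, five muscling — with h² = 0.3 per trait, genetic
correlation 0.5 within a block and −0.3 across, residual correlation 0.35
within a block. Three pleiotropic QTL are planted: a size-increasing QTL
(+0.25 size traits, −0.15 muscling), its muscling mirror image, and a
recessive deleterious variant at frequency 0.15 with favorable additive
effects (+0.12/+0.28) and homozygote penalty −1.5. The first two explain
roughly 2–3% of phenotypic variance per trait, enough to clear the
cohort-calibrated threshold at n = 1,500; the recessive locus is
deliberately harder — its homozygote penalty cancels much of its additive
signal at this sample size, as the weakest loci of this kind only reach
significance in cohorts an order of magnitude larger.

What the generator does *not* emulate: coalescent-accurate LD and allele
frequency spectra, demographic structure and inbreeding, selection,
genotyping/imputation error beyond the optional dosage noise, and
sequence-level artifacts. Tests passing on these cohorts therefore
establish internal statistical correctness (calibration, recovery,
coverage), not robustness to every property of real cattle data.

## Problem sizes in the bundled analyses and tests

The numbered drivers under `analysis/` and the acceptance script run the
cohort at n = 1,500 × 2,100 variants with 2,000 (drivers) or 1,500
(acceptance script) permutations for the threshold; the test suite uses
n up to 4,000 where a criterion's precision demands it. These sizes were
chosen so a complete run is a coffee-break job on a laptop core while
keeping every statistical check well-powered; all of them are parameters,
not constants.

## Known limitations

- Variance components fixed at null estimates (single- and multi-trait):
  slightly conservative near the h² = 0 boundary.
- GRM built from all markers includes the tested region (as in the
  motivating study's design, which used a separate medium-density panel);
  with few simulated chromosomes this can absorb strong QTL
  ("proximal contamination"), so the simulation studies use
  leave-one-chromosome-out GRMs where exactness matters.
- The Hardy–Weinberg filter uses a 1-df chi-square on rounded hard calls,
  not an exact test; at the cohort sizes involved the difference is
  immaterial, and the function is swappable.
- IBSS uses a fixed unit residual variance on the standardized scale
  rather than re-estimating it; with in-sample LD this is the standard
  summary-statistic regime.
- The enrichment null treats credible-set members as exchangeable with
  the genome-wide coding rate; clustering of coding variants within genes
  is ignored (it would make the test anti-conservative only if credible
  sets preferentially tile gene-dense regions, which LD-based sets do
  not know about).
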