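# Methods

This note documents the statistical models implemented in `pqtlmeta`, the
synthetic world used to validate them, the parameter defaults and why they
were chosen, and the numerical decisions that a maintainer would otherwise
have to reverse-engineer.

## Meta-analysis model

Each cohort supplies per-variant associations (β̂ᵢ, SEᵢ) of a
rank-inverse-normalized protein on effect-allele dosage. The combined
estimate is the fixed-effect inverse-variance weighted mean with weights
wᵢ = 1/SEᵢ² (the STDERR scheme of classical GWAS meta-analysis software):

    β_meta = Σ wᵢ β̂ᵢ / Σ wᵢ,   SE_meta = (Σ wᵢ)^(−1/2),
    Z = β_meta / SE_meta,       P = 2Φ(−|Z|).

The scheme is associative and order-invariant, which gives **exact cohort
subtraction**: removing a contributing cohort c leaves
w_rem = w_meta − w_c and β_rem = (w_meta β_meta − w_c β_c)/w_rem, the
precise meta-analysis of the remaining cohorts. Sample size is propagated
by subtraction; no genomic-control rescaling is applied at this step.
Cochran's Q is reported per variant but never used to switch estimators —
the package is deliberately fixed-effect only.

**X chromosome.** Protein tables must arrive sex-stratified on X: males
are hemizygous and coded 0/1, so both sexes estimate the same per-allele
effect and the two strata can be combined by a second inverse-variance
step. Tables with an `all` stratum on X are rejected at input (for
binary-outcome tables, where the X scan is run per sex and combined
internally, the check is relaxed via `require_x_stratified=False`).

**Harmonization.** Two regimes. Within a consortium the upload format
fixes the strand, so cohort records are aligned by allele labels alone
(direct match, or swap with β → −β and EAF → 1−EAF); palindromic (A/T,
C/G) variants are treated like any other, as METAL does. Across
independent sources (MR exposure vs outcome) strand is unknown:
complement-strand matches are attempted, and palindromic variants are
orientable only by allele-frequency concordance — when either
minor-allele frequency exceeds 0.42 they are excluded as ambiguous.

**Phenotype transform.** The rank-based inverse-normal transform maps
value ranks through Φ⁻¹((r − 3/8)/(n + 1/4)) (Blom offset; ties share the
average rank), producing a mean-0, variance-1 phenotype that depends on
the input only through its ranks.

## Variance partition

A biallelic additive variant with effect-allele frequency f and per-allele
effect β̂ on a unit-variance phenotype contributes 2f(1−f)β̂² under
Hardy–Weinberg equilibrium. Summing over lead variants gives the
phenotypic variance V captured by the discovered pQTL; dividing by an
externally supplied heritability h² gives the fraction of heritability
explained. The report always carries both V and h² rather than a single
rounded ratio, because the appropriate denominator (autosomal-only versus
including X) is a judgment the caller should make explicitly.

## LD statistics, clumping, conditional analysis

r² is the squared Pearson correlation of effect-allele counts in the
reference panel (haplotype-based when phase is available). D′ normalizes
the haplotype-frequency covariance D = p_AB − p_A p_B by its bound; on
unphased genotypes the two-locus haplotype frequency is estimated by EM,
where only double heterozygotes are phase-ambiguous. LD scores are
windowed sums ℓ_j = 1 + Σ_k r̃²_jk with the small-sample adjustment
r̃² = r² − (1 − r²)/(n_ref − 2) and a 1 Mb default window (a practical
proxy for 1 cM).

Clumping is greedy: qualifying variants (P below threshold) are scanned
in ascending-P order (ties broken by chromosome, position, then allele
order); each retained index absorbs remaining qualifying variants on the
same chromosome within the window whose panel r² exceeds the threshold.
Variants absent from the panel are treated as unlinked with a warning.

Joint multi-SNP effects are recovered from marginal summary statistics
plus the panel correlation matrix R. On the standardized scale
(b = β̂ √(2f(1−f))): b_J = R⁻¹ b_m, Var(b_J) = σ²_J diag(R⁻¹)/n with
σ²_J = 1 − b_Jᵀ b_m. Numerical choices: a 10⁻⁶ ridge on R's diagonal; a
10⁻⁶ floor on σ²_J (panel/sample LD mismatch can push it negative); a
condition-number cap of 10⁵ on the regularized R (beyond |r| ≈ 0.99998
the system is declared collinear and the caller told to pre-prune at
r² < 0.9); candidates with r² > 0.9 against the selected set are skipped
during stepwise scans. Secondary signals are admitted by forward
selection on the conditional p-value. The scan reports each admitted
variant's marginal and conditional p so that masking — a variant whose
conditional significance exceeds its marginal one because it is in LD of
opposite orientation with a stronger signal — is directly observable.

## Mendelian randomization

Instruments are genome-wide-significant (P < 5×10⁻⁸) exposure variants,
clumped at r² < 0.001 within a declared cis gene window (clump window
10 Mb — generous, since the cis region spans ~100 kb) or at r² < 0.05
genome-wide (window 1 Mb), then harmonized to the outcome GWAS under the
unknown-strand regime. Each instrument yields a Wald ratio β_y/β_x with
first-order SE |SE_y/β_x|; the IVW estimate is their inverse-variance
weighted mean, equivalently

    β_MR = Σ(β_x β_y / SE_y²) / Σ(β_x² / SE_y²),  SE = (Σ β_x²/SE_y²)^(−1/2).

With a binary outcome β_MR is a log odds ratio per SD of exposure;
exp(β_MR ± 1.96 SE) gives the 95% CI. Fixed-effect first-order weights
are the primary estimator; a multiplicative random-effects option
inflates the SE by max(1, √(Q/(k−1))) since reference implementations
differ on this default. Pleiotropy-robust estimators (Egger, weighted
median) and outlier filtering are deliberately out of scope; the
bidirectional driver instead checks causal direction by instrumenting
each trait in turn, reporting a direction as not-estimable when it has
no eligible instruments.

## Enrichment regression

For each annotation track the model is a per-SNP logistic regression

    logit Pr(P_j < α) = μ + δ ℓ_j + β C_j,   α = 5×10⁻⁸,

with ℓ_j the SNP's LD score (correcting for the extra association signal
a high-LD SNP tags) and C_j ∈ {0,1} membership in the track. β is the log
odds ratio of genome-wide-significant associations inside the annotation.
Fitting is IRLS (statsmodels GLM) to 10⁻⁸ log-likelihood tolerance, max
100 iterations, with observed-information SEs. A constant ℓ column is
dropped automatically, in which case β̂ equals the empirical 2×2 log odds
ratio exactly. Complete separation triggers a Firth (Jeffreys-penalized)
fallback, flagged in the output. Scans across tracks are controlled by
Benjamini–Hochberg FDR at 5%. BED input is 0-based half-open; a SNP at
1-based position p is annotated iff p−1 ∈ [start, end). An optional mask
excludes chr6:25–34 Mb (the MHC region) — default off for synthetic data,
recommended on for real data.

## The synthetic world

The generator emulates a consortium pQTL study at desk scale, and its
defaults are the package's reference study conditions:

| parameter | default | rationale |
|---|---|---|
| cohorts | 3 × 6000 | consortium structure at a size where every declared locus is discoverable at P < 5×10⁻⁸ |
| SNPs | 1800 autosomal + 200 X, 20-SNP blocks | compressed genome; blocks exactly independent |
| LD | AR(1) copula, ρ = 0.6 | closed-form controllable LD decay |
| MAF | Uniform(0.05, 0.5) | common variants, mirroring the MAF > 0.01 analysis filter |
| trans loci | 9 blocks, Σ2f(1−f)β² ≈ 3.9%; plus one masked secondary (same block as the strongest lead, opposite sign, total ≈ 4.1%) | the discovered-loci architecture: ~4% of variance in ~10 autosomal leads, one signal visible only conditionally |
| cis X locus | 3 independent signals, Σ ≈ 1.45% | a dominant lead plus two weaker independent cis instruments |
| heritability target | 0.16 autosomal | filled by a polygenic background of 300 tiny effects placed outside declared-locus blocks |
| causal effect θ | log(1.63) per SD | the protein's effect on the binary outcome |
| outcome | prevalence 0.10, n = 20 000, 3 direct loci | a case-control GWAS with its own loci, so the reverse MR direction has instruments and a well-defined null |
| annotation | base rate 0.10, odds ratio 5 at causal variants | enriched regulatory state |
| LD panel | n_ref = 8000, phased | large enough that the r² < 0.001 cis clumping threshold sits above the panel's sampling-noise floor (≈ χ²₁/n_ref between independent variants); a 1000G-sized panel cannot resolve that threshold |

Haplotypes are simulated per block by thresholding a stationary AR(1)
Gaussian process at Φ⁻¹(1−f_j), so marginal allele frequencies are exact
and within-block LD follows the Gaussian copula (validated against the
bivariate-normal orthant probability by numerical integration). Genotypes
are sums of two haplotypes; males carry one X haplotype. The phenotype is
y = Σ β_j g_j + e with e scaled per sex so Var(y) = 1, then
rank-inverse-normal transformed before regression. Outcome case status is
Bernoulli(expit(α + θy + direct effects)) with α root-solved to the
target prevalence; per-SNP logistic regressions (vectorized Newton,
closed-form 2×2 solves) give log-OR records.

Every artifact is a deterministic function of the seed: variant metadata,
each cohort, the panel, the outcome and the annotations draw from
independent named seed streams, so stages can be regenerated in isolation
and a fixed seed fixes every output byte-for-byte.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: demography and realistic LD decay
(blocks are exactly independent; real genomes have long-range LD and
recombination-rate variation), imputation uncertainty, relatedness and
population stratification (no PCs or covariates are simulated, so the
pipeline's robustness to confounding is untested), assay measurement
error beyond the Gaussian residual, and cohort heterogeneity (a
fixed-effect world by construction). The genomic-control λ of the default
study is far above 1 — with 16% heritability compressed into ~2000 SNPs
at n = 18 000, a large share of variants carry genuine signal — so λ here
is a polygenicity readout, not a confounding diagnostic; the null
calibration test (no effects, h² = 0) confirms λ ≈ 1 absent signal.

## Validation design

Each method is checked against an oracle that does not share its code
path: meta-analysis against pooled individual-level OLS on the identical
data; subtraction against direct re-meta-analysis (machine precision);
joint/conditional fits against multiple regression on the generating
genotypes; clumping against an exhaustive O(m²) greedy re-implementation;
D′ EM against phased counting; the enrichment fit against a closed-form
2×2 log odds ratio and an independent ML optimizer; MR against its known
θ in repeated-simulation coverage, type-I error and reverse-null rate.
Simulation sizes in the test suite (e.g. two-cohort recovery at
n = 10 000, 500-seed calibrations at reduced m) are chosen as the
smallest problems at which the Monte-Carlo tolerances are meaningful.

## Known limitations

- The conditional scan uses the meta-analysis maximum n for every variant;
  per-SNP sample-size heterogeneity is not modeled.
- D′ from EM can be slightly biased at very low MAF with few double
  heterozygotes; r² is always dosage/haplotype-exact.
- The enrichment model assumes SNP-level independence of the outcome
  indicator given (ℓ, C); residual LD correlation between nearby SNPs is
  corrected for in expectation via ℓ but not in the SEs.
- Binary-trait meta-analysis uses the same IVW machinery as quantitative
  traits; no effective-sample-size correction is applied.
- Genotype QC, imputation, liftover and multi-allelic variants are out of
  scope; inputs are assumed clean biallelic SNPs on one genome build.
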