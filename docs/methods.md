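# Methods

`cismr` implements a cis-Mendelian-randomization (MR) plus colocalisation
workflow for circulating protein markers and disease outcomes, operating
entirely on GWAS summary statistics.  This note records the statistical
models, the numerical choices, what the synthetic-data generator does and
does not emulate, and known limitations.

## Input model and harmonisation

Summary statistics are per-variant marginal associations: effect `beta` per
copy of the effect allele (SD units for protein traits, log-odds for binary
outcomes), its standard error, two-sided p-value, effect-allele frequency
(EAF) and sample size.  Only biallelic SNPs are accepted; indels and
multi-allelic records are rejected at ingestion because the analysis is
defined over SNPs and allele reconciliation rules below assume single
nucleotides.

Variants are matched across datasets on (chromosome, position) — rsids vary
across consortia and are used only for reporting.  Allele reconciliation
tries, in order: identity, effect/other swap (negate beta, EAF → 1−EAF),
strand complement, complement plus swap.  Palindromic (A/T, C/G) SNPs cannot
be strand-resolved from alleles: those with minor allele frequency above
0.40 in either trait are dropped; at or below 0.40 they are aligned by
frequency (effect alleles forced to the same side of 0.5).  The frequency
rule is this package's explicit choice for a step that is usually left
implicit; it is wrong with probability that shrinks as MAF moves away from
0.5, which is why the 0.40 cap matters.  Exposure EAF is authoritative when
the traits disagree; disagreement above 0.2 triggers a warning.

LD is computed from a phased reference panel as the signed Pearson
correlation r of effect-allele indicator columns, with columns flipped when
the panel stores the opposite allele, so r carries the same sign convention
as the harmonised betas.

## Multi-study meta-analysis

Per-variant effects across protein GWAS are pooled by fixed-effects inverse
variance: weights w_i = 1/se_i², pooled beta = Σw_i b_i / Σw_i, pooled
se = (Σw_i)^(−1/2).  Cochran's Q = Σw_i (b_i − b_pool)² on χ²(k−1) gives a
per-variant heterogeneity p-value; variants with p_het < 0.001 are removed
before instrument construction, since a cross-study inconsistent pQTL is
more likely an assay or harmonisation artefact than a real signal.
Two-sided p-values use the normal approximation throughout (sample sizes in
this setting are thousands and up).  Studies with >50% participant overlap
must be resolved by the user (exclusion list); no overlap detection is
attempted.  Cross-study agreement is summarised by the Pearson correlation
and sign-concordance of effects over LD-pruned (r² < 0.01) significant SNPs,
aligned to the protein-increasing allele of the anchor study so that shared
allele coding cannot inflate the correlation.

## Instruments

For each protein, candidate instrument SNPs are the cis variants
(gene ± 250 kb, boundaries inclusive) passing MAF ≥ 0.01,
palindrome-MAF ≤ 0.40 and p < 5×10⁻⁸ (strict), greedily pruned to pairwise
r² < 0.10 in ascending p-value order (ties: position, then rsid — the
ordering makes pruning fully deterministic).  Greedy p-ordered pruning was
chosen over window-based clumping because it implements the stated r² rule
with no further assumptions.

Instrument strength: per-SNP variance explained r²_j = 2·EAF_j(1−EAF_j)·b_j²
(per-allele effect on an SD-standardised trait), summed over the pruned set
without an LD cross-term — with residual pairwise r² < 0.10 the
approximation is mild and slightly anti-conservative.  F = [r²/(1−r²)]·
[(n−k−1)/k].  The effective n is supplied per protein in configuration
(meta-analysis n is the default), since pooled GWAS have no single sample
size.

## MR estimation

Single-SNP instruments use the Wald ratio b_y/b_x with the first-order
delta-method SE √(se_y²/b_x² + b_y²·se_x²/b_x⁴); the second term
(exposure uncertainty) is retained because it is cheap and conservative.

Multi-SNP instruments use generalised IVW: with Bx, By the exposure and
outcome beta vectors, D = diag(outcome SEs) and R the signed LD matrix,
Ω = D·R·D and

    beta = (Bxᵀ Ω⁻¹ Bx)⁻¹ Bxᵀ Ω⁻¹ By,   var_base = (Bxᵀ Ω⁻¹ Bx)⁻¹.

Residual heterogeneity Q = (By − Bx·beta)ᵀ Ω⁻¹ (By − Bx·beta) drives a
multiplicative random-effects inflation φ = max(1, Q/(k−1)),
se = √(φ·var_base).  The multiplicative model (rather than additive) is the
standard choice when the inflation rule is stated only as "SEs were
inflated"; the truncation at 1 means the SE never deflates.  A consequence
worth knowing: under the null with valid instruments the test statistic is
Z/√max(1, W) with W ~ χ²_{k−1}/(k−1) independent of Z, so the test is
strictly conservative — exact size 0.038–0.042 for k between 2 and 30 at
nominal 0.05.  With inflation off the estimator reduces exactly to textbook
fixed-effects IVW when R = I (verified to 10⁻¹⁰ in tests).

R is ridge-regularised (+10⁻⁶ on the diagonal) when its smallest eigenvalue
falls below 10⁻⁸, which handles near-duplicate SNPs; a still-singular Ω is a
fatal error reported with its condition number.  Exposure-side uncertainty
is ignored in IVW weights (standard two-sample practice) — a documented
limitation that biases toward the null when instruments are weak.
Leave-one-out re-estimates the effect dropping each SNP in turn (k ≥ 3;
two-SNP sub-fits fall back to the Wald ratio) and flags drops whose estimate
leaves the base 95% CI or flips sign.

ORs and CIs are exp-transformed from the log scale with multiplier 1.96.

## Colocalisation

Per-variant evidence is the Wakefield approximate Bayes factor,
log ABF = ½·ln(V/(V+W)) + z²W/(2(V+W)) with V = se² and W the squared prior
SD of a true effect: 0.2 for quantitative traits and 0.15 for case-control
(log-odds) traits — the defaults of the model family this implements,
exposed in configuration because the trait-type priors actually used in any
given study are rarely stated.

Under the single-causal-variant assumption the five pairwise hypotheses get
evidences by summing variant configurations (all in log space; raw ABFs are
never exponentiated):

    L1 = logΣ_j abf1_j            L2 = logΣ_j abf2_j
    L4 = logΣ_j abf1_j·abf2_j     L3 = log(Σ_j abf1_j · Σ_k abf2_k − e^{L4})

with posteriors ∝ {1, p1·e^L1, p2·e^L2, p1p2·e^L3, p12·e^L4} and priors
p1 = p2 = 10⁻⁴, p12 = 10⁻⁵.  PPH4 > 0.70 is the shared-variant call
threshold.  Both the pairwise and the three-trait posteriors are verified
against brute-force enumeration over causal-variant assignments (m ≤ 12) to
10⁻⁸.

Secondary signals: forward stepwise selection in z-space picks conditionally
independent signals at p < 5×10⁻⁸, with conditional statistics
z_{j|S} = (z_j − r_{jS}R_SS⁻¹z_S)/√(1 − r_{jS}R_SS⁻¹r_{Sj}); betas are
shrunk proportionally and SEs preserved.  This z-space approximation of
conditional-and-joint analysis is valid for aligned, standardised summary
statistics and avoids per-SNP sample-size bookkeeping; collinear variants
(denominator ≤ 10⁻⁶) are skipped with a warning.  Pairwise-conditional
colocalisation runs coloc on every {marginal, per-signal conditional}
combination of the two traits and reports the maximum-PPH4 cell as the
headline (the full grid is retained) — the reduction rule is made explicit
here because published analyses typically report a single PPH4 per pair.

The three-trait extension enumerates the 15 sharing configurations of three
traits (each trait null or causal; causal traits partitioned into groups
sharing one variant), with per-variant priors by group size
p1 = 10⁻⁴, p2 = 10⁻⁶, p3 = 10⁻⁷ and distinct-variant sums computed by
inclusion–exclusion on log-sum-exp terms.

## Evidence tiers, replication, artefact flags

MR p-values are Benjamini–Hochberg adjusted *within* the validation and
discovery arms separately; the arm of a protein–outcome pair is determined
by a prior-evidence score table (score ≥ 0.05 → validation, missing score →
discovery), and the test universe of each arm is every attempted pair,
including those whose colocalisation later fails.  Tiers: q < 0.05 strong,
0.05 ≤ q < 0.20 suggestive, else little (boundaries assigned to the weaker
tier per the half-open intervals).

Replication estimates are pooled with both fixed-effects and
DerSimonian–Laird random-effects (τ² = max(0, (Q−df)/(Σw − Σw²/Σw)),
I² = max(0, (Q−df)/Q)·100); both are always reported, with random-effects
as the headline.

Instrument SNPs that are annotated missense variants, or in LD r² > 0.80
(strict) with one, are flagged as potential aptamer/epitope binding
artefacts; multi-SNP instruments get a revised estimate excluding flagged
SNPs when at least one survives, and flagged single-SNP instruments are
marked unresolvable by exclusion.

## Synthetic data

The generator exists so every stage can be tested against known ground
truth.  A reference panel of phased haplotypes is drawn by thresholding a
stationary AR(1) Gaussian latent process (parameter `ld_decay`) at
variant-specific quantiles with MAF ~ U(0.05, 0.5); diploid genotypes pair
panel haplotypes at random.  Protein GWAS regress a unit-variance trait
(causal genetic score plus noise) on each variant separately, per study,
with optional between-study perturbation of causal effects (`het_sd`).
Binary outcomes come from an individual-level logistic model whose linear
predictor is α × (true genetic exposure score) + direct variant effects +
an intercept solved to hit the case fraction; per-variant logistic
regressions (vectorised Newton–Raphson, validated against statsmodels) give
log-odds summary statistics.  Scenarios h0–h4 mirror the five
colocalisation hypotheses; `h3` places the outcome's causal variant at a
distinct index from the exposure's, `h4` re-uses it via α ≠ 0.

Defaults are desk-scale: 200 variants spaced 1 kb, 1000 haplotypes,
`ld_decay` 0.5, n = 10,000 per trait, two exposure studies, case fraction
0.33, exposure effect 0.3 SD per allele at one causal SNP, and
α = ln(2) for shared scenarios.  The α default is deliberately larger than
effects typically reported for protein–disease pairs because the emulated
study design pairs weak effects with outcome GWAS of 10⁵–10⁶ participants;
at n = 10,000 the same detectability requires a stronger effect.  A fast
approximate mode draws marginal z-statistics directly as
z ~ N(√n·R·b_joint, R) and is used for large replicate counts (type-I
error, recovery); it bypasses genotype sampling, case-control likelihood
and non-collapsibility, all of which are exercised by the individual-level
mode instead.

What the generator does not emulate — hence what passing tests cannot
show about real data: realistic human LD maps and allele-frequency spectra,
imputation error, sample overlap between exposure and outcome GWAS,
population stratification, and assay artefacts (missense flags are tested
with constructed annotation tables only).

## Problem sizes used in the shipped checks

Oracle equivalences use 100 random windows (m ≤ 12) and 1000 random
instruments.  Calibration and recovery use the fast summary mode: 5000 null
replicates and 1000 causal replicates at k = 8, AR(1) ρ = 0.3,
n_exposure = 20,000, n_outcome = 50,000.  Scenario discrimination uses 200
individual-level replicates per scenario at the default sizes.  The
end-to-end determinism check runs a two-protein study twice and compares
output bytes.

## Known limitations

- The multiplicative random-effects test is conservative under the null
  (exact size ≈ 0.039 at k = 8), a direct consequence of truncating φ at 1.
- r² summation without LD cross-terms slightly overstates instrument
  variance explained when residual LD is near the 0.10 bound.
- The z-space conditional analysis assumes one homogeneous sample size per
  trait within a window.
- The single-causal-variant assumption of the colocalisation model is
  inherited wholesale; regions with allelic heterogeneity are handled only
  through the conditional decomposition.
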