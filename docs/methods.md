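# Methods

This note documents the statistical models implemented in `pleioscan`,
the conventions and defaults chosen where the design was genuinely
open, and what the synthetic-data generator does and does not emulate.

## Data model and conventions

Variants are keyed `chr:pos:ref:alt` on GRCh38 with X coded as 23; the
alt allele is always the effect allele. Cross-cohort alignment accepts
a ref/alt swap (β negated, AF complemented); A/T and C/G alleles cannot
be strand-resolved from the alleles alone and are only flagged, since
harmonised panels are assumed. Each `chr:pos:ref:alt` is a distinct
variant — multi-allelic sites are represented as separate records.

p-values are carried in natural-log space throughout
(`scipy.special.log_ndtr` / `ndtri_exp`), so z ↔ p ↔ χ² conversions
round-trip to better than 1e−9 relative error down to p ≈ 1e−300, and
the TSV reader falls back to z = β/se when a printed p-value has
underflowed to 0. Records with missing allele frequency are accepted
but excluded from the √heritability transform and enrichment
calculations, with a warning.

## Meta-analysis

Fixed-effects inverse-variance weighting: β = Σwᵢβᵢ/Σwᵢ with
wᵢ = 1/seᵢ², se = (Σwᵢ)^(−1/2), two-sided normal p on β/se. A variant
present in one cohort only passes through with its β and se untouched
(bit-identically), which is how population-specific low-frequency
alleles enter the combined scan. No heterogeneity statistics or
random-effects model: the pipeline is fixed-effects by design.

## Independent-signal selection

With associations reaching p ≪ 1e−100, a fixed r² cutoff admits false
"independent" peaks: a neighbour at correlation r of a causal variant
carries expected χ² = r²·χ²_causal, so even r² = 0.05 of a χ² = 1000
peak leaves expected χ² = 50. Each selected signal therefore carries a
dynamic threshold

    T = min(0.1, r₅),   r₅ = 5.0 / χ²_signal,

the r² at which the expected residual χ² equals 5. Selection is greedy
per chromosome in decreasing χ² (ties broken by chrom, pos, ref, alt
for determinism); a candidate survives iff

* p < 5×10⁻⁸;
* r² to every already-selected, more significant signal within ±2 Mb is
  **strictly** below that signal's T (equality rejects);
* no selected signal with T < 0.02 lies within 1 Mb (at such extreme
  peaks, small r² values are themselves unreliable, so no secondary is
  trusted at all);
* fewer than two selected signals lie within 1 Mb, unless
  `allow_conditional_third` is set and the candidate remains
  genome-wide significant after conditioning on both simultaneously.

Open details are resolved as follows and exposed in `SelectionConfig`:
all distances are centre-to-centre; the ±2 Mb screen is symmetric
between candidate and selected signal; the per-Mb cap uses sliding
spans anchored at each selected signal; missing LD pairs inside the
window reject the candidate (conservative default, `missing_ld="allow"`
to override); MHC exclusion (6:28510120–33480577) is off by default and
on in replication presets.

Conditional analysis is a summary-statistic approximation rather than
an individual-level refit: on the standardized scale

    z_cond = (z_t − R_tC R_C⁻¹ z_C) / √(1 − R_tC R_C⁻¹ R_Ct),

where R is the signed LD matrix over {target} ∪ conditioning set. The
effective sample size cancels on the z scale; the approximation assumes
the LD panel matches the association sample. Conditioning sets with
near-singular LD (condition number > 1e8) raise rather than return an
unstable estimate.

Locus grouping is single-linkage chaining of selected signals within
1 Mb. Coding-variant tagging reports the coding variant with maximal
r² > 0.95 to each lead; a lead that is itself coding tags itself at
r² = 1.

## Line-model classification

For a set of index variants with effects on two traits, both
transformed to the √heritability scale (β, se multiplied by
√(2·MAF·(1−MAF)), leaving z unchanged), each mixture component g is a
bivariate normal prior on true effects concentrated around a line
through the origin with slope s, scale τ and correlation ρ:

    Σ_g = τ² [ (1+ρ)·u uᵀ + (1−ρ)·v vᵀ ],
    u = (1, s)/√(1+s²),  v = (−s, 1)/√(1+s²).

This rotation construction was chosen so that at s = 1 the prior's
coordinate correlation equals ρ exactly (Σ = τ²[[1,ρ],[ρ,1]]), giving ρ
a concrete interpretation; other parameterizations of "tightness around
the line" exist and may differ in detail. The observed pair adds
independent Gaussian noise diag(se₁², se₂²) — appropriate when the two
scans share no samples; an `err_corr` parameter adds off-diagonal
se₁·se₂·ρ_err for overlapping-sample pairs (default 0).

Defaults mirror standard usage: ρ = 0.99 (a line with modest wobble),
scale initialised so that 95% of pooled |effects| lie within twice the
scale (pooled over both traits — a per-trait rule would give two
numbers where one is needed), scales equal across groups, and EM
optimising only mixture proportions and any free slopes. Free slopes
are parameterized by angle (bounded at ±89.9°) so near-vertical lines
are handled smoothly, updated by bounded 1-D maximisation of the
expected complete-data log-likelihood; the update is only accepted when
it does not decrease the objective, making the procedure a generalised
EM with a provably non-decreasing log-likelihood (asserted each
iteration in tests). Five evenly-spread angle restarts guard against
local optima; ties break by log-likelihood then smallest |slope|.
Convergence: Δloglik < 1e−6 or 1000 iterations.

Model comparison fits one free-slope group against a two-group model
(one slope fixed at 0 for "discovery-only" variants, or both slopes
free for a population-wide quantitative trait) and reports the raw
statistic 2Δloglik. No χ² p-value is attached: the one-group model sits
on the boundary of the two-group parameter space (π = 0), where the
usual asymptotics fail; a heuristic `strong_evidence` flag marks
statistics above 20.

Memberships are sampled by Gibbs (default 10,000 iterations, 1,000
burn-in, seeded): variant labels from their conditional categorical
given π, then π ~ Dirichlet(1 + counts). With π fixed the chain's
marginals equal the closed-form responsibilities — the oracle
equivalence the tests assert. Monte-Carlo standard errors come from 20
batch means. Sharing proportions are estimated on the top half of
discovery associations only (weak associations cannot be assigned
confidently in either direction), as the fraction with shared-group
posterior above 0.8; the p-value filter is applied at this estimation
step, not before fitting. The filter compares significance values
ordinally, so log-scale p-values are accepted where raw ones would
underflow.

## Overlap statistics

Overlap thresholds are exact fractions 0.05/N (comparison-wide) and 1/N
(one expected by chance) of the number N of index variants; printed
two-significant-figure forms come from a formatting helper, never from
rounding inside the computation. Direction consistency compares effect
signs after allele harmonisation; a query β of exactly 0 counts as
neither direction and is reported separately. Contingency enrichment
uses the two-sided Fisher exact test (point-probability method) on
[[a, b−a], [c, d−c]]; both the proportion ratio (a/b)/(c/d) and the
odds ratio are reported since they diverge for common proportions — on
the worked 16/51-vs-32/366 table the proportion ratio is 3.59 and the
odds ratio 4.77, so a rounded "3.5-fold" print is consistent only with
the former. Membership correlations are Spearman with average-rank
ties and the large-sample t approximation for p (checked against a
permutation oracle at small n).

## PRS PheWAS

The score is Σ wᵢ·dosageᵢ standardized to mean 0, s.d. 1 over the
analysed individuals; all odds ratios are per 1 s.d. Weight variants
missing from the dosage matrix would be imputed to the constant 2·AF,
which vanishes under standardization, so they are dropped with a
warning. Per endpoint, a maximum-likelihood logistic regression (IRLS
via statsmodels GLM; the contract is the MLE, not a particular solver)
of case status on score plus covariates; endpoints with fewer than 50
cases (or controls) are excluded and counted; sex-specific endpoints
are fitted within the appropriate sex with the sex covariate dropped.
Separation or non-convergence flags the endpoint without estimates.
Because it is ambiguous whether a Bonferroni denominator should predate
or postdate the case-floor exclusions, thresholds under both
conventions (0.05/configured and 0.05/tested) are attached to every
report. The exclusion rerun removes cases of a named index endpoint
(and re-standardizes the score over the remaining individuals) to break
associations driven purely by sample overlap; the noMHC rerun drops
score weights inside 6:28510120–33480577 before scoring.

## Synthetic-data generator

The generator produces data with exactly the structure the analyses
assume, which makes it a calibration instrument, not a biobank
emulator.

* **LD blocks.** AR(1) mode builds r_ij = λ^|i−j| exactly (PSD by
  construction; optional random per-variant allele-coding signs via a
  congruence transform). Haplotype mode samples a copying Markov chain
  whose copy probability is set per adjacent pair so the allelic
  correlation is λ while marginal frequencies follow a Beta(1,3)-drawn
  MAF (clamped to ≥ 0.01), and reports the empirical correlation of the
  sampled haplotypes (a Gram matrix, hence PSD). Default λ = 0.9 with
  20-kb spacing gives realistic within-block structure; blocks are
  placed on alternating chromosomes 20 Mb apart so they are
  independent by construction.
* **True effects.** Causal bivariate effects are drawn from the
  line-group mixture on the standardized-genotype scale, so the
  √heritability transform in the classifier exactly inverts the
  per-allele conversion and classifier inputs match its prior by
  construction. Additional traits sharing the same discovery effects
  are drawn from the group-conditional normal. Default architecture:
  slopes 0 and 0.43, τ = 0.15, ρ = 0.99, proportions (0.62, 0.38),
  effective sample sizes 3×10⁵ and (for the hormone-like trait with
  disjoint controls) 226,947; observation errors of different traits
  are independent by default.
* **Marginal statistics.** E[z_j] = Σ_c r_jc·z_c (LD spread); noise has
  variance 1/n per variant, drawn with covariance R/n in `"exact"` mode
  (the sampling covariance of marginal estimators under LD, factored
  through an eigenvalue-clipped square root since empirical LD can be
  numerically semi-definite), independently in `"fast"` mode, or
  disabled.
* **Cohorts.** Dosages are two latent-Gaussian-threshold haplotypes per
  individual (marginal AFs exact in expectation; dosage LD somewhat
  attenuated relative to the target R — acceptable because the PheWAS
  stage depends on the score, not on fine LD); endpoints follow
  logit P(case) = α + γ·PRS_std + covariate terms with α solved by
  root-finding to hit a target prevalence.

Not emulated: case-control ascertainment, relatedness, mixed-model
score tests, imputation uncertainty, genotyping batch structure beyond
a dummy covariate, and sample overlap between scans (an error
correlation parameter exists but defaults to independence). Passing
tests therefore demonstrate correctness of the statistical machinery
under its own assumptions, not robustness to the violations real
biobank data exhibit.

## Problem sizes and seeds

The analysis scripts use 120 blocks × 30 variants (one causal each) at
seed 2026 — enough for stable mixture fits and a ~118-signal selection
set while the full pipeline completes in about a minute. The
acceptance script uses 200 random blocks for the selection oracle, 20
replicates × 400 variants for slope recovery (observation se = τ/3),
20 replicates × 417 variants for the sharing estimator, and 1,000 null
endpoints × 2,000 individuals for PheWAS calibration. The sharing
replicates use se = 0.02 ≈ τ/7.5, the scale implied by effective
sample sizes of several hundred thousand, so that top-half variants —
as in a well-powered scan — admit confident assignment. All randomness
flows from explicit seeds; every generator is bit-reproducible given
seed and spec.

## Known limitations

* The conditional-association approximation degrades when the LD panel
  and association sample diverge, exactly as for any summary-statistic
  joint analysis; it is used only to confirm third signals within 1 Mb.
* The dynamic-threshold rule guarantees expected residual χ² ≤ 5 under
  a single-causal-variant model per admitted neighbour; allelic
  heterogeneity at a locus can still produce conservative behaviour
  (suppressed true secondaries) in hard-zone regions.
* The line-model mixture fixes τ and ρ; no posterior uncertainty on
  them is propagated, and k > 2 groups, while supported by the code,
  have no tuned presets.
* Fisher's exact test is conservative for large unbalanced tables;
  the worked examples here are all small enough for exactness to be
  the virtue.
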