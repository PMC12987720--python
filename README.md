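# pleioscan

Summary-statistic analyses for dissecting the genetic architecture of a
complex disease into its pleiotropic components — built for the setting
where a large case-control GWAS (the running example throughout is
autoimmune hypothyroidism in a biobank meta-analysis) is compared
against secondary scans (other autoimmune disease, a quantitative
hormone level, cancer endpoints) using nothing but per-variant summary
statistics, LD matrices and, for the polygenic-score stage, dosages.

It is aimed at statistical geneticists who need the pipeline's pieces
as tested, reusable functions rather than one-off scripts:

1. **Meta-analysis & elementary statistics** (`pleioscan.sumstats`) —
   inverse-variance-weighted fixed-effects meta-analysis
   (β = Σwᵢβᵢ/Σwᵢ, w = 1/se², se = (Σw)^(−1/2)), p/z/χ² conversions
   carried in log space so p-values near 1e−300 survive round trips,
   the √heritability transform (β, se) ↦ (β, se)·√(2·MAF·(1−MAF)), and
   allele-frequency enrichment ratios.
2. **Independent-signal selection** (`pleioscan.signals`) — greedy
   per-chromosome selection of genome-wide-significant (p < 5×10⁻⁸)
   associations with a *dynamic* LD threshold per signal,
   T = min(0.1, 5/χ²), chosen so the expected residual χ² of any
   admitted neighbour stays below 5 (a neighbour at correlation r of a
   causal variant has expected χ² = r²·χ²). Very strong peaks
   (T < 0.02) suppress all secondaries within 1 Mb; at most two signals
   per 1 Mb unless a third survives summary-statistic conditional
   analysis on the first two; 1-Mb locus grouping and r² > 0.95
   coding-variant tagging included.
3. **Line-model classification** (`pleioscan.linemodels`) — a two-group
   Bayesian mixture over bivariate effect sizes where each group
   concentrates true effects around a line through the origin
   (slope s, scale τ, correlation ρ), fitted by EM with free slopes
   optimised on the angle scale, compared by likelihood ratio, with
   Gibbs-sampled membership probabilities and sharing-proportion
   estimates.
4. **Cross-trait overlap statistics** (`pleioscan.overlap`) —
   thresholded overlap counts at 0.05/N and 1/N, direction-of-effect
   partitions, Fisher-exact contingency enrichment, Spearman
   correlation of membership probabilities.
5. **PRS PheWAS** (`pleioscan.phewas`) — standardized polygenic scores
   from dosages and weights, phenome-wide logistic scans with covariate
   adjustment, a 50-case endpoint floor, Bonferroni thresholds, and the
   exclusion / noMHC sensitivity reruns.
6. **Synthetic data** (`pleioscan.simulate`) — LD blocks (AR(1) or
   sampled haplotypes), line-mixture true effects, marginal summary
   statistics with LD-spread and LD-correlated noise, and
   individual-level cohorts with logistic endpoints, so the whole
   pipeline is testable without access-controlled biobank data.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study
(120 LD blocks, one causal variant each, biobank-scale effective sample
sizes; trait 1 is itself an IVW meta-analysis of two cohorts):

```sh
python analysis/01_simulate_study.py
python analysis/02_select_signals.py
python analysis/03_classify_effects.py
python analysis/04_overlap_stats.py
python analysis/05_prs_phewas.py
```

Output of the classification stage (seed 2026):

```
[trait1-trait2] one- vs two-group 2*dLL = 604.4 (strong evidence for 2 groups)
[trait1-trait2] fitted slopes [0.0, 0.435], pi [0.62 0.38], scale init 0.1559
[trait1-trait2] sharing among top half: 37.3% at posterior > 0.8; 24 variants at >= 99% confidence shared
[trait1-trait3] fitted slopes [0.132, 1.001], pi [0.846 0.154], scale init 0.1644
```

The generator placed 38% of causal variants on a slope-0.43 line shared
with trait 2 and drew trait 3 from slopes 0.13/0.99: the two-group fit
decisively beats one group (2ΔlogL = 604), the free slopes land on the
generating values, and the sharing-proportion estimator recovers the
shared fraction among the top half of discovery associations (37.3% at
posterior > 0.8 against a generating 38%). The signal-selection stage
before it reports `118 independent signals in 118 loci`, with the lead
being the true causal variant at 87% of signals, and the PheWAS stage
recovers a generating odds ratio of 1.71 per score s.d. as
`OR 1.673 (1.617-1.731)` while always excluding endpoints with fewer
than 50 cases.

A thin `pleioscan` CLI wraps the same functions
(`pleioscan simulate|signals|classify|overlap|phewas --help`).

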