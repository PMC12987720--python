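"""Synthetic multi-trait GWAS data with the structure the pipeline assumes.

The generator produces, without any external data:

* LD blocks — either an exact AR(1) correlation structure
  (r_ij = lambda^|i-j|, optionally with random per-variant allele-coding
  signs) or haplotypes sampled from a copying Markov chain whose
  empirical allelic correlation is reported as the LD matrix;
* true bivariate effect sizes drawn from line-model groups (lines
  through the origin with group-specific slopes), the generative mirror
  of the classifier prior;
* marginal summary statistics: the expected standardized marginal effect
  at variant j is the LD-spread sum_c r_jc * b_c of the causal effects,
  plus estimation noise of variance 1/n (optionally LD-correlated across
  variants), converted to per-allele units;
* individual-level cohorts (dosages, covariates, binary endpoints driven
  by a standardized polygenic score through a logistic model) for the
  PheWAS stage.

Effects are simulated on the standardized-genotype scale and converted
to per-allele units, so the sqrt(2*maf*(1-maf)) transform applied before
classification exactly inverts the conversion.

All generators accept either an integer seed or a ``numpy.random.Generator``
and are bit-reproducible given the same seed and spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pleioscan.linemodels import LineGroup, group_covariance
from pleioscan.sumstats import LDMatrix, SumStats, Variant, z_to_ln_p


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# LD blocks
# ---------------------------------------------------------------------------

@dataclass
class LDBlockSpec:
    """Specification of one simulated LD block."""

    n_variants: int = 50
    maf_beta: tuple[float, float] = (1.0, 3.0)  # Beta shape pair for MAF draw
    ar1_lambda: float = 0.9                     # adjacent-variant correlation
    random_sign: bool = False                   # random allele-coding signs
    mode: str = "ar1"                           # "ar1" | "haplotype"
    n_haplotypes: int = 10_000                  # haplotype mode population
    chrom: int = 1
    base_pos: int = 1_000_000
    spacing_bp: int = 10_000
    min_maf: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar1_lambda < 1.0:
            raise ValueError(f"ar1 decay must be in [0, 1), got {self.ar1_lambda}")
        if self.mode not in ("ar1", "haplotype"):
            raise ValueError(f"unknown LD mode {self.mode!r}")
        if self.mode == "haplotype" and self.n_haplotypes < 2 * self.n_variants:
            raise ValueError("haplotype mode needs >= 2 * n_variants haplotypes")

    def variant_ids(self) -> list[str]:
        alleles = ["A", "C", "G", "T"]
        out = []
        for i in range(self.n_variants):
            ref, alt = alleles[i % 4], alleles[(i + 1) % 4]
            out.append(Variant(self.chrom, self.base_pos + i * self.spacing_bp,
                               ref, alt).id)
        return out


def _draw_afs(spec: LDBlockSpec, rng: np.random.Generator) -> np.ndarray:
    a, b = spec.maf_beta
    maf = rng.beta(a, b, size=spec.n_variants)
    maf = np.clip(maf, spec.min_maf, 0.5)
    flip = rng.random(spec.n_variants) < 0.5  # alt may be major or minor
    return np.where(flip, 1.0 - maf, maf)


def _sample_haplotypes(af: np.ndarray, lam: float, n_hap: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Copying Markov chain over sites with adjacent allelic correlation lam.

    Site j+1 copies the presence/absence state of site j with a
    probability chosen so the pairwise correlation is lam while the
    marginal frequency stays af[j+1]; otherwise it draws a fresh
    Bernoulli.  Correlation decays roughly as lam^distance.
    """
    m = len(af)
    H = np.empty((n_hap, m), dtype=np.int8)
    H[:, 0] = rng.random(n_hap) < af[0]
    for j in range(1, m):
        p_prev, p_cur = af[j - 1], af[j]
        sd_prev = math.sqrt(p_prev * (1 - p_prev))
        sd_cur = math.sqrt(p_cur * (1 - p_cur))
        c = lam * sd_cur / sd_prev
        c = min(c, 0.999)
        q = (p_cur - c * p_prev) / (1.0 - c)
        q = min(max(q, 0.0), 1.0)
        copy = rng.random(n_hap) < c
        fresh = rng.random(n_hap) < q
        H[:, j] = np.where(copy, H[:, j - 1], fresh)
    return H


def simulate_ld_block(spec: LDBlockSpec, seed=0) -> tuple[LDMatrix, np.ndarray]:
    """Generate one LD block; returns (LDMatrix, alt-allele frequencies).

    AR(1) mode builds r_ij = lambda^|i-j| exactly (positive semidefinite
    by construction); with ``random_sign`` each variant gets a random
    allele-coding sign s_i and r_ij becomes s_i s_j lambda^|i-j| (a
    congruence transform, still PSD).  Haplotype mode samples
    ``n_haplotypes`` haplotypes from the copying chain and reports their
    empirical correlation matrix (a Gram matrix, hence PSD).
    """
    rng = _rng(seed)
    af = _draw_afs(spec, rng)
    vids = spec.variant_ids()
    if spec.mode == "ar1":
        idx = np.arange(spec.n_variants)
        with np.errstate(divide="ignore"):
            r = spec.ar1_lambda ** np.abs(idx[:, None] - idx[None, :])
        if spec.ar1_lambda == 0.0:
            r = np.eye(spec.n_variants)
        if spec.random_sign:
            s = rng.choice([-1.0, 1.0], size=spec.n_variants)
            r = r * np.outer(s, s)
            np.fill_diagonal(r, 1.0)
        return LDMatrix(variants=vids, r=r), af
    # haplotype mode: empirical correlation of sampled haplotypes
    H = _sample_haplotypes(af, spec.ar1_lambda, spec.n_haplotypes, rng)
    af_emp = H.mean(axis=0)
    af_emp = np.clip(af_emp, 1.0 / spec.n_haplotypes, 1.0 - 1.0 / spec.n_haplotypes)
    X = (H - af_emp) / np.sqrt(af_emp * (1.0 - af_emp))
    r = (X.T @ X) / spec.n_haplotypes
    d = np.sqrt(np.diag(r))
    r = r / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(variants=vids, r=r), af_emp


# ---------------------------------------------------------------------------
# Trait architectures and true effects
# ---------------------------------------------------------------------------

@dataclass
class TraitArchitecture:
    """Generative architecture for a pair of traits over simulated blocks."""

    n1: float = 400_000            # trait-1 (discovery) effective sample size
    n2: float = 400_000            # trait-2 (query) effective sample size
    groups: list[LineGroup] = field(default_factory=lambda: [
        LineGroup(slope=0.0, scale=0.15, correlation=0.99, label="trait1_only"),
        LineGroup(slope=0.43, scale=0.15, correlation=0.99, label="shared"),
    ])
    proportions: tuple[float, ...] = (0.62, 0.38)
    causal_per_block: int = 1
    trait_labels: tuple[str, str] = ("trait1", "trait2")

    def __post_init__(self) -> None:
        if len(self.proportions) != len(self.groups):
            raise ValueError("proportions and groups must align")
        if not math.isclose(sum(self.proportions), 1.0, abs_tol=1e-9):
            raise ValueError("proportions must sum to 1")
        if any(p < 0 for p in self.proportions):
            raise ValueError("proportions must be non-negative")


def simulate_effect_pairs(n_variants: int, architecture: TraitArchitecture,
                          seed=0) -> tuple[np.ndarray, np.ndarray]:
    """Draw true bivariate effects from the line-group mixture.

    Returns ``(effects, labels)`` where ``effects`` is (n, 2) on the
    standardized-genotype scale and ``labels`` the 0-based generating
    group per variant — retained as ground truth for recovery checks.
    """
    rng = _rng(seed)
    labels = rng.choice(len(architecture.groups), size=n_variants,
                        p=np.asarray(architecture.proportions, float))
    effects = np.zeros((n_variants, 2))
    for gi, g in enumerate(architecture.groups):
        mask = labels == gi
        k = int(mask.sum())
        if k:
            cov = group_covariance(g)
            effects[mask] = rng.multivariate_normal(np.zeros(2), cov, size=k,
                                                    method="cholesky")
    return effects, labels


def simulate_conditional_trait(b1: np.ndarray, groups: list[LineGroup],
                               proportions, seed=0) -> tuple[np.ndarray, np.ndarray]:
    """Draw a further trait's true effects given existing trait-1 effects.

    Each variant gets a group from ``proportions``; its effect on the new
    trait is drawn from the group's bivariate-normal line prior
    conditioned on the observed b1 (mean b1 * Sigma12/Sigma11, variance
    Sigma22 - Sigma12^2/Sigma11).  This lets several trait pairs share
    one discovery trait, as when one scan is compared against multiple
    secondary phenotypes.  Returns ``(b_new, labels)``.
    """
    rng = _rng(seed)
    b1 = np.asarray(b1, float)
    labels = rng.choice(len(groups), size=b1.shape[0],
                        p=np.asarray(proportions, float))
    out = np.zeros_like(b1)
    for gi, g in enumerate(groups):
        mask = labels == gi
        if not mask.any():
            continue
        cov = group_covariance(g)
        mean = b1[mask] * cov[0, 1] / cov[0, 0]
        var = cov[1, 1] - cov[0, 1] ** 2 / cov[0, 0]
        out[mask] = mean + math.sqrt(max(var, 0.0)) * rng.standard_normal(mask.sum())
    return out, labels


# ---------------------------------------------------------------------------
# Marginal summary statistics
# ---------------------------------------------------------------------------

def simulate_marginal_sumstats(true_effects: np.ndarray, ld: LDMatrix,
                               af: np.ndarray, n: float, seed=0,
                               trait_id: str = "trait",
                               noise: str = "exact") -> SumStats:
    """Marginal GWAS summary statistics over one LD block for one trait.

    ``true_effects`` are causal effects on the standardized-genotype
    scale (zero for non-causal variants).  The expected marginal
    standardized effect at variant j is the LD spread sum_c r_jc * b_c,
    so a neighbour at correlation r of a single causal variant carries
    expected z equal to r times the causal z (and expected chi-square
    r^2 times the causal chi-square).  Estimation noise has variance 1/n
    per variant; ``noise="exact"`` draws it with covariance R/n (the
    sampling covariance of marginal estimates under LD), ``"fast"``
    draws it independently, ``"off"`` disables it.  Per-allele beta and
    se divide by sqrt(2*af*(1-af)).
    """
    rng = _rng(seed)
    b = np.asarray(true_effects, float)
    m = len(ld)
    if b.shape != (m,):
        raise ValueError(f"true_effects shape {b.shape} does not match LD ({m})")
    expected = ld.r @ b
    se_std = 1.0 / math.sqrt(n)
    if noise == "exact":
        # eigenvalue-clipped factor: empirical LD matrices can be
        # numerically semi-definite
        w, V = np.linalg.eigh(ld.r)
        L = V * np.sqrt(np.clip(w, 0.0, None))
        eps = se_std * (L @ rng.standard_normal(m))
    elif noise == "fast":
        eps = se_std * rng.standard_normal(m)
    elif noise == "off":
        eps = np.zeros(m)
    else:
        raise ValueError(f"unknown noise mode {noise!r}")
    beta_std = expected + eps
    scale = np.sqrt(2.0 * af * (1.0 - af))
    beta = beta_std / scale
    se = np.full(m, se_std) / scale
    z = beta_std / se_std
    ln_p = z_to_ln_p(z)
    rows = []
    for j, vid in enumerate(ld.variants):
        v = Variant.parse(vid)
        rows.append({"variant_id": vid, "chrom": v.chrom, "pos": v.pos,
                     "ref": v.ref, "alt": v.alt, "beta": beta[j], "se": se[j],
                     "pval": math.exp(ln_p[j]), "af": af[j],
                     "n_cases": np.nan, "n_controls": np.nan,
                     "ln_pval": ln_p[j]})
    ss = SumStats(trait_id=trait_id, df=pd.DataFrame(rows))
    ss.noise_mode = noise  # type: ignore[attr-defined]
    return ss


def effective_n(n_cases: float, n_controls: float) -> float:
    """Effective sample size of a case-control design: 4/(1/ca + 1/co)."""
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


# ---------------------------------------------------------------------------
# Multi-block two-trait study
# ---------------------------------------------------------------------------

@dataclass
class StudySim:
    """A complete simulated two-trait study over many LD blocks."""

    sumstats1: SumStats
    sumstats2: SumStats
    ld_blocks: list[LDMatrix]
    true_effects: np.ndarray   # (n_variants_total, 2) standardized scale
    labels: np.ndarray         # generating group per variant (-1 = non-causal)
    causal_ids: list[str]


def simulate_two_trait_study(n_blocks: int, architecture: TraitArchitecture,
                             block_spec: LDBlockSpec | None = None, seed=0,
                             noise: str = "exact") -> StudySim:
    """Simulate paired summary statistics across independent LD blocks.

    Each block carries ``architecture.causal_per_block`` causal variants
    (positions drawn uniformly) whose bivariate true effects come from
    the line-group mixture; blocks are spaced far apart on alternating
    chromosome arms so they are LD- and window-independent.
    """
    rng = _rng(seed)
    base = block_spec or LDBlockSpec()
    ss1_parts, ss2_parts, blocks = [], [], []
    all_effects, all_labels, causal_ids = [], [], []
    for bi in range(n_blocks):
        spec = LDBlockSpec(**{**base.__dict__,
                              "chrom": (bi % 22) + 1,
                              "base_pos": base.base_pos + (bi // 22) * 20_000_000})
        ld, af = simulate_ld_block(spec, rng)
        eff, lab = simulate_effect_pairs(architecture.causal_per_block,
                                         architecture, rng)
        b1 = np.zeros(len(ld))
        b2 = np.zeros(len(ld))
        lab_full = np.full(len(ld), -1)
        pos = rng.choice(len(ld), size=architecture.causal_per_block, replace=False)
        b1[pos], b2[pos] = eff[:, 0], eff[:, 1]
        lab_full[pos] = lab
        causal_ids.extend(ld.variants[p] for p in pos)
        ss1_parts.append(simulate_marginal_sumstats(
            b1, ld, af, architecture.n1, rng, architecture.trait_labels[0], noise))
        ss2_parts.append(simulate_marginal_sumstats(
            b2, ld, af, architecture.n2, rng, architecture.trait_labels[1], noise))
        blocks.append(ld)
        all_effects.append(np.column_stack([b1, b2]))
        all_labels.append(lab_full)
    df1 = pd.concat([s.df for s in ss1_parts], ignore_index=True)
    df2 = pd.concat([s.df for s in ss2_parts], ignore_index=True)
    return StudySim(
        sumstats1=SumStats(architecture.trait_labels[0], df1),
        sumstats2=SumStats(architecture.trait_labels[1], df2),
        ld_blocks=blocks,
        true_effects=np.vstack(all_effects),
        labels=np.concatenate(all_labels),
        causal_ids=causal_ids,
    )


# ---------------------------------------------------------------------------
# Two-population allele frequencies (enrichment test bed)
# ---------------------------------------------------------------------------

def simulate_two_population_af(af_target: np.ndarray, seed=0,
                               log_ratio_sd: float = 1.0,
                               p_absent: float = 0.05) -> np.ndarray:
    """Reference-population AFs with log-normal divergence from the target.

    With probability ``p_absent`` the allele is absent from the reference
    (frequency exactly 0), exercising the infinite-enrichment path.
    """
    rng = _rng(seed)
    af_target = np.asarray(af_target, float)
    ratio = np.exp(rng.normal(0.0, log_ratio_sd, size=af_target.shape))
    af_ref = np.clip(af_target / ratio, 0.0, 0.999)
    absent = rng.random(af_target.shape) < p_absent
    return np.where(absent, 0.0, af_ref)


# ---------------------------------------------------------------------------
# Individual-level cohort for the PheWAS stage
# ---------------------------------------------------------------------------

@dataclass
class CohortSim:
    """Simulated individual-level cohort: dosages, covariates, endpoints."""

    dosages: pd.DataFrame    # individuals x variants, values in {0,1,2}
    covariates: pd.DataFrame  # sex, age, age2, batch dummies, PCs
    endpoints: pd.DataFrame  # individuals x endpoints, 0/1
    prs_true: np.ndarray     # standardized generating PRS
    gamma: dict[str, float]  # ground-truth log-OR per endpoint


def simulate_dosages(af: np.ndarray, ld: LDMatrix, n_individuals: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Dosages as the sum of two latent-Gaussian-threshold haplotypes."""
    m = len(af)
    w, V = np.linalg.eigh(ld.r)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    from scipy.stats import norm
    thresh = norm.ppf(af)
    dos = np.zeros((n_individuals, m), dtype=np.int8)
    for _ in range(2):
        z = rng.standard_normal((n_individuals, m)) @ L.T
        dos += (z < thresh).astype(np.int8)
    return dos


def simulate_cohort(af: np.ndarray, ld: LDMatrix, prs_weights: np.ndarray,
                    n_individuals: int = 10_000,
                    gamma: dict[str, float] | float = 0.0,
                    prevalence: float | dict[str, float] = 0.05,
                    n_null_endpoints: int = 0,
                    covariate_effects: dict[str, float] | None = None,
                    seed=0) -> CohortSim:
    """Simulate a cohort with endpoints driven by a polygenic score.

    Each endpoint e follows logit P(case) = alpha_e + gamma_e * PRS_std
    + covariate terms, with alpha_e set so the expected prevalence
    matches ``prevalence``.  ``gamma`` may be a single value (one
    endpoint named "D1") or a dict of endpoint -> log-OR per PRS s.d.;
    ``n_null_endpoints`` appends endpoints N1..Nk with gamma = 0.
    """
    rng = _rng(seed)
    if isinstance(gamma, (int, float)):
        gamma = {"D1": float(gamma)}
    gamma = dict(gamma)
    for i in range(n_null_endpoints):
        gamma[f"N{i + 1}"] = 0.0

    dos = simulate_dosages(np.asarray(af, float), ld, n_individuals, rng)
    raw = dos @ np.asarray(prs_weights, float)
    sd = raw.std()
    prs = (raw - raw.mean()) / (sd if sd > 0 else 1.0)

    sex = rng.integers(0, 2, n_individuals)
    age = rng.normal(60.0, 10.0, n_individuals)
    batch = rng.integers(0, 2, n_individuals)
    pcs = rng.standard_normal((n_individuals, 6))
    cov = pd.DataFrame({"sex": sex, "age": age, "age2": age ** 2,
                        "batch": batch,
                        **{f"PC{i + 1}": pcs[:, i] for i in range(6)}})
    cov_eff = covariate_effects or {}
    lin_cov = np.zeros(n_individuals)
    for name, eff in cov_eff.items():
        x = cov[name].to_numpy(dtype=float)
        lin_cov += eff * (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)

    endpoints = {}
    for name, g in gamma.items():
        prev = prevalence[name] if isinstance(prevalence, dict) else prevalence
        alpha = _solve_intercept(prev, g * prs + lin_cov)
        p = 1.0 / (1.0 + np.exp(-(alpha + g * prs + lin_cov)))
        endpoints[name] = (rng.random(n_individuals) < p).astype(np.int8)
    dosdf = pd.DataFrame(dos, columns=ld.variants)
    return CohortSim(dosages=dosdf, covariates=cov,
                     endpoints=pd.DataFrame(endpoints),
                     prs_true=prs, gamma=gamma)


def _solve_intercept(prevalence: float, linpred: np.ndarray) -> float:
    """Intercept making mean sigmoid(alpha + linpred) equal the prevalence."""
    from scipy.optimize import brentq
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")

    def f(a):
        return np.mean(1.0 / (1.0 + np.exp(-(a + linpred)))) - prevalence

    return float(brentq(f, -30.0, 30.0))
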