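"""Polygenic-score construction and phenome-wide logistic association scan.

The PRS is a weighted sum of alt-allele dosages, standardized to mean 0
and s.d. 1 over the analysed individuals, so every reported odds ratio
is per 1 s.d. of score.  The scan fits, per binary endpoint, a logistic
regression of case status on the standardized PRS plus covariates
(maximum likelihood via iteratively reweighted least squares), skipping
endpoints with fewer than 50 cases and restricting sex-specific
endpoints to the appropriate sex.  Two sensitivity modes mirror common
practice: an exclusion scan that first removes cases of a named index
endpoint, and a noMHC scan that drops score weights inside the MHC
(chr6:28510120-33480577, GRCh38).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from pleioscan.sumstats import Variant

logger = logging.getLogger(__name__)

MHC_REGION = (6, 28_510_120, 33_480_577)


@dataclass
class PrsWeights:
    """Per-alt-allele score weights (externally derived)."""

    df: pd.DataFrame  # columns: variant_id, weight
    provenance: str = ""

    def __post_init__(self) -> None:
        if not {"variant_id", "weight"} <= set(self.df.columns):
            raise ValueError("weights need variant_id and weight columns")
        if self.df["variant_id"].duplicated().any():
            raise ValueError("duplicate variant ids in weights")

    @classmethod
    def read(cls, path, provenance: str = "") -> "PrsWeights":
        return cls(pd.read_csv(path, sep="\t", comment="#"), provenance or str(path))

    def exclude_region(self, region: tuple[int, int, int] = MHC_REGION) -> "PrsWeights":
        chrom, lo, hi = region

        def inside(vid: str) -> bool:
            v = Variant.parse(vid)
            return v.chrom == chrom and lo <= v.pos <= hi

        keep = ~self.df["variant_id"].map(inside)
        return PrsWeights(self.df.loc[keep].reset_index(drop=True),
                          provenance=f"{self.provenance} (region-excluded)")


class EmptyScoreError(ValueError):
    """No weight variant overlaps the dosage matrix."""


def compute_prs(dosages: pd.DataFrame, weights: PrsWeights,
                exclude_region: tuple[int, int, int] | None = None,
                missing_policy: str = "impute_af") -> np.ndarray:
    """Standardized polygenic score from a dosage matrix.

    ``dosages`` is individuals x variants (columns named by variant id,
    values 0/1/2 alt-allele counts).  Weight variants absent from the
    matrix would conventionally be imputed to a constant 2*af dosage,
    which vanishes under standardization, so both policies
    (``"impute_af"`` and ``"drop"``) reduce to dropping them with a
    warning.  Raises :class:`EmptyScoreError` when no weight variant
    overlaps or the score has zero variance (standardization
    undefined).  The score is invariant to variant order.
    """
    w = weights if exclude_region is None else weights.exclude_region(exclude_region)
    present = w.df.loc[w.df["variant_id"].isin(dosages.columns)]
    n_missing = len(w.df) - len(present)
    if present.empty:
        raise EmptyScoreError("no weight variant present in the dosage matrix")
    if n_missing:
        logger.warning("%d/%d weight variants missing from dosages (%s policy)",
                       n_missing, len(w.df), missing_policy)
    X = dosages[present["variant_id"]].to_numpy(dtype=float)
    raw = X @ present["weight"].to_numpy(dtype=float)
    sd = raw.std()
    if sd == 0:
        raise EmptyScoreError("score has zero variance; cannot standardize")
    return (raw - raw.mean()) / sd


@dataclass
class PhewasResult:
    """Logistic association of one endpoint with the standardized PRS."""

    endpoint: str
    n_cases: int
    n_controls: int
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    pvalue: float | None
    sex_restriction: str = "all"    # "all" | "male" | "female"
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.excluded:
            assert self.odds_ratio is None and self.pvalue is None
        elif self.odds_ratio is not None and self.ci_low is not None:
            assert self.ci_low <= self.odds_ratio <= self.ci_high


@dataclass
class PhewasConfig:
    min_cases: int = 50
    ci_level: float = 0.95
    covariate_columns: list[str] | None = None   # None = all columns
    n_endpoints_configured: int | None = None    # Bonferroni denominator
    sex_column: str = "sex"                      # 1 = female, 0 = male


def phenotype_exclusion(endpoints: pd.DataFrame,
                        index_endpoint: str) -> np.ndarray:
    """Boolean keep-mask removing cases of the index endpoint.

    Used by the exclusion scan to break associations that arise only
    through sample overlap with the index condition.  Raises when the
    endpoint is unknown or when nobody would remain.
    """
    if index_endpoint not in endpoints.columns:
        raise KeyError(f"unknown endpoint {index_endpoint!r}")
    keep = endpoints[index_endpoint].to_numpy() == 0
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("all individuals are cases of the index endpoint")
    logger.info("exclusion mode: removed %d cases of %s", n_removed, index_endpoint)
    return keep


def run_phewas(scores: np.ndarray, endpoints: pd.DataFrame,
               covariates: pd.DataFrame,
               config: PhewasConfig | None = None,
               sex_restrictions: dict[str, str] | None = None,
               exclude_endpoint: str | None = None) -> pd.DataFrame:
    """Phenome-wide logistic scan of a standardized score.

    Per endpoint: restrict to the appropriate sex when the endpoint is
    sex-specific, drop endpoints with fewer than ``min_cases`` cases (or
    fewer than ``min_cases`` controls, which is equally uninformative),
    then fit case ~ score + covariates by maximum-likelihood logistic
    regression.  Separation or non-convergence flags the endpoint
    without estimates.  The returned frame carries Bonferroni thresholds
    under both denominator conventions (endpoints configured vs
    endpoints actually tested) as frame attributes.
    """
    config = config or PhewasConfig()
    sex_restrictions = sex_restrictions or {}
    scores = np.asarray(scores, float)
    if exclude_endpoint is not None:
        keep = phenotype_exclusion(endpoints, exclude_endpoint)
        scores = scores[keep]
        endpoints = endpoints.loc[keep].reset_index(drop=True)
        covariates = covariates.loc[keep].reset_index(drop=True)
        # re-standardize over the analysed individuals
        scores = (scores - scores.mean()) / scores.std()

    cov_cols = config.covariate_columns or list(covariates.columns)
    zcrit = stats.norm.ppf(0.5 + config.ci_level / 2.0)
    results: list[PhewasResult] = []
    for ep in endpoints.columns:
        if exclude_endpoint is not None and ep == exclude_endpoint:
            continue
        restrict = sex_restrictions.get(ep, "all")
        mask = np.ones(len(endpoints), dtype=bool)
        if restrict == "female":
            mask = covariates[config.sex_column].to_numpy() == 1
        elif restrict == "male":
            mask = covariates[config.sex_column].to_numpy() == 0
        y = endpoints[ep].to_numpy()[mask]
        n_cases, n_controls = int(y.sum()), int(len(y) - y.sum())
        if n_cases < config.min_cases or n_controls < config.min_cases:
            results.append(PhewasResult(
                endpoint=ep, n_cases=n_cases, n_controls=n_controls,
                odds_ratio=None, ci_low=None, ci_high=None, pvalue=None,
                sex_restriction=restrict, excluded=True,
                exclusion_reason=f"<{config.min_cases} cases"
                if n_cases < config.min_cases else f"<{config.min_cases} controls"))
            continue
        cols = [c for c in cov_cols if c != config.sex_column or restrict == "all"]
        X = np.column_stack([scores[mask],
                             covariates.loc[mask, cols].to_numpy(dtype=float)])
        X = sm.add_constant(X, prepend=True)
        try:
            with np.errstate(all="ignore"):
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            beta = float(fit.params[1])
            se = float(fit.bse[1])
            if not (math.isfinite(beta) and math.isfinite(se)) or se > 50:
                raise ValueError("unstable fit (quasi-separation)")
            results.append(PhewasResult(
                endpoint=ep, n_cases=n_cases, n_controls=n_controls,
                odds_ratio=math.exp(beta),
                ci_low=math.exp(beta - zcrit * se),
                ci_high=math.exp(beta + zcrit * se),
                pvalue=float(fit.pvalues[1]), sex_restriction=restrict))
        except (Exception,) as exc:  # perfect separation, singular design
            logger.warning("endpoint %s not estimable: %s", ep, exc)
            results.append(PhewasResult(
                endpoint=ep, n_cases=n_cases, n_controls=n_controls,
                odds_ratio=None, ci_low=None, ci_high=None, pvalue=None,
                sex_restriction=restrict, excluded=True,
                exclusion_reason=f"fit failed: {exc}"))

    out = pd.DataFrame([r.__dict__ for r in results])
    n_tested = int((~out["excluded"]).sum()) if len(out) else 0
    n_conf = config.n_endpoints_configured or len(out)
    out.attrs["bonferroni_configured"] = 0.05 / n_conf if n_conf else math.nan
    out.attrs["bonferroni_tested"] = 0.05 / n_tested if n_tested else math.nan
    out.attrs["n_tested"] = n_tested
    out.attrs["n_excluded"] = int(len(out) - n_tested)
    return out
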