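"""Cross-trait lookup statistics at index variants.

Given the index variants of a discovery trait and summary statistics of
a query trait, counts how many index variants associate with the query
at two thresholds derived from the number of index variants N:
0.05/N (Bonferroni, "comparison-wide") and 1/N (one expected by
chance), partitions the lenient overlaps by direction of effect, and
provides contingency enrichment (Fisher exact) and rank correlation of
group-membership probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pleioscan.signals import IndexSignal
from pleioscan.sumstats import AlleleMismatchError, SumStats, Variant, align_to


def format_sig(x: float, digits: int = 2) -> str:
    """Round to ``digits`` significant figures, as printed in reports."""
    if x == 0 or not math.isfinite(x):
        return str(x)
    from decimal import Decimal
    q = round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)
    return f"{Decimal(repr(q)):f}" if 1e-4 <= abs(q) < 1e6 else f"{q:.{digits - 1}e}"


@dataclass
class OverlapReport:
    """Thresholded overlap of a query trait at discovery index variants."""

    n_index: int
    strict_threshold: float        # 0.05 / n_index
    lenient_threshold: float       # 1 / n_index
    n_strict: int
    n_lenient: int
    n_same_direction: int          # among lenient overlaps
    n_opposite_direction: int
    n_zero_beta: int               # query beta exactly 0: neither direction
    missing_ids: list[str]
    table: pd.DataFrame            # per-variant p_query / concordance

    def __post_init__(self) -> None:
        assert self.n_strict <= self.n_lenient <= self.n_index
        assert (self.n_same_direction + self.n_opposite_direction
                + self.n_zero_beta == self.n_lenient)

    def summary(self) -> str:
        return (
            f"{self.n_strict} of the {self.n_index} index variants show "
            f"P < {format_sig(self.strict_threshold)} (0.05/{self.n_index}) "
            f"and {self.n_lenient} P < {format_sig(self.lenient_threshold)} "
            f"(1/{self.n_index}), including {self.n_same_direction} of "
            f"{self.n_lenient} with the same direction of effect"
            f" ({self.n_opposite_direction} opposite)."
        )


def overlap_counts(index_signals: list[IndexSignal] | list[str],
                   index_sumstats: SumStats,
                   query: SumStats) -> OverlapReport:
    """Count query-trait associations at the discovery index variants.

    The query record at each index variant is allele-harmonised to the
    index coding (ref/alt swaps flip the query beta) before comparing
    directions of effect.  Index variants absent from the query are
    listed in ``missing_ids`` and excluded from every count.
    """
    if not index_signals:
        raise ValueError("need at least one index variant")
    ids = [s.variant_id if isinstance(s, IndexSignal) else s for s in index_signals]
    n_index = len(ids)
    strict = 0.05 / n_index
    lenient = 1.0 / n_index
    ln_strict, ln_lenient = math.log(strict), math.log(lenient)

    qdf = query.df.set_index("variant_id")
    idf = index_sumstats.df.set_index("variant_id")
    rows, missing = [], []
    for vid in ids:
        target = Variant.parse(vid)
        qrow = None
        if vid in qdf.index:
            qrow = qdf.loc[vid]
            q_beta, q_lnp = float(qrow["beta"]), float(qrow["ln_pval"])
        else:
            swapped = Variant(target.chrom, target.pos, target.alt, target.ref).id
            if swapped in qdf.index:
                qrow = qdf.loc[swapped]
                q_beta, q_lnp = -float(qrow["beta"]), float(qrow["ln_pval"])
        if qrow is None:
            missing.append(vid)
            continue
        i_beta = float(idf.loc[vid, "beta"]) if vid in idf.index else math.nan
        concord = ("zero" if q_beta == 0 or i_beta == 0 or math.isnan(i_beta)
                   else ("same" if math.copysign(1, q_beta) == math.copysign(1, i_beta)
                         else "opposite"))
        rows.append({"variant_id": vid, "ln_p_query": q_lnp,
                     "p_query": math.exp(q_lnp), "beta_index": i_beta,
                     "beta_query": q_beta, "concordance": concord,
                     "strict": q_lnp < ln_strict, "lenient": q_lnp < ln_lenient})
    table = pd.DataFrame(rows)
    if table.empty:
        table = pd.DataFrame(columns=["variant_id", "ln_p_query", "p_query",
                                      "beta_index", "beta_query", "concordance",
                                      "strict", "lenient"])
    len_mask = table["lenient"] if len(table) else pd.Series(dtype=bool)
    return OverlapReport(
        n_index=n_index,
        strict_threshold=strict, lenient_threshold=lenient,
        n_strict=int(table["strict"].sum()) if len(table) else 0,
        n_lenient=int(len_mask.sum()) if len(table) else 0,
        n_same_direction=int(((table["concordance"] == "same") & len_mask).sum()) if len(table) else 0,
        n_opposite_direction=int(((table["concordance"] == "opposite") & len_mask).sum()) if len(table) else 0,
        n_zero_beta=int(((table["concordance"] == "zero") & len_mask).sum()) if len(table) else 0,
        missing_ids=missing, table=table)


@dataclass(frozen=True)
class EnrichmentResult:
    prop1: float
    prop2: float
    ratio: float          # prop1 / prop2; inf flagged when prop2 == 0
    ratio_infinite: bool
    odds_ratio: float
    fisher_p: float


def contingency_enrichment(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """Enrichment of a-of-b over c-of-d with a two-sided Fisher exact test.

    Builds the 2x2 table [[a, b-a], [c, d-c]] and reports the proportion
    ratio (a/b)/(c/d) alongside the exact p-value (two-sided by the
    point-probability method).  Note the proportion ratio and the odds
    ratio differ for common proportions; both are returned.
    """
    for name, x in (("a", a), ("b", b), ("c", c), ("d", d)):
        if x < 0 or x != int(x):
            raise ValueError(f"{name} must be a non-negative integer")
    if a > b or c > d:
        raise ValueError("need a <= b and c <= d (a of b vs c of d)")
    if b == 0 or d == 0:
        raise ValueError("denominators must be positive")
    prop1, prop2 = a / b, c / d
    infinite = prop2 == 0 and prop1 > 0
    ratio = math.inf if infinite else (math.nan if prop1 == prop2 == 0
                                       else prop1 / prop2)
    odds, p = stats.fisher_exact([[a, b - a], [c, d - c]], alternative="two-sided")
    return EnrichmentResult(prop1=prop1, prop2=prop2, ratio=ratio,
                            ratio_infinite=infinite, odds_ratio=float(odds),
                            fisher_p=float(p))


def membership_correlation(probs_a: np.ndarray, probs_b: np.ndarray) -> dict:
    """Spearman rank correlation between two membership-probability vectors.

    Average ranks for ties; p-value from the large-sample t
    approximation.  Raises on constant input (undefined correlation).
    """
    a = np.asarray(probs_a, float)
    b = np.asarray(probs_b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two aligned vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(a, b)
    return {"spearman_rho": float(rho), "p": float(p), "n": len(a)}


def disjointness_check(set_a: set | list, set_b: set | list) -> int:
    """Number of ids shared by two high-confidence assignment sets."""
    return len(set(set_a) & set(set_b))
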