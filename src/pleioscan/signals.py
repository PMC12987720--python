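"""Greedy dynamic-LD-threshold selection of independent GWAS signals.

A fixed r-squared cutoff (e.g. 0.05) misbehaves when associations reach
p-values below 1e-100: even tiny residual LD to such a peak carries
genome-wide-significant expected signal, because the expected chi-square
of an LD neighbour is r^2 times the chi-square of the causal variant.
Each selected signal therefore gets a dynamic threshold

    T = min(0.1, r5),   r5 = 5.0 / chisq_lead,

the r^2 at which the expected residual chi-square is 5.  Candidates are
taken per chromosome in decreasing significance; a candidate survives
only if its r^2 to every previously selected, more significant signal
within +-2 Mb is strictly below that signal's T.  Where T < 0.02 (very
strong peaks, where small r^2 values are themselves unreliable) no
secondary signal is allowed within 1 Mb at all, and at most two signals
are reported per 1 Mb unless a third is confirmed by conditional
analysis on the first two simultaneously at genome-wide significance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pleioscan.sumstats import (
    LDMatrix,
    SumStats,
    chisq_to_ln_p,
    ln_p_to_z,
    z_to_ln_p,
)

logger = logging.getLogger(__name__)

#: MHC region on GRCh38, conventionally excluded from signal counting
MHC_REGION = (6, 28_510_120, 33_480_577)


@dataclass
class SelectionConfig:
    """Tuning constants of the independent-signal definition."""

    gws_threshold: float = 5e-8
    window_bp: int = 2_000_000
    t_cap: float = 0.1
    residual_chisq: float = 5.0
    hard_zone_t: float = 0.02
    hard_zone_bp: int = 1_000_000
    per_mb_cap: int = 2
    per_mb_span: int = 1_000_000
    allow_conditional_third: bool = False
    conditional_n_eff: float | None = None
    mhc_exclusion: bool = False
    mhc_region: tuple[int, int, int] = MHC_REGION
    missing_ld: str = "reject"  # candidate fate when an LD pair is unknown

    def __post_init__(self) -> None:
        for name in ("gws_threshold", "t_cap", "residual_chisq", "hard_zone_t"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hard_zone_t > self.t_cap:
            raise ValueError("hard_zone_t must not exceed t_cap")
        if self.missing_ld not in ("reject", "allow"):
            raise ValueError("missing_ld must be 'reject' or 'allow'")


@dataclass
class IndexSignal:
    """One selected LD-independent association."""

    variant_id: str
    chrom: int
    pos: int
    ln_pvalue: float
    chisq: float
    t_threshold: float
    rank: int
    locus_id: int = -1
    conditional_flag: str = "none"   # "none" | "confirmed_third"
    coding_variant: str | None = None
    coding_r2: float | None = None

    @property
    def pvalue(self) -> float:
        return math.exp(self.ln_pvalue)


def dynamic_threshold(chisq_lead: float, config: SelectionConfig | None = None) -> float:
    """Per-signal dynamic r^2 threshold T = min(t_cap, residual_chisq/chisq)."""
    config = config or SelectionConfig()
    if not chisq_lead > 0:
        raise ValueError(f"chi-square must be positive, got {chisq_lead}")
    return min(config.t_cap, config.residual_chisq / chisq_lead)


class MissingLDError(KeyError):
    """An r^2 needed by the selection rules is not in the LD panel."""


def _pair_r2(ld_lookup, vid_a: str, vid_b: str) -> float | None:
    """Signed-correlation lookup squared; None when the pair is unknown."""
    r = ld_lookup(vid_a, vid_b)
    return None if r is None else r * r


def _make_ld_lookup(ld: LDMatrix | list[LDMatrix] | dict):
    """Normalise the accepted LD inputs to a pairwise r lookup."""
    if isinstance(ld, LDMatrix):
        blocks = [ld]
    elif isinstance(ld, dict):
        blocks = list(ld.values())
    else:
        blocks = list(ld)
    owner: dict[str, LDMatrix] = {}
    for b in blocks:
        for v in b.variants:
            owner[v] = b

    def lookup(a: str, b: str) -> float | None:
        blk = owner.get(a)
        if blk is None or b not in blk:
            blk_b = owner.get(b)
            if blk_b is not None and a in blk_b:
                blk = blk_b
            else:
                # variants on distinct simulated blocks are unlinked
                return 0.0 if (a in owner and b in owner and owner[a] is not owner[b]) else None
        return blk.pair_r(a, b)

    return lookup


def select_independent_signals(sumstats: SumStats, ld,
                               config: SelectionConfig | None = None,
                               ) -> list[IndexSignal]:
    """Greedy per-chromosome selection of LD-independent associations.

    Candidates (p < ``gws_threshold``) are visited in decreasing
    chi-square, ties broken by (chrom, pos, ref, alt).  A candidate is
    selected iff

    a. it is genome-wide significant;
    b. r^2 to every already-selected, more significant signal within
       +-``window_bp`` is strictly below that signal's dynamic T;
    c. no already-selected signal with T < ``hard_zone_t`` lies within
       ``hard_zone_bp``;
    d. fewer than ``per_mb_cap`` selected signals lie within
       ``per_mb_span`` — unless ``allow_conditional_third`` and the
       candidate stays genome-wide significant after conditioning on all
       of them simultaneously (flagged ``confirmed_third``).

    Unknown LD pairs inside the window reject the candidate by default
    (``missing_ld="reject"``, the conservative choice) or are treated as
    unlinked with ``"allow"``.  Optionally drops candidates inside the
    MHC region first.  Output order is selection (rank) order.
    """
    config = config or SelectionConfig()
    lookup = _make_ld_lookup(ld)
    df = sumstats.df
    ln_thresh = math.log(config.gws_threshold)
    cand = df.loc[df["ln_pval"] < ln_thresh,
                  ["variant_id", "chrom", "pos", "ref", "alt", "ln_pval"]].copy()
    if config.mhc_exclusion:
        c, lo, hi = config.mhc_region
        inside = (cand["chrom"] == c) & (cand["pos"] >= lo) & (cand["pos"] <= hi)
        cand = cand.loc[~inside]
    if cand.empty:
        return []
    z = ln_p_to_z(cand["ln_pval"].to_numpy())
    cand["chisq"] = np.square(z)
    cand = cand.sort_values(["chisq", "chrom", "pos", "ref", "alt"],
                            ascending=[False, True, True, True, True],
                            kind="mergesort")

    selected: list[IndexSignal] = []
    by_chrom: dict[int, list[IndexSignal]] = {}

    for row in cand.itertuples(index=False):
        chrom_sel = by_chrom.setdefault(int(row.chrom), [])
        ok = True
        flag = "none"
        near_cap: list[IndexSignal] = []
        for s in chrom_sel:
            dist = abs(s.pos - row.pos)
            if dist <= config.window_bp:
                r2 = _pair_r2(lookup, row.variant_id, s.variant_id)
                if r2 is None:
                    if config.missing_ld == "reject":
                        logger.warning("missing LD %s-%s: candidate rejected",
                                       row.variant_id, s.variant_id)
                        ok = False
                        break
                    r2 = 0.0
                if r2 >= s.t_threshold:          # strict: equality rejects
                    ok = False
                    break
            if dist <= config.hard_zone_bp and s.t_threshold < config.hard_zone_t:
                ok = False
                break
            if dist <= config.per_mb_span:
                near_cap.append(s)
        if ok and len(near_cap) >= config.per_mb_cap:
            if (config.allow_conditional_third
                    and len(near_cap) == config.per_mb_cap):
                try:
                    _, ln_p_cond = conditional_association(
                        row.variant_id, [s.variant_id for s in near_cap],
                        sumstats, lookup)
                    if ln_p_cond < ln_thresh:
                        flag = "confirmed_third"
                    else:
                        ok = False
                except (MissingLDError, np.linalg.LinAlgError) as exc:
                    logger.warning("conditional check failed for %s: %s",
                                   row.variant_id, exc)
                    ok = False
            else:
                ok = False
        if not ok:
            continue
        sig = IndexSignal(
            variant_id=row.variant_id, chrom=int(row.chrom), pos=int(row.pos),
            ln_pvalue=float(row.ln_pval), chisq=float(row.chisq),
            t_threshold=dynamic_threshold(float(row.chisq), config),
            rank=len(selected) + 1, conditional_flag=flag)
        selected.append(sig)
        chrom_sel.append(sig)

    group_loci(selected, span_bp=config.per_mb_span)
    return selected


def conditional_association(target_id: str, conditioning_ids: list[str],
                            sumstats: SumStats, ld,
                            n_eff: float | None = None) -> tuple[float, float]:
    """Summary-statistic conditional z and ln p of a target variant.

    Residualises the target's standardized marginal effect on the
    conditioning set through the LD matrix:

        z_cond = (z_t - R_tC R_C^-1 z_C) / sqrt(1 - R_tC R_C^-1 R_Ct).

    On the z scale the effective sample size cancels, so ``n_eff`` is
    accepted for interface compatibility but unused.  This is an
    approximation to individual-level joint refitting and shares its
    assumptions (homogeneous LD panel, standardized genotypes).
    Returns ``(z_cond, ln_p_cond)``.
    """
    if not conditioning_ids:
        raise ValueError("conditioning set must be non-empty")
    lookup = ld if callable(ld) else _make_ld_lookup(ld)
    ids = [target_id] + list(conditioning_ids)
    k = len(ids)
    R = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r = lookup(ids[i], ids[j])
            if r is None:
                raise MissingLDError(f"no LD for pair {ids[i]}-{ids[j]}")
            R[i, j] = R[j, i] = r
    zmap = _signed_z(sumstats, ids)
    z = np.array([zmap[v] for v in ids])
    R_C = R[1:, 1:]
    R_tC = R[0, 1:]
    cond = np.linalg.cond(R_C)
    if cond > 1e8:
        raise np.linalg.LinAlgError(
            f"conditioning LD submatrix near-singular (cond={cond:.2g})")
    w = np.linalg.solve(R_C, z[1:])
    denom2 = 1.0 - float(R_tC @ np.linalg.solve(R_C, R_tC))
    if denom2 <= 1e-12:
        raise np.linalg.LinAlgError("target fully explained by conditioning set")
    z_cond = (z[0] - float(R_tC @ w)) / math.sqrt(denom2)
    return z_cond, float(z_to_ln_p(z_cond))


def _signed_z(sumstats: SumStats, ids: list[str]) -> dict[str, float]:
    df = sumstats.df
    sub = df.loc[df["variant_id"].isin(ids)]
    missing = set(ids) - set(sub["variant_id"])
    if missing:
        raise KeyError(f"variants absent from summary statistics: {sorted(missing)}")
    out = {}
    for row in sub.itertuples(index=False):
        zabs = ln_p_to_z(row.ln_pval)
        out[row.variant_id] = math.copysign(zabs, row.beta)
    return out


def group_loci(signals: list[IndexSignal], span_bp: int = 1_000_000) -> int:
    """Assign 1-based locus ids by single-linkage position chaining.

    Consecutive signals on the same chromosome at most ``span_bp`` apart
    share a locus (a conservative grouping of nearby independent
    signals into one genomic region).  Mutates ``signals`` in place and
    returns the number of distinct loci.
    """
    if not signals:
        return 0
    order = sorted(signals, key=lambda s: (s.chrom, s.pos))
    locus = 0
    prev = None
    for s in order:
        if prev is None or s.chrom != prev.chrom or s.pos - prev.pos > span_bp:
            locus += 1
        s.locus_id = locus
        prev = s
    return locus


def tag_coding(signals: list[IndexSignal], ld, coding_variants: list[str],
               r2_min: float = 0.95) -> list[IndexSignal]:
    """Tag each signal with the best-linked protein-coding variant.

    The tag is the coding variant with maximal r^2 to the lead among
    those exceeding ``r2_min``; a lead that is itself coding tags itself
    at r^2 = 1.  Signals with no qualifying coding variant keep
    ``coding_variant=None``.  Mutates and returns ``signals``.
    """
    lookup = ld if callable(ld) else _make_ld_lookup(ld)
    coding = list(dict.fromkeys(coding_variants))
    for s in signals:
        if s.variant_id in coding:
            s.coding_variant, s.coding_r2 = s.variant_id, 1.0
            continue
        best_id, best_r2 = None, r2_min
        for cv in coding:
            r2 = _pair_r2(lookup, s.variant_id, cv)
            if r2 is not None and r2 > best_r2:
                best_id, best_r2 = cv, r2
        if best_id is not None:
            s.coding_variant, s.coding_r2 = best_id, best_r2
    return signals


def signals_to_frame(signals: list[IndexSignal]) -> pd.DataFrame:
    """Tabular view matching the signals TSV layout."""
    return pd.DataFrame([{
        "rank": s.rank, "variant_id": s.variant_id, "chrom": s.chrom,
        "pos": s.pos, "pval": s.pvalue, "chisq": s.chisq, "T": s.t_threshold,
        "locus_id": s.locus_id, "conditional_flag": s.conditional_flag,
        "coding_variant": s.coding_variant if s.coding_variant else "NA",
        "coding_r2": s.coding_r2 if s.coding_r2 is not None else "NA",
    } for s in signals])
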