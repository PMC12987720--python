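"""Core data model and elementary statistics for GWAS summary data.

Variants are identified by the canonical string ``chr:pos:ref:alt`` on
GRCh38, with the X chromosome coded as 23.  The alt allele is always the
effect allele; when two cohorts code the same site with ref/alt swapped,
alignment flips the sign of beta and replaces af by 1 - af.

p-values are manipulated in natural-log space throughout so that
associations far beyond the double-precision underflow point
(p < 1e-300) survive p <-> z <-> chi-square round trips.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special

logger = logging.getLogger(__name__)

_LN2 = math.log(2.0)

#: canonical column order of the summary-statistic TSV dialect
SUMSTATS_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "beta",
    "se",
    "pval",
    "af",
    "n_cases",
    "n_controls",
]

_CHROM_ALIASES = {"X": 23, "x": 23, "23": 23}


class SumStatsFormatError(ValueError):
    """A summary-statistic file is structurally unusable (e.g. missing columns)."""


class AlleleMismatchError(ValueError):
    """Records claimed to be on the same variant have irreconcilable alleles."""


def _parse_chrom(label: str | int) -> int:
    s = str(label).removeprefix("chr")
    if s in _CHROM_ALIASES:
        return _CHROM_ALIASES[s]
    c = int(s)
    if not 1 <= c <= 23:
        raise ValueError(f"chromosome out of range: {label!r}")
    return c


@dataclass(frozen=True, order=True)
class Variant:
    """A sequence variant keyed by chrom:pos:ref:alt (GRCh38; X coded as 23)."""

    chrom: int
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles identical: {self.ref}")
        if not 1 <= self.chrom <= 23:
            raise ValueError(f"chromosome out of range: {self.chrom}")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, vid: str) -> "Variant":
        m = re.fullmatch(r"(chr)?([0-9Xx]+):(\d+):([ACGTNacgtn]+):([ACGTNacgtn]+)", vid)
        if m is None:
            raise ValueError(f"cannot parse variant id {vid!r}")
        return cls(_parse_chrom(m.group(2)), int(m.group(3)),
                   m.group(4).upper(), m.group(5).upper())

    def is_ambiguous_strand(self) -> bool:
        """A/T or C/G SNVs cannot be strand-resolved from alleles alone."""
        pair = {self.ref, self.alt}
        return pair in ({"A", "T"}, {"C", "G"})

    def __str__(self) -> str:
        return self.id


@dataclass
class AssocRecord:
    """Marginal association of the alt allele of one variant with one trait.

    ``beta`` is the per-alt-allele effect (log-odds for binary traits),
    ``se`` its standard error, ``pvalue`` a two-sided p in (0, 1], ``af``
    the alt-allele frequency.  ``ln_pvalue`` carries the p-value in
    natural-log space and takes precedence over ``pvalue`` where both are
    set, so p-values below the underflow point are preserved.
    """

    variant: Variant
    beta: float
    se: float
    pvalue: float | None = None
    af: float | None = None
    n_cases: float | None = None
    n_controls: float | None = None
    ln_pvalue: float | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.variant}: se must be > 0, got {self.se}")
        if self.af is not None and not 0 < self.af < 1:
            raise ValueError(f"{self.variant}: af must be in (0,1), got {self.af}")
        if self.ln_pvalue is None and self.pvalue is not None:
            if not 0 < self.pvalue <= 1:
                raise ValueError(f"{self.variant}: p must be in (0,1], got {self.pvalue}")
            self.ln_pvalue = math.log(self.pvalue)
        if self.ln_pvalue is not None and self.pvalue is None:
            self.pvalue = math.exp(self.ln_pvalue)

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def chisq(self) -> float:
        return self.z ** 2

    def check_p_consistency(self, tol: float = 1e-2) -> bool:
        """|z| implied by the stored p agrees with |beta/se| within ``tol``."""
        if self.ln_pvalue is None:
            return True
        return abs(ln_p_to_z(self.ln_pvalue) - abs(self.z)) <= tol * max(1.0, abs(self.z))


# ---------------------------------------------------------------------------
# p / z / chi-square conversions (log-space so p ~ 1e-300 round-trips)
# ---------------------------------------------------------------------------

def z_to_ln_p(z: float | np.ndarray) -> float | np.ndarray:
    """Natural log of the two-sided p-value for a standard-normal z."""
    return _LN2 + special.log_ndtr(-np.abs(z))


def z_to_p(z: float | np.ndarray) -> float | np.ndarray:
    return np.exp(z_to_ln_p(z))


def p_to_z(p: float | np.ndarray) -> float | np.ndarray:
    """|z| such that the two-sided p-value equals ``p`` (p in (0, 1])."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p must lie in (0, 1]")
    return ln_p_to_z(np.log(p))


def ln_p_to_z(ln_p: float | np.ndarray) -> float | np.ndarray:
    """|z| from a two-sided p given in natural-log space."""
    ln_p = np.asarray(ln_p, dtype=float)
    if np.any(ln_p > 0):
        raise ValueError("ln(p) must be <= 0")
    out = -special.ndtri_exp(ln_p - _LN2)
    # p == 1 maps to z == 0 exactly, not -0.0
    out = np.abs(out)
    return float(out) if out.ndim == 0 else out


def z_to_chisq(z: float | np.ndarray) -> float | np.ndarray:
    return np.square(z)


def chisq_to_z(chisq: float | np.ndarray) -> float | np.ndarray:
    chisq = np.asarray(chisq, dtype=float)
    if np.any(chisq < 0):
        raise ValueError("chi-square must be >= 0")
    out = np.sqrt(chisq)
    return float(out) if out.ndim == 0 else out


def chisq_to_ln_p(chisq: float | np.ndarray) -> float | np.ndarray:
    """ln p for a 1-df chi-square statistic (equals the two-sided normal p)."""
    return z_to_ln_p(chisq_to_z(chisq))


def chisq_to_p(chisq: float | np.ndarray) -> float | np.ndarray:
    return np.exp(chisq_to_ln_p(chisq))


def p_to_chisq(p: float | np.ndarray) -> float | np.ndarray:
    return np.square(p_to_z(p))


# ---------------------------------------------------------------------------
# SumStats container
# ---------------------------------------------------------------------------

@dataclass
class SumStats:
    """Per-variant association results for one trait.

    Backed by a :class:`pandas.DataFrame` with :data:`SUMSTATS_COLUMNS`
    plus ``ln_pval``; rows sorted by (chrom, pos, ref, alt) and variant
    ids unique.
    """

    trait_id: str
    df: pd.DataFrame
    build: str = "GRCh38"

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
        if missing:
            raise SumStatsFormatError(f"missing columns: {missing}")
        if "ln_pval" not in df.columns:
            with np.errstate(divide="ignore"):
                df["ln_pval"] = np.log(df["pval"].to_numpy(dtype=float))
        if df["variant_id"].duplicated().any():
            dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise ValueError(f"duplicate variant id: {dup}")
        df = df.sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()

    def record(self, variant_id: str) -> AssocRecord:
        rows = self.df.loc[self.df["variant_id"] == variant_id]
        if rows.empty:
            raise KeyError(variant_id)
        return _row_to_record(rows.iloc[0])

    def records(self) -> Iterable[AssocRecord]:
        for _, row in self.df.iterrows():
            yield _row_to_record(row)

    @classmethod
    def from_records(cls, trait_id: str, records: Sequence[AssocRecord],
                     build: str = "GRCh38") -> "SumStats":
        rows = []
        for r in records:
            rows.append({
                "variant_id": r.variant.id, "chrom": r.variant.chrom,
                "pos": r.variant.pos, "ref": r.variant.ref, "alt": r.variant.alt,
                "beta": r.beta, "se": r.se, "pval": r.pvalue,
                "af": np.nan if r.af is None else r.af,
                "n_cases": np.nan if r.n_cases is None else r.n_cases,
                "n_controls": np.nan if r.n_controls is None else r.n_controls,
                "ln_pval": r.ln_pvalue,
            })
        df = pd.DataFrame(rows, columns=SUMSTATS_COLUMNS + ["ln_pval"])
        return cls(trait_id=trait_id, df=df, build=build)


def _row_to_record(row: pd.Series) -> AssocRecord:
    def _opt(x):
        return None if x is None or (isinstance(x, float) and math.isnan(x)) else x

    return AssocRecord(
        variant=Variant(int(row["chrom"]), int(row["pos"]), row["ref"], row["alt"]),
        beta=float(row["beta"]), se=float(row["se"]),
        pvalue=_opt(float(row["pval"])) if not pd.isna(row["pval"]) else None,
        af=_opt(row["af"]), n_cases=_opt(row["n_cases"]),
        n_controls=_opt(row["n_controls"]),
        ln_pvalue=_opt(row.get("ln_pval")),
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

#: maps canonical column -> accepted header aliases (case-insensitive)
DEFAULT_DIALECT = {
    "variant_id": ["variant_id", "variant", "snp", "id", "rsid"],
    "chrom": ["chrom", "chr", "chromosome", "#chrom"],
    "pos": ["pos", "position", "bp", "base_pair_location"],
    "ref": ["ref", "reference_allele", "other_allele", "allele1"],
    "alt": ["alt", "effect_allele", "allele2"],
    "beta": ["beta", "effect", "b"],
    "se": ["se", "sebeta", "standard_error", "stderr"],
    "pval": ["pval", "p", "pvalue", "p_value", "pval_meta"],
    "af": ["af", "af_alt", "eaf", "effect_allele_frequency", "maf"],
    "n_cases": ["n_cases", "ncase", "cases"],
    "n_controls": ["n_controls", "ncontrol", "controls"],
}

_MANDATORY = ["beta", "se"]


def _resolve_columns(header: Sequence[str], dialect: dict | None) -> dict[str, str]:
    aliases = {k: [a.lower() for a in v] for k, v in DEFAULT_DIALECT.items()}
    if dialect:
        for canon, name in dialect.items():
            aliases.setdefault(canon, []).insert(0, name.lower())
    lower = {h.lower(): h for h in header}
    out = {}
    for canon, names in aliases.items():
        for name in names:
            if name in lower:
                out[canon] = lower[name]
                break
    return out


def read_sumstats(path, trait_id: str | None = None,
                  dialect: dict | None = None,
                  on_bad_row: str = "skip") -> SumStats:
    """Read a tab-delimited summary-statistic file.

    Variant identity may come either from a ``variant_id`` column
    (``chr:pos:ref:alt``) or from separate chrom/pos/ref/alt columns.
    Rows violating record invariants (se <= 0, af outside (0,1),
    non-numeric fields) are rejected; ``on_bad_row`` chooses between
    ``"skip"`` (log and drop) and ``"fail"``.

    Parameters
    ----------
    dialect:
        Optional mapping from canonical column names
        (:data:`SUMSTATS_COLUMNS`) to the actual headers in the file,
        overriding the built-in alias table.
    """
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = _resolve_columns(raw.columns, dialect)
    have_id = "variant_id" in cols
    have_parts = all(k in cols for k in ("chrom", "pos", "ref", "alt"))
    if not have_id and not have_parts:
        raise SumStatsFormatError(
            f"{path}: need a variant-id column or chrom/pos/ref/alt columns; "
            f"found {list(raw.columns)}")
    for c in _MANDATORY:
        if c not in cols:
            raise SumStatsFormatError(f"{path}: missing mandatory column {c!r}")

    records, report = [], []
    for i, row in raw.iterrows():
        try:
            if have_id:
                variant = Variant.parse(row[cols["variant_id"]])
            else:
                variant = Variant(_parse_chrom(row[cols["chrom"]]),
                                  int(row[cols["pos"]]),
                                  str(row[cols["ref"]]).upper(),
                                  str(row[cols["alt"]]).upper())

            def _get(c, cast=float):
                if c not in cols:
                    return None
                v = row[cols[c]]
                if pd.isna(v) or v in ("", "NA", "nan", "."):
                    return None
                return cast(v)

            beta = float(row[cols["beta"]])
            se = float(row[cols["se"]])
            pval = _get("pval")
            ln_pval = None
            if pval is not None and pval <= 0.0 and se > 0:
                # beyond double-precision underflow: recover from z
                pval, ln_pval = None, float(z_to_ln_p(beta / se))
            rec = AssocRecord(variant=variant, beta=beta, se=se, pvalue=pval,
                              ln_pvalue=ln_pval, af=_get("af"),
                              n_cases=_get("n_cases"),
                              n_controls=_get("n_controls"))
            records.append(rec)
        except (ValueError, KeyError) as exc:
            report.append((int(i) + 2, str(exc)))  # +2: header + 1-based
            if on_bad_row == "fail":
                raise SumStatsFormatError(f"{path} line {int(i) + 2}: {exc}") from exc
    for line_no, msg in report:
        logger.warning("%s line %d rejected: %s", path, line_no, msg)
    ss = SumStats.from_records(trait_id or str(path), records)
    ss.row_report = report  # type: ignore[attr-defined]
    return ss


def write_sumstats(ss: SumStats, path, float_fmt: str = "%.10g") -> None:
    """Write the canonical tab-delimited dialect (round-trips with read)."""
    ss.df[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False,
                                   float_format=float_fmt, na_rep="NA")


# ---------------------------------------------------------------------------
# LD matrix
# ---------------------------------------------------------------------------

@dataclass
class LDMatrix:
    """Signed allelic correlations over an ordered variant panel."""

    variants: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.variants)
        if self.r.shape != (n, n):
            raise ValueError(f"r has shape {self.r.shape}, expected {(n, n)}")
        self.validate()
        self._index = {v: i for i, v in enumerate(self.variants)}

    def validate(self, tol: float = 1e-8) -> None:
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValueError("LD matrix diagonal must be 1")
        if not np.allclose(self.r, self.r.T, atol=tol):
            raise ValueError("LD matrix must be symmetric")
        if np.any(np.abs(self.r) > 1 + 1e-9):
            raise ValueError("|r| must be <= 1")
        if len(self.variants) > 1:
            w = np.linalg.eigvalsh(self.r)
            if w.min() < -1e-6 * max(1.0, w.max()):
                raise ValueError(f"LD matrix not PSD (min eigenvalue {w.min():.3g})")

    @property
    def r2(self) -> np.ndarray:
        return np.square(self.r)

    def __len__(self) -> int:
        return len(self.variants)

    def index(self, vid: str) -> int:
        return self._index[vid]

    def __contains__(self, vid: str) -> bool:
        return vid in self._index

    def pair_r(self, vid_i: str, vid_j: str) -> float:
        return float(self.r[self._index[vid_i], self._index[vid_j]])

    def submatrix(self, vids: Sequence[str]) -> np.ndarray:
        idx = [self._index[v] for v in vids]
        return self.r[np.ix_(idx, idx)]


def read_ld_dense(matrix_path, variants_path) -> LDMatrix:
    """Dense whitespace-delimited square matrix + sidecar variant list."""
    with open(variants_path) as fh:
        variants = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    r = np.loadtxt(matrix_path)
    if r.ndim == 0:
        r = r.reshape(1, 1)
    return LDMatrix(variants=variants, r=r)


def read_ld_triplets(path) -> LDMatrix:
    """Long format ``id_i<TAB>id_j<TAB>r``; unlisted pairs default to r = 0."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     names=["i", "j", "r"], dtype={"i": str, "j": str})
    variants = sorted(set(df["i"]) | set(df["j"]),
                      key=lambda v: (Variant.parse(v).chrom, Variant.parse(v).pos, v))
    idx = {v: k for k, v in enumerate(variants)}
    r = np.eye(len(variants))
    for _, row in df.iterrows():
        a, b = idx[row["i"]], idx[row["j"]]
        r[a, b] = r[b, a] = float(row["r"])
    return LDMatrix(variants=variants, r=r)


def write_ld_dense(ld: LDMatrix, matrix_path, variants_path) -> None:
    np.savetxt(matrix_path, ld.r, fmt="%.8g")
    with open(variants_path, "w") as fh:
        fh.write("\n".join(ld.variants) + "\n")


# ---------------------------------------------------------------------------
# Meta-analysis and scale transforms
# ---------------------------------------------------------------------------

def align_to(record: AssocRecord, target: Variant) -> AssocRecord:
    """Express ``record`` with ``target.alt`` as the effect allele.

    Accepts either identical alleles or a ref/alt swap (beta negated,
    af complemented).  Ambiguous-strand variants are only flagged via a
    log warning, never flipped on strand.
    """
    v = record.variant
    if (v.chrom, v.pos) != (target.chrom, target.pos):
        raise AlleleMismatchError(f"different sites: {v} vs {target}")
    if (v.ref, v.alt) == (target.ref, target.alt):
        return record
    if (v.ref, v.alt) == (target.alt, target.ref):
        if target.is_ambiguous_strand():
            logger.warning("strand-ambiguous alleles at %s; flip assumes same strand", target)
        return replace(record, variant=target, beta=-record.beta,
                       af=None if record.af is None else 1.0 - record.af)
    raise AlleleMismatchError(f"alleles irreconcilable: {v} vs {target}")


def ivw_meta(records: Sequence[AssocRecord]) -> AssocRecord:
    """Inverse-variance-weighted fixed-effects meta-analysis of one variant.

    beta = sum(w_i b_i) / sum(w_i) with w_i = 1/se_i^2 and
    se = sum(w_i)^(-1/2); the two-sided p comes from the normal z.
    A single cohort passes through bit-identically (its beta/se are
    untouched), matching how variants absent from one cohort are handled.
    """
    if not records:
        raise ValueError("ivw_meta needs at least one record")
    target = records[0].variant
    aligned = [align_to(r, target) for r in records]
    if len(aligned) == 1:
        r = aligned[0]
        return replace(r, pvalue=None, ln_pvalue=z_to_ln_p(r.z))
    w = np.array([1.0 / r.se ** 2 for r in aligned])
    betas = np.array([r.beta for r in aligned])
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    afs = [r.af for r in aligned if r.af is not None]
    ns_ca = [r.n_cases for r in aligned if r.n_cases is not None]
    ns_co = [r.n_controls for r in aligned if r.n_controls is not None]
    af = None
    if afs:
        wa = [1.0 / r.se ** 2 for r in aligned if r.af is not None]
        af = float(np.average(afs, weights=wa))
    return AssocRecord(variant=target, beta=beta, se=se,
                       ln_pvalue=z_to_ln_p(beta / se), af=af,
                       n_cases=sum(ns_ca) if ns_ca else None,
                       n_controls=sum(ns_co) if ns_co else None)


def heritability_scale(beta: float | np.ndarray, se: float | np.ndarray,
                       af: float | np.ndarray) -> tuple:
    """Transform (beta, se) to the sqrt-heritability scale.

    Both are multiplied by sqrt(2 * MAF * (1 - MAF)), so the magnitude of
    the transformed effect reflects per-variant variance explained while
    z = beta/se is unchanged.
    """
    af = np.asarray(af, dtype=float)
    if np.any(af <= 0) or np.any(af >= 1):
        raise ValueError("af must lie in (0, 1)")
    maf = np.minimum(af, 1.0 - af)
    m = np.sqrt(2.0 * maf * (1.0 - maf))
    b, s = np.asarray(beta) * m, np.asarray(se) * m
    if np.ndim(beta) == 0:
        return float(b), float(s)
    return b, s


@dataclass(frozen=True)
class AfEnrichment:
    ratio: float  # inf when the reference population lacks the allele
    infinite: bool
    enriched: bool  # ratio >= fold threshold

    def formatted(self) -> str:
        return "inf" if self.infinite else f"{self.ratio:.3g}"


def af_enrichment(af_target: float, af_reference: float,
                  fold: float = 5.0) -> AfEnrichment:
    """Allele-frequency enrichment of a target population over a reference.

    A reference frequency of exactly 0 yields the infinite-enrichment
    flag (printed as "inf"); ``enriched`` marks ratios >= ``fold``
    (default 5, the conventional cut for population-enriched alleles).
    """
    if not 0 < af_target < 1:
        raise ValueError("af_target must be in (0, 1)")
    if not 0 <= af_reference < 1:
        raise ValueError("af_reference must be in [0, 1)")
    if af_reference == 0.0:
        return AfEnrichment(ratio=math.inf, infinite=True, enriched=True)
    ratio = af_target / af_reference
    return AfEnrichment(ratio=ratio, infinite=False, enriched=ratio >= fold)
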