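"""Core GWAS summary-statistics containers, I/O and harmonization.

Summary statistics are held in a :class:`SumStatsTable`, a thin wrapper
around a :class:`pandas.DataFrame` with one row per (variant, stratum)
association.  Coordinates are 1-based inclusive throughout; BED input is
converted at the boundary (see :mod:`pqtlmeta.enrichment`).

The X chromosome is analyzed sex-stratified (males carry one allele, coded
0/1), so protein-phenotype tables must supply X-chromosome rows in the
``male``/``female`` strata, never ``all``.  Binary-outcome tables may carry
combined X records (``require_x_stratified=False``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

ALLOWED_CHROMS = tuple(str(c) for c in range(1, 23)) + ("X",)
STRATA = ("all", "male", "female")

#: canonical internal column order
COLUMNS = [
    "chrom", "pos", "effect_allele", "other_allele", "rsid",
    "eaf", "beta", "se", "pval", "n", "stratum",
]

#: GWAS-SSF-style column names used on disk
SSF_NAMES = {
    "chrom": "chromosome",
    "pos": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "rsid": "rsid",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "pval": "p_value",
    "n": "n",
    "stratum": "stratum",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: palindromic variants whose minor-allele frequency exceeds this cannot be
#: oriented by allele frequency and are excluded from harmonization
PALINDROMIC_MAF_MAX = 0.42


class SumStatsError(ValueError):
    """Raised for irrecoverable summary-statistics problems."""


@dataclass(frozen=True)
class VariantKey:
    """Chromosome/position/allele identity of a biallelic SNP."""

    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    rsid: str | None = None

    def __post_init__(self):
        if self.chrom not in ALLOWED_CHROMS:
            raise SumStatsError(f"chromosome {self.chrom!r} not in 1-22, X")
        if self.pos < 1:
            raise SumStatsError("position must be >= 1 (1-based)")
        if self.effect_allele == self.other_allele:
            raise SumStatsError("effect and other allele must differ")

    @property
    def is_palindromic(self) -> bool:
        return _COMPLEMENT.get(self.effect_allele) == self.other_allele


@dataclass
class AssocRecord:
    """One variant's association estimate in one analysis stratum.

    ``beta`` is the per-effect-allele estimate on the standardized
    (unit-variance) phenotype scale for quantitative traits, or the log
    odds ratio for binary outcomes.
    """

    key: VariantKey
    beta: float
    se: float
    pval: float
    eaf: float
    n: float
    stratum: str = "all"

    def __post_init__(self):
        if self.se <= 0:
            raise SumStatsError("standard error must be positive")
        if not 0 < self.eaf < 1:
            raise SumStatsError("EAF must lie strictly in (0, 1)")
        if not 0 < self.pval <= 1:
            raise SumStatsError("p-value must lie in (0, 1]")
        if self.n <= 0:
            raise SumStatsError("sample size must be positive")
        if self.stratum not in STRATA:
            raise SumStatsError(f"stratum {self.stratum!r} not in {STRATA}")


@dataclass
class QCReport:
    """Row-level quality-control accounting for one read operation."""

    n_read: int = 0
    n_kept: int = 0
    rejects: dict[str, int] = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return sum(self.rejects.values())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"n_read": self.n_read, "n_kept": self.n_kept,
             "n_rejected": self.n_rejected, "rejects": self.rejects},
            indent=2))


@dataclass
class SumStatsTable:
    """Ordered collection of association records plus provenance."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise SumStatsError(f"missing columns: {missing}")
        self.df = self.df[COLUMNS].copy()
        self.df["chrom"] = self.df["chrom"].astype(str)
        self.df = self.df.sort_values(
            ["chrom", "pos", "effect_allele", "other_allele", "stratum"],
            kind="mergesort").reset_index(drop=True)
        dup = self.df.duplicated(
            ["chrom", "pos", "effect_allele", "other_allele", "stratum"])
        if dup.any():
            raise SumStatsError(
                f"{int(dup.sum())} duplicate (variant, stratum) rows")

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> Iterable[AssocRecord]:
        for row in self.df.itertuples(index=False):
            yield AssocRecord(
                key=VariantKey(row.chrom, int(row.pos), row.effect_allele,
                               row.other_allele,
                               None if pd.isna(row.rsid) else row.rsid),
                beta=row.beta, se=row.se, pval=row.pval, eaf=row.eaf,
                n=row.n, stratum=row.stratum)


def _valid_mask(df: pd.DataFrame, require_x_stratified: bool,
                rejects: dict[str, int]) -> np.ndarray:
    """Vectorized AssocRecord invariants; counts failures by reason."""
    checks = {
        "bad_chrom": ~df["chrom"].isin(ALLOWED_CHROMS),
        "bad_pos": ~(df["pos"] >= 1),
        "same_alleles": df["effect_allele"] == df["other_allele"],
        "bad_allele": ~(df["effect_allele"].isin(_COMPLEMENT)
                        & df["other_allele"].isin(_COMPLEMENT)),
        "nonpositive_se": ~(df["se"] > 0),
        "eaf_out_of_range": ~((df["eaf"] > 0) & (df["eaf"] < 1)),
        "bad_pval": ~((df["pval"] > 0) & (df["pval"] <= 1)),
        "nonpositive_n": ~(df["n"] > 0),
        "bad_stratum": ~df["stratum"].isin(STRATA),
    }
    if require_x_stratified:
        checks["x_not_stratified"] = (df["chrom"] == "X") & (
            df["stratum"] == "all")
    bad = np.zeros(len(df), dtype=bool)
    for reason, mask in checks.items():
        mask = mask.to_numpy(dtype=bool) & ~bad
        if mask.any():
            rejects[reason] = rejects.get(reason, 0) + int(mask.sum())
        bad |= mask
    return ~bad


def read_sumstats(path: str | Path, dialect: Mapping[str, str] | None = None,
                  require_x_stratified: bool = True,
                  meta: dict | None = None) -> tuple[SumStatsTable, QCReport]:
    """Read a tab-delimited GWAS-SSF-style table.

    Parameters
    ----------
    path
        Tab-delimited file with a header row.
    dialect
        Optional mapping from canonical column names (``chrom``, ``pos``,
        ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``,
        ``pval``, ``n``, optional ``rsid``/``stratum``) to the file's
        column names, for foreign layouts.  Defaults to GWAS-SSF names.
    require_x_stratified
        Reject X-chromosome rows carrying stratum ``all`` (the default for
        protein-phenotype inputs, which must arrive sex-stratified).

    Returns
    -------
    (table, qc)
        Rows violating record invariants are dropped and tallied in ``qc``.
    """
    colmap = dict(SSF_NAMES)
    if dialect:
        colmap.update(dialect)
    raw = pd.read_csv(path, sep="\t", dtype={colmap["chrom"]: str},
                      na_values=["NA", ""], keep_default_na=True)
    required = [k for k in COLUMNS if k not in ("rsid", "stratum")]
    for canon in required:
        if colmap[canon] not in raw.columns:
            raise SumStatsError(
                f"required column {colmap[canon]!r} (for {canon}) missing "
                f"from {path}")
    df = pd.DataFrame({c: raw[colmap[c]] for c in required})
    df["rsid"] = raw[colmap["rsid"]] if colmap["rsid"] in raw.columns else None
    df["stratum"] = (raw[colmap["stratum"]]
                     if colmap["stratum"] in raw.columns else "all")
    rejects: dict[str, int] = {}
    n_read = len(df)
    # unparsable numerics become NaN and are rejected row-wise
    for c in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    numbad = df[["pos", "eaf", "beta", "se", "pval", "n"]].isna().any(axis=1)
    if numbad.any():
        rejects["unparsable_numeric"] = int(numbad.sum())
    df = df[~numbad]
    df["pos"] = df["pos"].astype(np.int64)
    df["chrom"] = df["chrom"].astype(str)
    for c in ("effect_allele", "other_allele"):
        df[c] = df[c].astype(str).str.upper()
    keep = _valid_mask(df, require_x_stratified, rejects)
    df = df[keep]
    qc = QCReport(n_read=n_read, n_kept=len(df), rejects=rejects)
    return SumStatsTable(df, meta=dict(meta or {}, path=str(path))), qc


def write_sumstats(table: SumStatsTable, path: str | Path) -> None:
    """Write a table as tab-delimited GWAS-SSF-style text."""
    out = table.df.rename(columns=SSF_NAMES)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# allele harmonization


def _complement(allele: str) -> str:
    return _COMPLEMENT[allele]


@dataclass
class HarmonizeResult:
    record: AssocRecord | None
    action: str  # "identical" | "flipped" | "strand" | "strand_flipped"
    ok: bool
    reason: str | None = None


def harmonize_alleles(a: AssocRecord, b: AssocRecord,
                      trust_strand: bool = False) -> HarmonizeResult:
    """Re-express ``b`` on ``a``'s effect allele.

    Attempts, in order: direct match; effect/other swap (beta negated,
    EAF complemented); strand complement; strand complement plus swap.
    Palindromic (A/T, C/G) pairs are orientable only by allele frequency:
    when either minor-allele frequency exceeds ``PALINDROMIC_MAF_MAX`` the
    pair is flagged non-harmonizable, otherwise the orientation that makes
    the two EAFs concordant (both < 0.5 or both > 0.5) is chosen.

    ``trust_strand=True`` declares both records on the same strand (a
    consortium's standardized upload format): palindromic pairs are then
    matched by allele labels like any other variant, and only the two
    no-complement attempts are made.  Use for within-study alignment;
    leave False for cross-source joins (e.g. exposure vs outcome GWAS).
    """
    if (a.key.chrom, a.key.pos) != (b.key.chrom, b.key.pos):
        raise SumStatsError("harmonize_alleles requires matching chrom/pos")
    ea, oa = a.key.effect_allele, a.key.other_allele
    eb, ob = b.key.effect_allele, b.key.other_allele

    if trust_strand:
        if (eb, ob) == (ea, oa):
            return HarmonizeResult(b, "identical", True)
        if (ob, eb) == (ea, oa):
            return HarmonizeResult(_swap(b), "flipped", True)
        return HarmonizeResult(None, "none", False, "allele_mismatch")

    if a.key.is_palindromic or b.key.is_palindromic:
        same = {eb, ob} == {ea, oa}
        if not same:
            return HarmonizeResult(None, "none", False, "allele_mismatch")
        if min(a.eaf, 1 - a.eaf) > PALINDROMIC_MAF_MAX or \
           min(b.eaf, 1 - b.eaf) > PALINDROMIC_MAF_MAX:
            return HarmonizeResult(None, "none", False,
                                   "palindromic_ambiguous")
        # orient purely by EAF concordance; strand (hence the label
        # arrangement) is unknowable for palindromes
        concordant = (a.eaf < 0.5) == (b.eaf < 0.5)
        key = VariantKey(a.key.chrom, a.key.pos, ea, oa, b.key.rsid)
        if concordant:
            rec = AssocRecord(key, b.beta, b.se, b.pval, b.eaf, b.n,
                              b.stratum)
            return HarmonizeResult(rec, "identical", True)
        rec = AssocRecord(key, -b.beta, b.se, b.pval, 1.0 - b.eaf, b.n,
                          b.stratum)
        return HarmonizeResult(rec, "flipped", True)

    if (eb, ob) == (ea, oa):
        return HarmonizeResult(b, "identical", True)
    if (ob, eb) == (ea, oa):
        return HarmonizeResult(_swap(b), "flipped", True)
    ceb, cob = _complement(eb), _complement(ob)
    if (ceb, cob) == (ea, oa):
        return HarmonizeResult(_restrand(b, ceb, cob), "strand", True)
    if (cob, ceb) == (ea, oa):
        return HarmonizeResult(_swap(_restrand(b, ceb, cob)),
                               "strand_flipped", True)
    return HarmonizeResult(None, "none", False, "allele_mismatch")


def _swap(r: AssocRecord) -> AssocRecord:
    key = VariantKey(r.key.chrom, r.key.pos, r.key.other_allele,
                     r.key.effect_allele, r.key.rsid)
    return AssocRecord(key, -r.beta, r.se, r.pval, 1.0 - r.eaf, r.n,
                       r.stratum)


def _restrand(r: AssocRecord, ea: str, oa: str) -> AssocRecord:
    key = VariantKey(r.key.chrom, r.key.pos, ea, oa, r.key.rsid)
    return AssocRecord(key, r.beta, r.se, r.pval, r.eaf, r.n, r.stratum)


def harmonize_frame(target: pd.DataFrame, other: pd.DataFrame,
                    trust_strand: bool = False
                    ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Vectorized join of ``other`` onto ``target`` with allele alignment.

    Variants are matched on (chrom, pos).  Returns the inner join with
    ``other``'s ``beta``/``eaf`` re-expressed on ``target``'s effect allele
    (suffix ``_other``), dropping non-harmonizable pairs, plus drop counts.
    ``trust_strand`` as in :func:`harmonize_alleles`.
    """
    merged = target.merge(other, on=["chrom", "pos"],
                          suffixes=("", "_other"))
    if merged.empty:
        return merged, {"matched": 0}
    ea = merged["effect_allele"].to_numpy()
    oa = merged["other_allele"].to_numpy()
    eb = merged["effect_allele_other"].to_numpy()
    ob = merged["other_allele_other"].to_numpy()
    comp = np.vectorize(_COMPLEMENT.get)
    ceb, cob = comp(eb), comp(ob)
    unknown_strand = not trust_strand
    # palindromic ambiguity and strand flips arise only when the two
    # sources may sit on different strands
    palindromic = ((ceb == ob) | (comp(ea) == oa)) & unknown_strand

    direct = (eb == ea) & (ob == oa)
    swapped = (ob == ea) & (eb == oa)
    strand = ~palindromic & (ceb == ea) & (cob == oa) & unknown_strand
    strand_sw = ~palindromic & (cob == ea) & (ceb == oa) & unknown_strand

    eaf_a = merged["eaf"].to_numpy(float)
    eaf_b = merged["eaf_other"].to_numpy(float)
    pal_ok = palindromic & (direct | swapped) & \
        (np.minimum(eaf_a, 1 - eaf_a) <= PALINDROMIC_MAF_MAX) & \
        (np.minimum(eaf_b, 1 - eaf_b) <= PALINDROMIC_MAF_MAX)
    # palindrome orientation comes purely from EAF concordance
    concord = (eaf_a < 0.5) == (eaf_b < 0.5)
    pal_keep = pal_ok & concord
    pal_flip = pal_ok & ~concord

    keep_as_is = (~palindromic & (direct | strand)) | pal_keep
    flip = (~palindromic & (swapped | strand_sw)) | pal_flip
    ok = keep_as_is | flip

    merged = merged.copy()
    merged.loc[flip, "beta_other"] = -merged.loc[flip, "beta_other"]
    merged.loc[flip, "eaf_other"] = 1.0 - merged.loc[flip, "eaf_other"]
    merged["effect_allele_other"] = merged["effect_allele"]
    merged["other_allele_other"] = merged["other_allele"]
    counts = {
        "matched": int(len(merged)),
        "kept": int(ok.sum()),
        "flipped": int(flip.sum()),
        "dropped_palindromic": int((palindromic & ~pal_ok
                                    & (direct | swapped)).sum()),
        "dropped_mismatch": int((~ok).sum()
                                - (palindromic & ~pal_ok
                                   & (direct | swapped)).sum()),
    }
    return merged[ok].reset_index(drop=True), counts


# ---------------------------------------------------------------------------
# rank-based inverse-normal transform


def rank_inverse_normal(values, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal (inverse-gaussian) transform.

    Maps values to ``Phi^{-1}((r - c) / (n - 2c + 1))`` where ``r`` is the
    average rank (ties share the mean rank) and ``c`` is the Blom offset
    3/8, giving a sample with mean ~0 and variance ~1.  The result depends
    on the input only through its ranks, so any strictly monotone
    transformation of the input yields the identical output.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise SumStatsError("need a 1-d vector of length >= 2")
    if np.ptp(x) == 0:
        raise SumStatsError("constant input: transform undefined")
    r = stats.rankdata(x, method="average")
    q = (r - c) / (x.size - 2 * c + 1)
    return stats.norm.ppf(q)
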