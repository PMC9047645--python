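"""Fixed-effect inverse-variance meta-analysis and derived quantities.

Implements the STDERR-weighting scheme of classical GWAS meta-analysis
software: each cohort's estimate enters with weight 1/SE^2, so

    beta_meta = sum(w_i beta_i) / sum(w_i),   SE_meta = sum(w_i)^{-1/2}.

The scheme is exactly associative, which makes leave-one-cohort-out
subtraction an algebraic inverse: removing a contributing cohort's weight
and weighted effect recovers the meta-analysis of the remaining cohorts
to machine precision.  Cochran's Q is reported per variant but never used
to switch to a random-effects model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SumStatsTable, harmonize_frame

META_COLS = ["chrom", "pos", "effect_allele", "other_allele", "rsid",
             "eaf", "beta", "se", "z", "pval", "n", "k_cohorts", "het_q",
             "stratum"]

#: median of the 1-df chi-square distribution
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))


class MetaError(ValueError):
    pass


def _align_cohorts(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Stack cohort frames with alleles harmonized to first occurrence."""
    ref_cols = ["chrom", "pos", "effect_allele", "other_allele", "eaf",
                "beta"]
    base = tables[0]
    ref = base.drop_duplicates(["chrom", "pos"])[ref_cols]
    out = [base]
    for t in tables[1:]:
        known = t.merge(ref, on=["chrom", "pos"], how="left",
                        suffixes=("", "_ref"))
        new_mask = known["effect_allele_ref"].isna()
        aligned, _ = harmonize_frame(ref, t, trust_strand=True)
        keep = aligned[["chrom", "pos", "effect_allele", "other_allele"]].copy()
        for c in ("rsid", "eaf", "beta", "se", "pval", "n", "stratum"):
            keep[c] = aligned[f"{c}_other"] if f"{c}_other" in aligned \
                else aligned[c]
        novel = t[new_mask.to_numpy()]
        out.append(pd.concat([keep, novel[keep.columns]], ignore_index=True))
        ref = pd.concat([ref, novel[ref_cols]], ignore_index=True)\
            .drop_duplicates(["chrom", "pos"])
    return pd.concat(out, ignore_index=True)


def ivw_meta(tables: list[SumStatsTable], maf_min: float = 0.01,
             by_stratum: bool = True) -> pd.DataFrame:
    """Fixed-effect IVW meta-analysis across cohorts.

    Cohort alleles are harmonized to the orientation of the first cohort
    carrying each variant; variants present in a subset of cohorts are
    retained with ``k_cohorts`` recorded.  ``maf_min`` filters on the
    n-weighted meta EAF (minor-allele side).  Returns a frame of
    MetaRecords with ``beta``, ``se``, ``z``, ``pval``, Cochran's
    ``het_q`` and the n-weighted ``eaf``.
    """
    if not tables:
        raise MetaError("no cohorts supplied")
    stacked = _align_cohorts([t.df for t in tables])
    group_cols = ["chrom", "pos", "effect_allele", "other_allele"]
    if by_stratum:
        group_cols.append("stratum")
    w = 1.0 / stacked["se"] ** 2
    stacked = stacked.assign(_w=w, _wb=w * stacked["beta"],
                             _wn=stacked["n"] * stacked["eaf"])
    grp = stacked.groupby(group_cols, sort=False)
    agg = grp.agg(
        rsid=("rsid", "first"),
        sw=("_w", "sum"), swb=("_wb", "sum"),
        n=("n", "sum"), swn=("_wn", "sum"),
        k_cohorts=("beta", "size"),
    ).reset_index()
    agg["beta"] = agg["swb"] / agg["sw"]
    agg["se"] = np.sqrt(1.0 / agg["sw"])
    agg["z"] = agg["beta"] / agg["se"]
    agg["pval"] = 2 * stats.norm.sf(np.abs(agg["z"]))
    agg["pval"] = agg["pval"].clip(lower=np.finfo(float).tiny)
    agg["eaf"] = agg["swn"] / agg["n"]
    # Cochran's Q needs a second pass against the combined estimate
    key = group_cols
    merged = stacked.merge(agg[key + ["beta"]], on=key,
                           suffixes=("", "_meta"))
    merged["_q"] = merged["_w"] * (merged["beta"]
                                   - merged["beta_meta"]) ** 2
    q = merged.groupby(key, sort=False)["_q"].sum().reset_index(name="het_q")
    agg = agg.merge(q, on=key)
    if not by_stratum:
        agg["stratum"] = "all"
    maf = np.minimum(agg["eaf"], 1 - agg["eaf"])
    agg = agg[maf > maf_min]
    return agg[META_COLS].sort_values(
        ["chrom", "pos", "stratum"], kind="mergesort").reset_index(drop=True)


def x_chrom_meta(male: SumStatsTable | pd.DataFrame,
                 female: SumStatsTable | pd.DataFrame,
                 maf_min: float = 0.01) -> pd.DataFrame:
    """IVW combination of the male and female X-chromosome strata.

    Inputs are the per-stratum (possibly already cross-cohort meta-
    analyzed) records; males are assumed 0/1 coded so both strata carry
    per-allele effects on the same scale.  Variants present in a single
    stratum pass through flagged via ``k_cohorts=1``.
    """
    md = male.df if isinstance(male, SumStatsTable) else male
    fd = female.df if isinstance(female, SumStatsTable) else female
    md = md.assign(stratum="all")
    fd = fd.assign(stratum="all")
    tables = [SumStatsTable(md), SumStatsTable(fd)]
    return ivw_meta(tables, maf_min=maf_min, by_stratum=True)


def meta_subtract(meta_df: pd.DataFrame, cohort: SumStatsTable | pd.DataFrame
                  ) -> pd.DataFrame:
    """Exactly remove one contributing cohort from an IVW meta-analysis.

    With w = 1/SE^2: w_rem = w_meta - w_cohort, beta_rem = (w_meta
    beta_meta - w_c beta_c) / w_rem.  Raises if the cohort is not a
    proper subset (w_rem <= 0) at any shared variant.  Variants absent
    from the cohort pass through unchanged.
    """
    cd = cohort.df if isinstance(cohort, SumStatsTable) else cohort
    joined, _ = harmonize_frame(
        meta_df, cd[["chrom", "pos", "effect_allele", "other_allele",
                     "eaf", "beta", "se", "pval", "n", "stratum"]],
        trust_strand=True)
    if "stratum_other" in joined.columns:
        joined = joined[joined["stratum"] == joined["stratum_other"]]
    out = meta_df.copy()
    if joined.empty:
        return out
    w_meta = 1.0 / joined["se"] ** 2
    w_c = 1.0 / joined["se_other"] ** 2
    w_rem = w_meta - w_c
    if (w_rem <= 0).any():
        raise MetaError("cohort not a proper subset of meta "
                        f"({int((w_rem <= 0).sum())} variants with "
                        "non-positive remaining weight)")
    beta_rem = (w_meta * joined["beta"] - w_c * joined["beta_other"]) / w_rem
    se_rem = np.sqrt(1.0 / w_rem)
    idx = out.set_index(["chrom", "pos", "effect_allele", "other_allele",
                         "stratum"]).index
    jdx = pd.MultiIndex.from_frame(
        joined[["chrom", "pos", "effect_allele", "other_allele", "stratum"]])
    pos = idx.get_indexer(jdx)
    out.iloc[pos, out.columns.get_loc("beta")] = beta_rem.to_numpy()
    out.iloc[pos, out.columns.get_loc("se")] = se_rem.to_numpy()
    z = (beta_rem / se_rem).to_numpy()
    if "z" in out.columns:
        out.iloc[pos, out.columns.get_loc("z")] = z
    out.iloc[pos, out.columns.get_loc("pval")] = np.clip(
        2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    out.iloc[pos, out.columns.get_loc("n")] = (
        joined["n"] - joined["n_other"]).to_numpy()
    if "k_cohorts" in out.columns:
        out.iloc[pos, out.columns.get_loc("k_cohorts")] = (
            out.iloc[pos, out.columns.get_loc("k_cohorts")] - 1).to_numpy()
    return out


@dataclass
class VarianceExplainedReport:
    """Per-pQTL variance contributions under Hardy-Weinberg equilibrium."""

    per_variant: pd.DataFrame   # f, beta, v = 2 f (1-f) beta^2
    total: float                # V = sum of v
    h2_input: float | None
    fraction: float | None      # V / h2_input

    def to_dict(self) -> dict:
        return {"per_variant": self.per_variant.to_dict(orient="records"),
                "total": self.total, "h2_input": self.h2_input,
                "fraction": self.fraction}


def variance_explained(leads, h2_input: float | None = None
                       ) -> VarianceExplainedReport:
    """Phenotypic variance captured by lead pQTL.

    Each lead contributes 2 f (1-f) beta^2 — the variance of one additive
    biallelic variant on a unit-variance phenotype under Hardy-Weinberg
    equilibrium.  ``leads`` is an iterable of ``(f, beta)`` pairs,
    AssocRecord-like objects or a frame with ``eaf``/``beta`` columns.
    ``fraction`` (the share of heritability explained) is reported only
    when a positive ``h2_input`` is given.
    """
    if isinstance(leads, pd.DataFrame):
        pairs = list(zip(leads["eaf"], leads["beta"]))
    else:
        pairs = [(r.eaf, r.beta) if hasattr(r, "eaf") else tuple(r)
                 for r in leads]
    for f, _ in pairs:
        if not 0 < f < 1:
            raise MetaError("allele frequency must lie strictly in (0, 1)")
    rows = [(f, b, 2.0 * f * (1 - f) * b * b) for f, b in pairs]
    per = pd.DataFrame(rows, columns=["f", "beta", "v"])
    total = float(per["v"].sum())
    frac = None
    if h2_input is not None:
        if h2_input <= 0:
            raise MetaError("h2_input must be positive to report a fraction")
        frac = total / h2_input
    return VarianceExplainedReport(per, total, h2_input, frac)


def genomic_lambda(table: SumStatsTable | pd.DataFrame) -> float:
    """Genomic-control inflation factor: median chi2 over its null median."""
    df = table.df if isinstance(table, SumStatsTable) else table
    if len(df) < 100:
        raise MetaError("need at least 100 variants for a stable lambda")
    chi2 = (df["beta"] / df["se"]) ** 2
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)
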