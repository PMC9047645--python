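"""Two-sample Mendelian randomization from summary statistics.

Instruments are genome-wide-significant exposure variants, LD-clumped
(r2 < 0.001 within a cis gene window, or r2 < 0.05 genome-wide) and
harmonized to the outcome GWAS.  The causal effect is the fixed-effect
inverse-variance-weighted combination of per-instrument Wald ratios
(outcome effect / exposure effect) with first-order weights, which
reduces algebraically to

    beta_MR = sum(bx by / sy^2) / sum(bx^2 / sy^2),
    SE      = (sum(bx^2 / sy^2))^{-1/2}.

With a binary outcome the estimate is a log odds ratio per unit (SD) of
exposure.  An optional multiplicative random-effects scaling inflates
the SE by max(1, sqrt(Q / (k - 1))) when instrument heterogeneity
exceeds its expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LDReference, clump
from .sumstats import SumStatsTable, harmonize_frame

P_GENOME_WIDE = 5e-8
CLUMP_R2 = {"cis": 0.001, "genomewide": 0.05}


class MRError(ValueError):
    pass


@dataclass
class InstrumentSet:
    """Clumped, harmonized exposure-outcome instrument table.

    Columns: variant key fields plus ``beta_exp``/``se_exp``/``pval_exp``
    and ``beta_out``/``se_out``.
    """

    df: pd.DataFrame
    mode: str
    diagnostics: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.df)


@dataclass
class MRResult:
    beta: float                 # log-OR scale for binary outcomes
    se: float
    pval: float
    n_instruments: int
    ratios: pd.DataFrame        # per-instrument Wald ratio and SE
    q: float                    # Cochran's Q across ratios
    random_effects: bool = False

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (float(np.exp(self.beta - 1.96 * self.se)),
                float(np.exp(self.beta + 1.96 * self.se)))

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        return {"beta": self.beta, "se": self.se, "pval": self.pval,
                "odds_ratio": self.odds_ratio, "ci95": [lo, hi],
                "n_instruments": self.n_instruments, "cochran_q": self.q,
                "random_effects": self.random_effects}


def select_instruments(exposure: pd.DataFrame,
                       outcome: SumStatsTable | pd.DataFrame,
                       ref: LDReference, mode: str = "cis",
                       gene_window: tuple[str, int, int] | None = None,
                       p_threshold: float = P_GENOME_WIDE,
                       r2_threshold: float | None = None,
                       clump_window_kb: float | None = None
                       ) -> InstrumentSet:
    """Clump the exposure GWAS and join harmonized outcome effects.

    ``mode='cis'`` restricts to ``gene_window`` (chrom, start, end; 1-based
    inclusive) and clumps at r2 < 0.001 over a generous 10 Mb window;
    ``mode='genomewide'`` clumps everything at r2 < 0.05 over 1 Mb.
    Instruments missing from the outcome or non-harmonizable are dropped
    and counted in the diagnostics.
    """
    if mode not in CLUMP_R2:
        raise MRError(f"mode must be one of {sorted(CLUMP_R2)}")
    r2 = CLUMP_R2[mode] if r2_threshold is None else r2_threshold
    window = (10_000.0 if mode == "cis" else 1000.0) \
        if clump_window_kb is None else clump_window_kb
    exp = exposure
    if mode == "cis":
        if gene_window is None:
            raise MRError("cis mode requires a gene_window")
        c, lo, hi = gene_window
        exp = exposure[(exposure["chrom"] == str(c))
                       & exposure["pos"].between(lo, hi)]
    n_sig = int((exp["pval"] < p_threshold).sum())
    if n_sig == 0:
        raise MRError("no genome-wide-significant exposure variants "
                      f"({mode} mode)")
    clumped = clump(exp, ref, p_threshold=p_threshold, r2_threshold=r2,
                    window_kb=window)
    odf = outcome.df if isinstance(outcome, SumStatsTable) else outcome
    joined, counts = harmonize_frame(
        clumped.index,
        odf[["chrom", "pos", "effect_allele", "other_allele", "eaf",
             "beta", "se", "pval", "n"]])
    if joined.empty:
        raise MRError(
            "no instruments survive outcome join/harmonization; "
            f"diagnostics: clumped={clumped.n_index}, {counts}")
    df = joined.rename(columns={
        "beta": "beta_exp", "se": "se_exp", "pval": "pval_exp",
        "eaf": "eaf_exp", "beta_other": "beta_out", "se_other": "se_out",
        "pval_other": "pval_out", "eaf_other": "eaf_out"})
    keep = ["chrom", "pos", "effect_allele", "other_allele",
            "beta_exp", "se_exp", "pval_exp", "eaf_exp",
            "beta_out", "se_out", "pval_out", "eaf_out"]
    if "rsid" in df.columns:
        keep.insert(4, "rsid")
    diagnostics = dict(counts, n_significant=n_sig,
                       n_clumped=clumped.n_index,
                       n_missing_outcome=clumped.n_index - len(joined))
    return InstrumentSet(df[keep].reset_index(drop=True), mode, diagnostics)


def wald_ratio(beta_exp: float, beta_out: float, se_out: float
               ) -> tuple[float, float]:
    """Single-instrument causal estimate: by/bx with first-order SE."""
    if beta_exp == 0:
        raise MRError("exposure effect is zero; Wald ratio undefined")
    return beta_out / beta_exp, abs(se_out / beta_exp)


def ivw_mr(instruments: InstrumentSet | pd.DataFrame,
           random_effects: bool = False) -> MRResult:
    """Fixed-effect IVW causal estimate over the instrument set."""
    df = instruments.df if isinstance(instruments, InstrumentSet) \
        else instruments
    if len(df) == 0:
        raise MRError("empty instrument set")
    bx = df["beta_exp"].to_numpy(float)
    by = df["beta_out"].to_numpy(float)
    sy = df["se_out"].to_numpy(float)
    w = bx * bx / (sy * sy)
    beta = float(np.sum(bx * by / (sy * sy)) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    ratios = pd.DataFrame({
        "chrom": df["chrom"], "pos": df["pos"],
        "ratio": by / bx, "se": np.abs(sy / bx)})
    q = float(np.sum(w * (ratios["ratio"].to_numpy() - beta) ** 2))
    if random_effects and len(df) > 1:
        se *= max(1.0, np.sqrt(q / (len(df) - 1)))
    pval = float(2 * stats.norm.sf(abs(beta / se)))
    return MRResult(beta, se, pval, len(df), ratios, q,
                    random_effects=random_effects)


@dataclass
class BidirectionalResult:
    forward: MRResult | None
    reverse: MRResult | None
    forward_error: str | None = None
    reverse_error: str | None = None


def bidirectional_mr(trait_a: pd.DataFrame, trait_b: SumStatsTable,
                     ref: LDReference, mode: str = "genomewide",
                     p_threshold: float = P_GENOME_WIDE,
                     random_effects: bool = False) -> BidirectionalResult:
    """Run MR in both directions between two traits.

    Forward instruments on trait A's loci; reverse on trait B's.  A
    direction with no eligible instruments is reported as not-estimable
    rather than raising.
    """
    a_df = trait_a.df if isinstance(trait_a, SumStatsTable) else trait_a
    b_df = trait_b.df if isinstance(trait_b, SumStatsTable) else trait_b
    results: list[MRResult | None] = []
    errors: list[str | None] = []
    for exposure, outcome in ((a_df, b_df), (b_df, a_df)):
        try:
            inst = select_instruments(exposure, outcome, ref, mode=mode,
                                      p_threshold=p_threshold)
            results.append(ivw_mr(inst, random_effects=random_effects))
            errors.append(None)
        except MRError as e:
            results.append(None)
            errors.append(str(e))
    return BidirectionalResult(results[0], results[1], errors[0], errors[1])
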