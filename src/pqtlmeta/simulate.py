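"""Synthetic multi-cohort pQTL study generator with known ground truth.

The generator emulates the statistical structure of a consortium plasma-
protein GWAS at desk scale: K independent cohorts measuring a rank-
inverse-normalized protein, block-LD genotypes from a Gaussian-copula
haplotype model, a strong X-chromosome cis locus (three independent
signals) plus autosomal trans loci, a polygenic background filling the
target heritability, sex-stratified X analysis with 0/1 dosage coding for
hemizygous males, a binary outcome causally downstream of the protein
(plus direct outcome loci, the configuration two-sample MR assumes), and
an annotation track enriched for the causal variants.

Haplotypes are simulated per LD block by thresholding a stationary AR(1)
Gaussian process at Phi^{-1}(1 - f_j): column j carries the effect allele
when the latent value exceeds the threshold, so the marginal allele
frequency is exactly f_j and the copula correlation ``ld_rho`` controls
LD decay within the block.  Blocks are mutually independent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import assoc
from .ld import LDReference, write_panel_vcf
from .sumstats import SumStatsTable, rank_inverse_normal, write_sumstats

AUTOSOMES = [str(c) for c in range(1, 23)]

# seed-stream codes so every artifact has its own independent stream
_S_PANEL, _S_OUTCOME, _S_ANNOT, _S_VARIANTS = 1, 2, 3, 4
_S_COHORT = 100


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic consortium.

    Defaults mirror a desk-scale version of a 14-cohort plasma-protein
    meta-analysis: three cohorts totalling 6000 samples, ~2000 SNPs in
    20-SNP LD blocks, nine autosomal trans loci jointly explaining ~3.9%
    of phenotypic variance, three independent X-chromosome cis signals
    explaining ~1.4%, an autosomal heritability target of 16% filled by a
    polygenic background, a causal protein effect on a binary outcome of
    log(1.63) per phenotypic SD, and annotations enriched fivefold (odds
    scale) at causal variants.
    """

    seed: int = 0
    n_cohorts: int = 3
    n_per_cohort: tuple[int, ...] = (6000, 6000, 6000)
    male_fraction: float = 0.5
    m_autosomal: int = 1800
    m_x: int = 200
    ld_block_size: int = 20
    ld_rho: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    spacing_bp: int = 10_000
    #: autosomal trans loci as (block index, effect-allele freq, per-allele
    #: beta on the standardized phenotype scale); a repeated block index
    #: plants an additional signal in the same LD block — the second
    #: entry in block 4 is a masked secondary (opposite sign, positive LD
    #: with the lead) whose association emerges only conditionally
    trans_effects: tuple[tuple[int, float, float], ...] = (
        (4, 0.30, 0.175), (4, 0.30, -0.08),
        (14, 0.20, 0.12), (24, 0.40, 0.09),
        (34, 0.25, 0.10), (44, 0.15, 0.11), (54, 0.35, 0.08),
        (64, 0.10, 0.12), (74, 0.45, 0.07), (84, 0.30, 0.08),
    )
    #: X-chromosome cis signals as (X block index, freq, beta); the first
    #: is the dominant lead
    cis_x_effects: tuple[tuple[int, float, float], ...] = (
        (3, 0.30, 0.14), (4, 0.10, 0.13), (5, 0.20, 0.10),
    )
    h2_target: float = 0.16
    n_background: int = 300
    #: log odds of the binary outcome per SD of protein
    theta_causal: float = float(np.log(1.63))
    outcome_prevalence: float = 0.10
    n_outcome: int = 20_000
    #: autosomal loci acting on the outcome directly (not via the protein),
    #: giving the reverse MR direction its instruments
    outcome_direct_effects: tuple[tuple[int, float, float], ...] = (
        (9, 0.40, 0.25), (29, 0.40, 0.25), (49, 0.40, 0.25),
    )
    #: LD reference panel size; large (imputation-reference scale) so the
    #: r2 < 0.001 cis clumping threshold sits above the panel's sampling
    #: noise floor (~ chi2/n_ref between truly independent variants)
    n_ref: int = 8000
    annotation_enrichment_or: float = 5.0
    annotation_base_rate: float = 0.10

    def __post_init__(self):
        if len(self.n_per_cohort) != self.n_cohorts:
            raise ValueError("n_per_cohort length must equal n_cohorts")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not 0.01 < lo < hi <= 0.5:
            raise ValueError("maf_range must lie within (0.01, 0.5]")
        for _, f, _ in (*self.trans_effects, *self.cis_x_effects):
            if not 0 < f < 1:
                raise ValueError("effect allele frequencies must be in (0,1)")
        if self.declared_autosomal_var() > self.h2_target:
            raise ValueError("declared autosomal variance exceeds h2_target")

    def declared_autosomal_var(self) -> float:
        return float(sum(2 * f * (1 - f) * b * b
                         for _, f, b in self.trans_effects))

    def declared_cis_var(self) -> float:
        return float(sum(2 * f * (1 - f) * b * b
                         for _, f, b in self.cis_x_effects))

    def to_yaml(self, path: str | Path) -> None:
        import yaml
        d = dataclasses.asdict(self)
        d["theta_causal"] = float(d["theta_causal"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml
        d = yaml.safe_load(Path(path).read_text())
        for k in ("n_per_cohort", "trans_effects", "cis_x_effects",
                  "outcome_direct_effects", "maf_range"):
            if k in d:
                d[k] = tuple(tuple(x) if isinstance(x, list) else x
                             for x in d[k])
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of one simulated study."""

    causal: pd.DataFrame          # chrom,pos,rsid,f,beta,kind
    h2_autosomal: float
    h2_cis_x: float
    theta: float
    cis_window: tuple[str, int, int]
    annotated_rsids: list[str]
    outcome_direct: pd.DataFrame  # chrom,pos,rsid,f,log_or

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "causal": self.causal.to_dict(orient="records"),
            "h2_autosomal": self.h2_autosomal,
            "h2_cis_x": self.h2_cis_x,
            "theta": self.theta,
            "cis_window": list(self.cis_window),
            "annotated_rsids": self.annotated_rsids,
            "outcome_direct": self.outcome_direct.to_dict(orient="records"),
        }, indent=2))


def _rng(cfg: SimConfig, code: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, code]))


# ---------------------------------------------------------------------------
# variant metadata (deterministic in cfg.seed; shared by every artifact)


def variant_table(cfg: SimConfig) -> pd.DataFrame:
    """Variant metadata frame: positions, alleles, MAF, block structure,
    per-variant causal effects on protein and outcome, annotation truth."""
    rng = _rng(cfg, _S_VARIANTS)
    m = cfg.m_autosomal + cfg.m_x
    bs = cfg.ld_block_size
    n_blocks_auto = -(-cfg.m_autosomal // bs)

    rows = []
    snp = 0
    chrom_cursor = {c: 0 for c in AUTOSOMES + ["X"]}
    for b in range(n_blocks_auto):
        chrom = AUTOSOMES[b % len(AUTOSOMES)]
        size = min(bs, cfg.m_autosomal - b * bs)
        for _ in range(size):
            chrom_cursor[chrom] += cfg.spacing_bp
            rows.append((chrom, chrom_cursor[chrom], b))
            snp += 1
    n_blocks_x = -(-cfg.m_x // bs)
    for bx in range(n_blocks_x):
        size = min(bs, cfg.m_x - bx * bs)
        for _ in range(size):
            chrom_cursor["X"] += cfg.spacing_bp
            rows.append(("X", chrom_cursor["X"], n_blocks_auto + bx))
            snp += 1
    df = pd.DataFrame(rows, columns=["chrom", "pos", "block"])
    df["rsid"] = [f"rs{j + 1:06d}" for j in range(m)]
    bases = np.array(list("ACGT"))
    pair = rng.integers(0, 4, size=(m, 2))
    pair[:, 1] = (pair[:, 0] + 1 + rng.integers(0, 3, size=m)) % 4
    df["effect_allele"] = bases[pair[:, 0]]
    df["other_allele"] = bases[pair[:, 1]]
    df["maf"] = rng.uniform(*cfg.maf_range, size=m)
    df["beta"] = 0.0
    df["kind"] = ""
    df["outcome_log_or"] = 0.0

    placed: dict[int, int] = {}

    def _mid(block: int) -> int:
        """Middle SNP of a block; repeated declarations in the same block
        step outward two SNPs at a time (planting linked co-localized
        signals, e.g. a masked secondary)."""
        idx = df.index[df["block"] == block]
        if len(idx) == 0:
            raise ValueError(f"declared effect in nonexistent block {block}")
        k = placed.get(block, 0)
        placed[block] = k + 1
        j = len(idx) // 2 + 2 * k
        if j >= len(idx):
            raise ValueError(f"too many effects declared in block {block}")
        return int(idx[j])

    for b, f, beta in cfg.trans_effects:
        j = _mid(b)
        df.loc[j, ["maf", "beta", "kind"]] = [f, beta, "trans"]
    for b, f, beta in cfg.cis_x_effects:
        j = _mid(n_blocks_auto + b)
        df.loc[j, ["maf", "beta", "kind"]] = [f, beta, "cis"]
    for b, f, log_or in cfg.outcome_direct_effects:
        j = _mid(b)
        if df.loc[j, "kind"]:
            raise ValueError("outcome direct effect collides with pQTL")
        df.loc[j, "maf"] = f
        df.loc[j, "outcome_log_or"] = log_or
        df.loc[j, "kind"] = "outcome_direct"

    # polygenic background: tiny effects on autosomal SNPs outside the
    # declared-locus blocks (so the background never sits in LD with a
    # declared causal variant and marginal effects at leads stay clean)
    spare = cfg.h2_target - cfg.declared_autosomal_var()
    taken_blocks = set(df.loc[df["kind"] != "", "block"])
    free = df.index[(df["kind"] == "") & (df["chrom"] != "X")
                    & ~df["block"].isin(taken_blocks)].to_numpy()
    nbg = min(cfg.n_background, len(free))
    if spare > 0 and nbg > 0:
        bg = rng.choice(free, size=nbg, replace=False)
        v_per = spare / nbg
        f_bg = df.loc[bg, "maf"].to_numpy()
        mag = np.sqrt(v_per / (2 * f_bg * (1 - f_bg)))
        df.loc[bg, "beta"] = mag * rng.choice([-1.0, 1.0], size=nbg)
        df.loc[bg, "kind"] = "background"

    # annotation membership: enriched odds at declared causal variants
    arng = _rng(cfg, _S_ANNOT)
    p0 = cfg.annotation_base_rate
    odds1 = cfg.annotation_enrichment_or * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    causal = df["kind"].isin(["trans", "cis"]).to_numpy()
    u = arng.uniform(size=m)
    df["annotated"] = np.where(causal, u < p1, u < p0)
    return df


def cis_window(cfg: SimConfig, meta: pd.DataFrame | None = None,
               margin: int = 100_000) -> tuple[str, int, int]:
    """X-chromosome cis gene window covering the declared cis signals."""
    meta = variant_table(cfg) if meta is None else meta
    cis = meta[meta["kind"] == "cis"]
    return ("X", max(1, int(cis["pos"].min()) - margin),
            int(cis["pos"].max()) + margin)


# ---------------------------------------------------------------------------
# haplotypes and genotypes


def _draw_haplotypes(meta: pd.DataFrame, rho: float, n_hap: int,
                     rng: np.random.Generator,
                     cols: np.ndarray | None = None) -> np.ndarray:
    """Threshold an AR(1) latent Gaussian into 0/1 haplotypes.

    The AR(1) process restarts at each block boundary, so blocks are
    exactly independent.  ``cols`` restricts output to those variant
    columns (the full latent chain is still advanced for reproducibility
    of block structure, but only within the blocks touched).
    """
    maf = meta["maf"].to_numpy()
    block = meta["block"].to_numpy()
    thr = stats.norm.ppf(1.0 - maf)
    m = len(meta)
    want = np.zeros(m, dtype=bool)
    want[np.arange(m) if cols is None else cols] = True
    blocks_needed = np.unique(block[want])
    out_cols = np.flatnonzero(want)
    out = np.zeros((n_hap, len(out_cols)), dtype=np.int8)
    colmap = {c: i for i, c in enumerate(out_cols)}
    s = np.sqrt(1.0 - rho * rho)
    for b in blocks_needed:
        jj = np.flatnonzero(block == b)
        eps = rng.standard_normal((n_hap, len(jj)))
        z = eps[:, 0].copy()
        for t, j in enumerate(jj):
            if t > 0:
                z = rho * z + s * eps[:, t]
            if j in colmap:
                out[:, colmap[j]] = (z > thr[j]).astype(np.int8)
        del eps
    return out


def _draw_cohort_genotypes(meta: pd.DataFrame, cfg: SimConfig, n: int,
                           rng: np.random.Generator
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Genotypes for one cohort: diploid autosomes; X dosage 0/1 for males.

    Returns ``(G, is_male)`` where G[i, j] counts effect alleles (males
    carry a single X haplotype).
    """
    m = len(meta)
    is_male = rng.uniform(size=n) < cfg.male_fraction
    h1 = _draw_haplotypes(meta, cfg.ld_rho, n, rng)
    h2 = _draw_haplotypes(meta, cfg.ld_rho, n, rng)
    g = (h1 + h2).astype(np.int8)
    x_cols = np.flatnonzero((meta["chrom"] == "X").to_numpy())
    if len(x_cols):
        g[np.ix_(is_male, x_cols)] = h1[np.ix_(is_male, x_cols)]
    return g, is_male


def _phenotype(meta: pd.DataFrame, g: np.ndarray, is_male: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """Additive liability with unit variance before measurement transform."""
    beta = meta["beta"].to_numpy()
    f = meta["maf"].to_numpy()
    causal = np.flatnonzero(beta != 0)
    x_mask = (meta["chrom"] == "X").to_numpy()
    yg = g[:, causal].astype(float) @ beta[causal]
    # theoretical genetic variance per sex (X is haploid in males)
    auto_c = causal[~x_mask[causal]]
    x_c = causal[x_mask[causal]]
    v_auto = float(np.sum(2 * f[auto_c] * (1 - f[auto_c]) * beta[auto_c] ** 2))
    v_x_f = float(np.sum(2 * f[x_c] * (1 - f[x_c]) * beta[x_c] ** 2))
    v_x_m = float(np.sum(f[x_c] * (1 - f[x_c]) * beta[x_c] ** 2))
    var_e = 1.0 - v_auto - np.where(is_male, v_x_m, v_x_f)
    var_e = np.maximum(var_e, 0.05)
    return yg + rng.standard_normal(len(g)) * np.sqrt(var_e)


# ---------------------------------------------------------------------------
# public operations


def simulate_ld_panel(cfg: SimConfig) -> LDReference:
    """Phased diploid reference panel (X represented as female samples)."""
    meta = variant_table(cfg)
    rng = _rng(cfg, _S_PANEL)
    hap = np.vstack([_draw_haplotypes(meta, cfg.ld_rho, cfg.n_ref, rng),
                     _draw_haplotypes(meta, cfg.ld_rho, cfg.n_ref, rng)])
    # interleave so haplotypes 2i, 2i+1 belong to sample i
    order = np.empty(2 * cfg.n_ref, dtype=int)
    order[0::2] = np.arange(cfg.n_ref)
    order[1::2] = np.arange(cfg.n_ref) + cfg.n_ref
    hap = hap[order]
    geno = (hap[0::2] + hap[1::2]).astype(np.int8)
    keys = meta[["chrom", "pos", "effect_allele", "other_allele",
                 "rsid"]].copy()
    return LDReference(keys, geno, hap)


def _records(meta: pd.DataFrame, idx: np.ndarray, beta, se, pval, eaf, n,
             stratum: str) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": meta["chrom"].to_numpy()[idx],
        "pos": meta["pos"].to_numpy()[idx],
        "effect_allele": meta["effect_allele"].to_numpy()[idx],
        "other_allele": meta["other_allele"].to_numpy()[idx],
        "rsid": meta["rsid"].to_numpy()[idx],
        "eaf": eaf, "beta": beta, "se": se, "pval": pval, "n": n,
        "stratum": stratum,
    })


def cohort_individual_data(cfg: SimConfig, cohort: int,
                           meta: pd.DataFrame | None = None
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Individual-level data for one cohort: the exact draws behind
    :func:`simulate_cohort_gwas`.

    Returns ``(G, is_male, y)`` with ``y`` already rank-inverse-normal
    transformed — the regression input of the per-SNP scan, so pooled or
    joint individual-level fits can serve as oracles for summary-level
    methods.
    """
    if not 0 <= cohort < cfg.n_cohorts:
        raise ValueError("cohort index out of range")
    meta = variant_table(cfg) if meta is None else meta
    n = cfg.n_per_cohort[cohort]
    rng = _rng(cfg, _S_COHORT + cohort)
    g, is_male = _draw_cohort_genotypes(meta, cfg, n, rng)
    y = rank_inverse_normal(_phenotype(meta, g, is_male, rng))
    return g, is_male, y


def simulate_cohort_gwas(cfg: SimConfig, cohort: int,
                         meta: pd.DataFrame | None = None) -> SumStatsTable:
    """Marginal per-SNP GWAS of the protein in one cohort.

    The phenotype is rank-inverse-normal transformed before regression.
    Autosomes are analyzed in everyone (stratum ``all``); X-chromosome
    SNPs are analyzed separately in males (0/1 dosage) and females
    (0/1/2), yielding ``male``/``female`` strata.
    """
    g, is_male, y = cohort_individual_data(cfg, cohort, meta)
    meta = variant_table(cfg) if meta is None else meta
    n = cfg.n_per_cohort[cohort]

    x_mask = (meta["chrom"] == "X").to_numpy()
    auto = np.flatnonzero(~x_mask)
    xc = np.flatnonzero(x_mask)
    frames = []
    ga = g[:, auto].astype(float)
    beta, se, pval = assoc.ols_scan(ga, y)
    eaf = ga.mean(axis=0) / 2.0
    frames.append(_records(meta, auto, beta, se, pval, eaf, n, "all"))
    for stratum, sel in (("male", is_male), ("female", ~is_male)):
        gs = g[np.ix_(sel, xc)].astype(float)
        beta, se, pval = assoc.ols_scan(gs, y[sel])
        ploidy = 1.0 if stratum == "male" else 2.0
        eaf = gs.mean(axis=0) / ploidy
        frames.append(_records(meta, xc, beta, se, pval, eaf,
                               int(sel.sum()), stratum))
    df = pd.concat(frames, ignore_index=True)
    ok = (df["se"] > 0) & np.isfinite(df["se"]) & (df["eaf"] > 0) & \
        (df["eaf"] < 1)
    df.loc[~ok, "pval"] = np.nan
    df = df[ok].copy()
    df["pval"] = df["pval"].clip(lower=np.finfo(float).tiny)
    return SumStatsTable(df, meta={"cohort": cohort, "n": n,
                                   "phenotype": "protein"})


def simulate_outcome_gwas(cfg: SimConfig, meta: pd.DataFrame | None = None
                          ) -> SumStatsTable:
    """Case-control GWAS of the binary outcome downstream of the protein.

    Case status is Bernoulli(expit(alpha + theta * y + direct effects)),
    with alpha root-solved so the empirical prevalence matches the target.
    Per-SNP logistic regressions give log-OR records; X SNPs are analyzed
    per sex and inverse-variance combined into a single ``all`` record.
    """
    meta = variant_table(cfg) if meta is None else meta
    rng = _rng(cfg, _S_OUTCOME)
    n = cfg.n_outcome
    g, is_male = _draw_cohort_genotypes(meta, cfg, n, rng)
    y = _phenotype(meta, g, is_male, rng)
    direct = meta["outcome_log_or"].to_numpy()
    dj = np.flatnonzero(direct != 0)
    eta_gen = cfg.theta_causal * y
    if len(dj):
        gd = g[:, dj].astype(float)
        eta_gen = eta_gen + (gd - gd.mean(axis=0)) @ direct[dj]

    def excess(alpha: float) -> float:
        return float(np.mean(special.expit(alpha + eta_gen))
                     - cfg.outcome_prevalence)

    alpha = optimize.brentq(excess, -20.0, 20.0)
    case = rng.uniform(size=n) < special.expit(alpha + eta_gen)

    x_mask = (meta["chrom"] == "X").to_numpy()
    auto = np.flatnonzero(~x_mask)
    xc = np.flatnonzero(x_mask)
    ga = g[:, auto].astype(float)
    beta, se, pval = assoc.logistic_scan(ga, case.astype(float))
    frames = [_records(meta, auto, beta, se, pval, ga.mean(axis=0) / 2.0,
                       n, "all")]
    if len(xc):
        stats_by_sex = {}
        for label, sel in (("male", is_male), ("female", ~is_male)):
            gs = g[np.ix_(sel, xc)].astype(float)
            stats_by_sex[label] = assoc.logistic_scan(
                gs, case[sel].astype(float))
        (bm, sm, _), (bf, sf, _) = (stats_by_sex["male"],
                                    stats_by_sex["female"])
        wm, wf = 1.0 / sm ** 2, 1.0 / sf ** 2
        w = wm + wf
        bx = (wm * bm + wf * bf) / w
        sx = np.sqrt(1.0 / w)
        px = 2 * stats.norm.sf(np.abs(bx / sx))
        n_m, n_f = int(is_male.sum()), int((~is_male).sum())
        eaf_x = (g[:, xc].sum(axis=0)) / (n_m + 2.0 * n_f)
        frames.append(_records(meta, xc, bx, sx, px, eaf_x, n, "all"))
    df = pd.concat(frames, ignore_index=True)
    ok = np.isfinite(df["se"]) & (df["se"] > 0) & (df["eaf"] > 0) & \
        (df["eaf"] < 1)
    df = df[ok].copy()
    df["pval"] = df["pval"].clip(lower=np.finfo(float).tiny)
    return SumStatsTable(df, meta={"phenotype": "outcome", "n": n,
                                   "prevalence": float(case.mean())})


def simulate_annotations(cfg: SimConfig, meta: pd.DataFrame | None = None,
                         half_width: int = 500
                         ) -> tuple[pd.DataFrame, np.ndarray]:
    """BED-style annotation intervals realizing the configured enrichment.

    Membership was drawn in :func:`variant_table` (causal variants enter
    the annotation at ``annotation_enrichment_or`` times the baseline
    odds); each annotated SNP contributes a 0-based half-open interval
    around its position.  Returns (bed frame, membership truth).
    """
    meta = variant_table(cfg) if meta is None else meta
    member = meta["annotated"].to_numpy()
    ann = meta[member]
    bed = pd.DataFrame({
        "chrom": ann["chrom"].to_numpy(),
        "start": np.maximum(ann["pos"].to_numpy() - 1 - half_width, 0),
        "end": ann["pos"].to_numpy() + half_width,
        "name": ann["rsid"].to_numpy(),
    })
    return bed, member


def truth(cfg: SimConfig, meta: pd.DataFrame | None = None) -> SimTruth:
    meta = variant_table(cfg) if meta is None else meta
    causal = meta[meta["kind"].isin(["trans", "cis", "background"])]
    causal = causal[["chrom", "pos", "rsid", "maf", "beta", "kind"]].rename(
        columns={"maf": "f"})
    direct = meta[meta["outcome_log_or"] != 0]
    direct = direct[["chrom", "pos", "rsid", "maf", "outcome_log_or"]]\
        .rename(columns={"maf": "f", "outcome_log_or": "log_or"})
    return SimTruth(
        causal=causal.reset_index(drop=True),
        h2_autosomal=cfg.h2_target,
        h2_cis_x=cfg.declared_cis_var(),
        theta=cfg.theta_causal,
        cis_window=cis_window(cfg, meta),
        annotated_rsids=meta.loc[meta["annotated"], "rsid"].tolist(),
        outcome_direct=direct.reset_index(drop=True),
    )


def simulate_study(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full synthetic study to ``outdir``.

    Produces per-cohort GWAS-SSF TSVs, a phased VCF LD panel, the binary
    outcome GWAS TSV, an annotation BED track, the ground-truth JSON and
    the generating config YAML.  Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = variant_table(cfg)
    paths: dict[str, Path] = {}
    for i in range(cfg.n_cohorts):
        p = outdir / f"cohort{i}.tsv"
        write_sumstats(simulate_cohort_gwas(cfg, i, meta), p)
        paths[f"cohort{i}"] = p
    panel = simulate_ld_panel(cfg)
    paths["panel"] = outdir / "panel.vcf"
    write_panel_vcf(panel, paths["panel"])
    paths["outcome"] = outdir / "outcome.tsv"
    write_sumstats(simulate_outcome_gwas(cfg, meta), paths["outcome"])
    bed, _ = simulate_annotations(cfg, meta)
    paths["annotations"] = outdir / "annotations.bed"
    bed.to_csv(paths["annotations"], sep="\t", header=False, index=False)
    paths["truth"] = outdir / "truth.json"
    truth(cfg, meta).to_json(paths["truth"])
    paths["config"] = outdir / "config.yaml"
    cfg.to_yaml(paths["config"])
    return paths


# ---------------------------------------------------------------------------
# focused generators for calibration studies


def two_snp_dataset(n: int, f1: float, f2: float, rho: float,
                    beta1: float, beta2: float,
                    rng: np.random.Generator,
                    flip_second: bool = False
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Individual-level data for a two-SNP locus.

    Genotypes come from the same Gaussian-copula mechanism as the main
    simulator; ``flip_second`` recodes SNP 2 to its other allele
    (dosage -> 2 - dosage), inducing negative LD with SNP 1 — the masking
    configuration in which conditioning strengthens a secondary signal.
    Returns ``(G, y)`` with Var(y) = 1.
    """
    thr = stats.norm.ppf([1 - f1, 1 - f2])
    s = np.sqrt(1 - rho * rho)
    g = np.zeros((n, 2))
    for _ in range(2):  # two haplotypes
        e = rng.standard_normal((n, 2))
        z2 = rho * e[:, 0] + s * e[:, 1]
        g += np.column_stack([e[:, 0] > thr[0], z2 > thr[1]])
    if flip_second:
        g[:, 1] = 2 - g[:, 1]
        f2 = 1 - f2
    b = np.array([beta1, beta2])
    f = np.array([f1, f2])
    vg = float(np.var(g @ b))
    var_e = max(1.0 - vg, 0.05)
    y = g @ b + rng.standard_normal(n) * np.sqrt(var_e)
    return g, y - y.mean()


def null_enrichment_dataset(m: int, rng: np.random.Generator,
                            mu: float = -2.2, delta: float = 0.1,
                            base_rate: float = 0.1
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Significance indicators from the enrichment model's null.

    Per-SNP significance is Bernoulli(expit(mu + delta * ell_j)) with LD
    scores drawn from a shifted gamma, and annotation membership drawn
    independently of significance — the configuration under which the
    annotation coefficient of the enrichment regression is zero.
    Returns ``(ell, C, significant)``.
    """
    ell = 1.0 + rng.gamma(shape=2.0, scale=2.0, size=m)
    sig = rng.uniform(size=m) < special.expit(mu + delta * ell)
    c = rng.uniform(size=m) < base_rate
    return ell, c.astype(int), sig.astype(int)
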