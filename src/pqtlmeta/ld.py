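"""LD reference panels: pairwise r2 and D', LD scores, p-value clumping.

The panel stores effect-allele dosages (0/1/2) for a set of reference
samples, optionally with phased haplotypes (0/1).  D' uses haplotype
frequencies directly when haplotypes are available and otherwise the
two-locus EM maximum-likelihood haplotype-frequency estimate from unphased
genotypes.  r2 is the squared Pearson correlation of allele counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

KEY_COLS = ["chrom", "pos", "effect_allele", "other_allele"]


class PanelError(ValueError):
    pass


@dataclass
class LDReference:
    """Genotype reference panel for LD computation.

    ``keys``: one row per variant (chrom, pos, effect_allele, other_allele,
    rsid), position-sorted within chromosome.  ``genotypes``: (n_samples, m)
    effect-allele dosages.  ``haplotypes``: optional (2*n_samples, m) phased
    alleles; the panel is diploid (X represented by female samples).
    """

    keys: pd.DataFrame
    genotypes: np.ndarray
    haplotypes: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.keys = self.keys.reset_index(drop=True)
        if self.genotypes.shape != (self.genotypes.shape[0], len(self.keys)):
            raise PanelError("genotype matrix does not match keys")
        self._index = {}
        for j, row in enumerate(self.keys.itertuples(index=False)):
            self._index[(row.chrom, int(row.pos),
                         frozenset((row.effect_allele, row.other_allele)))] = j

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]

    def column(self, chrom, pos, effect_allele, other_allele) -> int | None:
        """Column index for a variant, matching either allele orientation."""
        return self._index.get(
            (str(chrom), int(pos), frozenset((effect_allele, other_allele))))


@dataclass
class LDPair:
    r2: float
    dprime: float
    ok: bool = True
    reason: str | None = None


def _dprime_from_hapfreq(p_ab: float, p_a: float, p_b: float) -> float:
    d = p_ab - p_a * p_b
    if d >= 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    return 0.0 if dmax <= 0 else abs(d) / dmax


def _em_hapfreq(ga: np.ndarray, gb: np.ndarray, max_iter: int = 200,
                tol: float = 1e-12) -> tuple[float, float, float]:
    """EM estimate of the A-B haplotype frequency from unphased dosages.

    Only double heterozygotes are phase-ambiguous; all other genotype
    combinations contribute known haplotype counts.
    """
    n = len(ga)
    p_a = float(np.mean(ga)) / 2.0
    p_b = float(np.mean(gb)) / 2.0
    dh = (ga == 1) & (gb == 1)
    n_dh = int(dh.sum())
    # every individual except a double heterozygote has a unique phase;
    # count their A-B haplotypes directly
    a_nh, b_nh = ga[~dh], gb[~dh]
    ab = np.zeros(len(a_nh))
    for val_a in (0, 1, 2):
        for val_b in (0, 1, 2):
            if val_a == 1 and val_b == 1:
                continue
            mask = (a_nh == val_a) & (b_nh == val_b)
            if not mask.any():
                continue
            # haplotypes: locus1 alleles sorted to pair with locus2; with
            # at most one heterozygous locus the pairing is forced
            h1 = (min(val_a, 1), min(val_b, 1))
            h2 = (val_a - h1[0], val_b - h1[1])
            ab[mask] = (h1 == (1, 1)) + (h2 == (1, 1))
    fixed = float(ab.sum())
    p_ab = p_a * p_b if p_a * p_b > 0 else 0.25
    for _ in range(max_iter):
        # P(AB/ab phase | double het) given current haplotype freqs
        p_Ab = p_a - p_ab
        p_aB = p_b - p_ab
        p_abq = 1 - p_a - p_b + p_ab
        num = p_ab * p_abq
        den = num + p_Ab * p_aB
        frac = 0.5 if den <= 0 else num / den
        new = (fixed + n_dh * frac) / (2.0 * n)
        if abs(new - p_ab) < tol:
            p_ab = new
            break
        p_ab = new
    return p_ab, p_a, p_b


def ld_pair(ref: LDReference, a, b) -> LDPair:
    """Pairwise LD (r2, D') between two panel variants.

    ``a``/``b`` may be column indices or (chrom, pos, ea, oa) tuples /
    VariantKey-like objects.  Monomorphic variants make LD undefined.
    """
    ja, jb = (_resolve(ref, v) for v in (a, b))
    ga = ref.genotypes[:, ja].astype(float)
    gb = ref.genotypes[:, jb].astype(float)
    if ga.std() == 0 or gb.std() == 0:
        return LDPair(np.nan, np.nan, ok=False, reason="monomorphic")
    if ref.haplotypes is not None:
        ha = ref.haplotypes[:, ja].astype(float)
        hb = ref.haplotypes[:, jb].astype(float)
        p_a, p_b = ha.mean(), hb.mean()
        p_ab = float(np.mean(ha * hb))
        d = p_ab - p_a * p_b
        denom = p_a * (1 - p_a) * p_b * (1 - p_b)
        r2 = d * d / denom
        return LDPair(float(r2), _dprime_from_hapfreq(p_ab, p_a, p_b))
    r = float(np.corrcoef(ga, gb)[0, 1])
    p_ab, p_a, p_b = _em_hapfreq(ga.astype(int), gb.astype(int))
    return LDPair(r * r, _dprime_from_hapfreq(p_ab, p_a, p_b))


def _resolve(ref: LDReference, v) -> int:
    if isinstance(v, (int, np.integer)):
        return int(v)
    if hasattr(v, "chrom"):
        j = ref.column(v.chrom, v.pos, v.effect_allele, v.other_allele)
    else:
        j = ref.column(*v)
    if j is None:
        raise PanelError(f"variant {v!r} not in panel")
    return j


def ld_scores(ref: LDReference, window_kb: float = 1000.0) -> np.ndarray:
    """Per-variant LD scores: windowed sums of bias-adjusted r2.

    ell_j = 1 + sum over other variants k within ``window_kb`` of
    r2_jk - (1 - r2_jk) / (n_ref - 2), the standard small-sample
    adjustment; the self term contributes exactly 1.
    """
    n = ref.n_samples
    out = np.ones(ref.m)
    pos = ref.keys["pos"].to_numpy()
    win = window_kb * 1000.0
    g = ref.genotypes.astype(float)
    sd = g.std(axis=0)
    for chrom, idx in ref.keys.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        poly = idx[sd[idx] > 0]
        if len(poly) < 2:
            continue
        x = g[:, poly]
        x = (x - x.mean(axis=0)) / x.std(axis=0)
        r = (x.T @ x) / x.shape[0]
        r2 = r * r
        adj = r2 - (1.0 - r2) / max(n - 2, 1)
        p = pos[poly]
        mask = np.abs(p[:, None] - p[None, :]) <= win
        np.fill_diagonal(mask, False)
        out[poly] += (adj * mask).sum(axis=1)
    return out


@dataclass
class ClumpResult:
    """Greedy clumping outcome: retained index variants and absorption map."""

    index: pd.DataFrame             # rows of the input retained as indices
    absorbed: pd.DataFrame          # removed variant, absorbing index, r2
    missing_from_panel: int = 0

    @property
    def n_index(self) -> int:
        return len(self.index)


def clump(table: pd.DataFrame, ref: LDReference, p_threshold: float = 5e-8,
          r2_threshold: float = 0.001, window_kb: float = 1000.0
          ) -> ClumpResult:
    """Greedy p-value clumping against a reference panel.

    Qualifying variants (p < ``p_threshold``) are scanned in order of
    ascending p (ties broken by chromosome, position, then allele order);
    each scan retains the best remaining variant as an index and absorbs
    every remaining qualifying variant on the same chromosome within
    ``window_kb`` whose panel r2 with the index exceeds ``r2_threshold``.
    Variants absent from the panel are treated as unlinked.
    """
    df = table.loc[table["pval"] < p_threshold].copy()
    df = df.sort_values(["pval", "chrom", "pos", "effect_allele",
                         "other_allele"], kind="mergesort")
    def _col(r):
        j = ref.column(r.chrom, r.pos, r.effect_allele, r.other_allele)
        return -1 if j is None else j

    cols = np.array([_col(r) for r in df.itertuples(index=False)],
                    dtype=int)
    n_missing = int((cols < 0).sum())
    if n_missing:
        warnings.warn(f"{n_missing} qualifying variants absent from LD "
                      "panel; treated as unlinked")
    g = ref.genotypes.astype(float)
    gstd = g.std(axis=0)
    pos = df["pos"].to_numpy()
    chrom = df["chrom"].to_numpy()
    alive = np.ones(len(df), dtype=bool)
    order = np.arange(len(df))
    index_rows, absorbed = [], []
    win = window_kb * 1000.0
    for i in order:
        if not alive[i]:
            continue
        alive[i] = False
        index_rows.append(i)
        cand = np.where(alive & (chrom == chrom[i])
                        & (np.abs(pos - pos[i]) <= win))[0]
        if len(cand) == 0 or cols[i] < 0:
            continue
        gi = g[:, cols[i]]
        if gstd[cols[i]] == 0:
            continue
        for k in cand:
            if cols[k] < 0 or gstd[cols[k]] == 0:
                continue
            r = np.corrcoef(gi, g[:, cols[k]])[0, 1]
            if r * r > r2_threshold:
                alive[k] = False
                absorbed.append((k, i, r * r))
    idx_df = df.iloc[index_rows].reset_index(drop=True)
    ab_df = pd.DataFrame(
        [(df.iloc[k]["chrom"], df.iloc[k]["pos"],
          df.iloc[k]["effect_allele"], df.iloc[k]["other_allele"],
          df.iloc[i]["chrom"], df.iloc[i]["pos"],
          df.iloc[i]["effect_allele"], df.iloc[i]["other_allele"], r2)
         for k, i, r2 in absorbed],
        columns=["chrom", "pos", "effect_allele", "other_allele",
                 "index_chrom", "index_pos", "index_effect_allele",
                 "index_other_allele", "r2"])
    return ClumpResult(idx_df, ab_df, n_missing)


# ---------------------------------------------------------------------------
# VCF I/O


def write_panel_vcf(ref: LDReference, path: str | Path) -> None:
    """Write the panel as a plain-text VCF with phased or unphased GT."""
    path = Path(path)
    n = ref.n_samples
    phased = ref.haplotypes is not None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(ref.keys["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype">\n')
        samples = "\t".join(f"S{i:04d}" for i in range(n))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + samples + "\n")
        if phased:
            lut = np.array(["0|0", "0|1", "1|0", "1|1"])
            codes = (2 * ref.haplotypes[0::2, :]
                     + ref.haplotypes[1::2, :]).astype(np.int8)
        else:
            lut = np.array(["0/0", "0/1", "1/1"])
            codes = ref.genotypes
        for j, row in enumerate(ref.keys.itertuples(index=False)):
            rsid = row.rsid if "rsid" in ref.keys.columns and \
                isinstance(row.rsid, str) else "."
            gts = "\t".join(lut[codes[:, j]])
            # ALT is the effect (counted) allele
            fh.write(f"{row.chrom}\t{row.pos}\t{rsid}\t{row.other_allele}\t"
                     f"{row.effect_allele}\t.\tPASS\t.\tGT\t{gts}\n")


def read_panel_vcf(path: str | Path) -> LDReference:
    """Load a hard-call VCF into an LDReference (dosages of ALT allele)."""
    from cyvcf2 import VCF

    keys, dosage_rows, hap_rows = [], [], []
    phased_all = True
    vcf = VCF(str(path))
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        keys.append((str(var.CHROM), int(var.POS), var.ALT[0], var.REF,
                     var.ID if var.ID else None))
        gt = np.asarray(var.genotype.array())
        a0 = np.clip(gt[:, 0], 0, 1)
        a1 = np.clip(gt[:, 1], 0, 1)
        dosage_rows.append(a0 + a1)
        hap_rows.append(np.column_stack([a0, a1]).reshape(-1))
        phased_all &= bool(np.all(gt[:, 2] == 1)) if gt.shape[1] > 2 else False
    keys_df = pd.DataFrame(keys, columns=KEY_COLS + ["rsid"])
    geno = np.asarray(dosage_rows, dtype=np.int8).T
    hap = np.asarray(hap_rows, dtype=np.int8).T if phased_all else None
    return LDReference(keys_df, geno, hap)
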