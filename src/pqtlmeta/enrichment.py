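"""SNP-level annotation enrichment of genome-wide-significant signals.

For each annotation track, a logistic regression of the per-SNP
significance indicator on the SNP's LD score and its annotation
membership:

    logit P(p_j < alpha_gw) = mu + delta * ell_j + beta * C_j

where ell_j corrects for the extra association signal a high-LD SNP tags
and beta is the log odds ratio of significant associations inside the
annotation versus outside — the parameter of interest.  Fits use
iteratively reweighted least squares (via statsmodels GLM); complete
separation falls back to a Firth-penalized fit.  Scans across tracks are
Benjamini-Hochberg corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

P_GENOME_WIDE = 5e-8
#: default mask for the major-histocompatibility-complex region, whose
#: extreme LD structure distorts SNP-level enrichment on real data
MHC_REGION = ("6", 25_000_000, 34_000_000)


class EnrichmentError(ValueError):
    pass


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED track (0-based half-open intervals), tab-delimited."""
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise EnrichmentError(f"{path}: malformed BED line {i}")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as e:
            raise EnrichmentError(f"{path}: malformed BED line {i}") from e
        chrom = parts[0].removeprefix("chr")
        rows.append((chrom, start, end,
                     parts[3] if len(parts) > 3 else ""))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def annotate_snps(table: pd.DataFrame, bed: pd.DataFrame,
                  scores: np.ndarray | pd.Series,
                  mask_mhc: bool = False) -> pd.DataFrame:
    """Attach annotation membership C_j and LD scores to a SNP table.

    BED intervals are 0-based half-open; SNP positions are 1-based, so a
    SNP at position p is annotated iff p - 1 falls in [start, end) of any
    interval.  SNPs without a finite LD score are dropped (counted in the
    ``n_dropped_no_score`` attribute of the result).
    """
    df = table.copy()
    ell = np.asarray(scores, dtype=float)
    if len(ell) != len(df):
        raise EnrichmentError("scores length does not match table")
    df["ell"] = ell
    trees: dict[str, IntervalTree] = {}
    for r in bed.itertuples(index=False):
        if r.end > r.start:
            trees.setdefault(str(r.chrom), IntervalTree()).addi(
                r.start, r.end)
    c = np.zeros(len(df), dtype=int)
    pos0 = df["pos"].to_numpy() - 1
    for i, (chrom, p) in enumerate(zip(df["chrom"].to_numpy(), pos0)):
        t = trees.get(str(chrom))
        if t is not None and t.overlaps_point(int(p)):
            c[i] = 1
    df["C"] = c
    if mask_mhc:
        mc, mlo, mhi = MHC_REGION
        df = df[~((df["chrom"] == mc) & df["pos"].between(mlo, mhi))]
    keep = np.isfinite(df["ell"].to_numpy())
    out = df[keep].reset_index(drop=True)
    out.attrs["n_dropped_no_score"] = int((~keep).sum())
    return out


@dataclass
class EnrichmentModel:
    mu: float
    delta: float | None          # None when the LD covariate is excluded
    beta: float
    se_mu: float
    se_delta: float | None
    se_beta: float
    z: float                     # Wald z for beta
    pval: float
    n_snps: int
    n_significant: int
    converged: bool = True
    firth: bool = False
    label: str = ""

    def to_dict(self) -> dict:
        return {"label": self.label, "mu": self.mu, "delta": self.delta,
                "beta": self.beta, "se_beta": self.se_beta, "z": self.z,
                "pval": self.pval, "n_snps": self.n_snps,
                "n_significant": self.n_significant,
                "converged": self.converged, "firth": self.firth}


def _firth_fit(x: np.ndarray, y: np.ndarray, max_iter: int = 100,
               tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Jeffreys-prior-penalized logistic fit (Firth), for separation."""
    k = x.shape[1]
    b = np.zeros(k)
    for _ in range(max_iter):
        eta = x @ b
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        xw = x * w[:, None]
        info = x.T @ xw
        cov = np.linalg.inv(info)
        h = np.einsum("ij,jk,ik->i", xw / np.maximum(w[:, None], 1e-12),
                      cov, xw)
        u = x.T @ (y - p + h * (0.5 - p))
        step = cov @ u
        b = b + step
        if np.abs(step).max() < tol:
            break
    eta = x @ b
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    cov = np.linalg.inv(x.T @ (x * w[:, None]))
    return b, np.sqrt(np.diag(cov))


def fit_enrichment(matrix: pd.DataFrame, pvals: np.ndarray | pd.Series,
                   alpha_gw: float = P_GENOME_WIDE,
                   ld_covariate: bool = True, label: str = ""
                   ) -> EnrichmentModel:
    """Maximum-likelihood fit of the enrichment logistic regression.

    ``matrix`` carries ``C`` (0/1 membership) and ``ell`` (LD score) per
    SNP; the outcome is the indicator 1{p_j < alpha_gw}.  A constant LD
    score (or ``ld_covariate=False``) drops the delta term, in which case
    the fitted beta equals the empirical log odds ratio of the 2x2
    significance-by-annotation table.  Complete separation triggers a
    Firth-penalized fallback, flagged in the result.
    """
    y = (np.asarray(pvals, dtype=float) < alpha_gw).astype(float)
    n_sig = int(y.sum())
    if n_sig == 0:
        raise EnrichmentError("outcome degenerate: no significant SNPs")
    if n_sig == len(y):
        raise EnrichmentError("outcome degenerate: all SNPs significant")
    c = matrix["C"].to_numpy(float)
    ell = matrix["ell"].to_numpy(float)
    use_ell = ld_covariate and np.ptp(ell) > 0
    cols = [np.ones_like(c)] + ([ell] if use_ell else []) + [c]
    x = np.column_stack(cols)
    firth = False
    try:
        with np.errstate(over="ignore"):
            fit = sm.GLM(y, x, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-8)
        params, bse = fit.params, fit.bse
        converged = bool(fit.converged)
        separated = (not np.all(np.isfinite(bse))) or np.abs(
            params).max() > 15
    except (PerfectSeparationError, np.linalg.LinAlgError):
        separated, converged = True, False
        params = bse = None
    if separated:
        params, bse = _firth_fit(x, y)
        converged, firth = True, True
    if use_ell:
        mu, delta, beta = params
        se_mu, se_delta, se_beta = bse
    else:
        (mu, beta), (se_mu, se_beta) = params, bse
        delta = se_delta = None
    z = float(beta / se_beta)
    return EnrichmentModel(
        mu=float(mu), delta=None if delta is None else float(delta),
        beta=float(beta), se_mu=float(se_mu),
        se_delta=None if se_delta is None else float(se_delta),
        se_beta=float(se_beta), z=z,
        pval=float(2 * stats.norm.sf(abs(z))), n_snps=len(y),
        n_significant=n_sig, converged=converged, firth=firth, label=label)


def enrichment_scan(table: pd.DataFrame, tracks: dict[str, pd.DataFrame],
                    scores: np.ndarray | pd.Series,
                    alpha_gw: float = P_GENOME_WIDE,
                    fdr: float = 0.05, mask_mhc: bool = False
                    ) -> pd.DataFrame:
    """Fit the enrichment model per annotation track with BH correction.

    ``tracks`` maps label -> BED frame.  Returns one row per track with
    the fitted coefficients, BH-adjusted q-value and status; tracks whose
    fit fails are reported with status ``error``.
    """
    rows = []
    for label, bed in tracks.items():
        try:
            mat = annotate_snps(table, bed, scores, mask_mhc=mask_mhc)
            model = fit_enrichment(mat, mat["pval"], alpha_gw=alpha_gw,
                                   label=label)
            rows.append(dict(model.to_dict(), status="ok"))
        except EnrichmentError as e:
            rows.append({"label": label, "status": f"error: {e}"})
    out = pd.DataFrame(rows)
    ok = out["status"] == "ok"
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "pval"],
                                         method="fdr_bh")[1]
    out["significant_fdr"] = out["q"] < fdr
    return out
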