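"""Vectorized single-SNP association scans.

Marginal one-SNP-at-a-time regressions across a genotype matrix: ordinary
least squares for quantitative phenotypes and Newton-iterated logistic
regression (intercept + dosage) for binary outcomes.  Both return effect,
standard error and a normal-approximation two-sided p-value per SNP, the
convention of GWAS software.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def _norm_p(z: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(z))


def ols_scan(g: np.ndarray, y: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP simple linear regression of ``y`` on each column of ``g``.

    Returns ``(beta, se, pval)`` arrays of length ``m``.  Monomorphic
    columns get ``beta = 0`` and ``se = inf``.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    n = g.shape[0]
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = yc @ gc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        rss = syy - beta * sxy
        sigma2 = np.maximum(rss, 0.0) / max(n - 2, 1)
        se = np.where(sxx > 0, np.sqrt(sigma2 / np.where(sxx > 0, sxx, 1.0)),
                      np.inf)
        z = np.where(np.isfinite(se) & (se > 0), beta / se, 0.0)
    return beta, se, _norm_p(z)


def logistic_scan(g: np.ndarray, y: np.ndarray, max_iter: int = 25,
                  tol: float = 1e-8, chunk: int = 256
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP logistic regression ``logit P(y=1) = a + b * g_j``.

    Newton-Raphson run simultaneously across SNPs (2x2 systems solved in
    closed form), chunked over columns to bound memory.  Returns
    ``(log_or, se, pval)``; non-converged or monomorphic columns get
    ``se = inf``.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    m = g.shape[1]
    beta = np.zeros(m)
    se = np.full(m, np.inf)
    base = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    a0 = np.log(base / (1 - base))
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        gc = g[:, lo:hi]
        a = np.full(hi - lo, a0)
        b = np.zeros(hi - lo)
        ok = gc.std(axis=0) > 0
        for _ in range(max_iter):
            eta = a + gc * b
            p = 1.0 / (1.0 + np.exp(-eta))
            w = p * (1.0 - p)
            r = y[:, None] - p
            s0 = w.sum(axis=0)
            s1 = np.einsum("ij,ij->j", w, gc)
            s2 = np.einsum("ij,ij,ij->j", w, gc, gc)
            u0 = r.sum(axis=0)
            u1 = np.einsum("ij,ij->j", r, gc)
            det = s0 * s2 - s1 * s1
            det = np.where(det > 1e-12, det, np.inf)
            da = (s2 * u0 - s1 * u1) / det
            db = (-s1 * u0 + s0 * u1) / det
            a += np.where(ok, da, 0.0)
            b += np.where(ok, db, 0.0)
            if max(np.abs(da).max(initial=0), np.abs(db).max(initial=0)) < tol:
                break
        det = s0 * s2 - s1 * s1
        good = ok & (det > 1e-12)
        beta[lo:hi] = np.where(good, b, 0.0)
        se[lo:hi] = np.where(good, np.sqrt(np.where(good, s0, 1.0)
                                           / np.where(good, det, 1.0)),
                             np.inf)
    with np.errstate(invalid="ignore"):
        z = np.where(np.isfinite(se), beta / se, 0.0)
    return beta, se, _norm_p(z)
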