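"""Approximate conditional and joint multi-SNP analysis from summary data.

Joint effects for a set S of SNPs are recovered from their marginal
summary statistics plus a reference LD correlation matrix R.  On the
standardized scale (unit-variance phenotype and genotypes) the marginal
effects b_m relate to the joint effects through b_J = R^{-1} b_m, with
Var(b_J) = sigma2_J diag(R^{-1}) / n and residual variance
sigma2_J = 1 - b_J' b_m.  Per-allele estimates are recovered by dividing
by sqrt(2 f (1 - f)).  Used for stepwise secondary-signal discovery
within a locus: a true signal hidden by negative LD with a stronger one
("masking") can reach significance only conditionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LDReference

#: ridge added to R's diagonal for numerical stability
RIDGE = 1e-6
#: floor on the joint residual variance
SIGMA2_FLOOR = 1e-6
#: collinearity guard: candidates with r2 above this against the selected
#: set are skipped
R2_COLLINEAR = 0.9
#: condition-number cap for the ridge-regularized R (1e5 ~ |r| 0.99998)
COND_CAP = 1e5


class ConditionalError(ValueError):
    pass


@dataclass
class JointModel:
    """Joint multi-SNP fit on a locus.

    ``beta_joint``/``se_joint`` are per-allele; ``beta_std``/``se_std``
    are on the standardized-genotype scale used internally.
    """

    variants: pd.DataFrame         # the marginal records of the set S
    beta_joint: np.ndarray
    se_joint: np.ndarray
    pval_joint: np.ndarray
    beta_std: np.ndarray
    se_std: np.ndarray
    sigma2: float
    n: float
    r_matrix: np.ndarray = field(repr=False, default=None)


def _std_scale(df: pd.DataFrame) -> np.ndarray:
    f = df["eaf"].to_numpy(float)
    return np.sqrt(2.0 * f * (1.0 - f))


def _correlation(ref: LDReference, df: pd.DataFrame) -> np.ndarray:
    cols = []
    for r in df.itertuples(index=False):
        j = ref.column(r.chrom, r.pos, r.effect_allele, r.other_allele)
        if j is None:
            raise ConditionalError(
                f"variant {r.chrom}:{r.pos} absent from LD panel")
        cols.append(j)
    g = ref.genotypes[:, cols].astype(float)
    sd = g.std(axis=0)
    if (sd == 0).any():
        raise ConditionalError("monomorphic variant in panel")
    gs = (g - g.mean(axis=0)) / sd
    r = (gs.T @ gs) / g.shape[0]
    # sign convention: panel dosages count each record's effect allele,
    # matching the orientation of the marginal betas
    ea_panel = [ref.keys.iloc[c]["effect_allele"] for c in cols]
    flip = np.array([1.0 if a == b else -1.0
                     for a, b in zip(ea_panel, df["effect_allele"])])
    return r * np.outer(flip, flip)


def joint_fit(marginals: pd.DataFrame, ref: LDReference, n: float
              ) -> JointModel:
    """Fit the joint model for the SNP set in ``marginals``.

    ``marginals`` needs columns chrom, pos, effect_allele, other_allele,
    eaf, beta, se (per-allele marginal estimates).  With a single SNP the
    joint fit equals the marginal record exactly.
    """
    df = marginals.reset_index(drop=True)
    scale = _std_scale(df)
    b_m = df["beta"].to_numpy(float) * scale
    if len(df) == 1:
        beta = df["beta"].to_numpy(float)
        se = df["se"].to_numpy(float)
        p = 2 * stats.norm.sf(np.abs(beta / se))
        return JointModel(df, beta, se, p, b_m, se * scale,
                          sigma2=float(max(1 - b_m @ b_m, SIGMA2_FLOOR)),
                          n=n, r_matrix=np.ones((1, 1)))
    r = _correlation(ref, df)
    r_reg = r + RIDGE * np.eye(len(df))
    if np.linalg.cond(r_reg) > COND_CAP:
        raise ConditionalError(
            "near-singular LD matrix; pre-prune the locus at r2 < "
            f"{R2_COLLINEAR}")
    rinv = np.linalg.inv(r_reg)
    b_j = rinv @ b_m
    sigma2 = float(max(1.0 - b_j @ b_m, SIGMA2_FLOOR))
    se_std = np.sqrt(sigma2 * np.diag(rinv) / n)
    beta_joint = b_j / scale
    se_joint = se_std / scale
    z = b_j / se_std
    pval = 2 * stats.norm.sf(np.abs(z))
    return JointModel(df, beta_joint, se_joint, pval, b_j, se_std,
                      sigma2, n, r)


@dataclass
class ConditionalScan:
    """Forward-selection result for one locus."""

    selected: pd.DataFrame     # marginal + conditional stats per signal
    model: JointModel | None
    trajectory: list[dict]     # per-step admission records
    skipped_collinear: int = 0


def conditional_scan(locus: pd.DataFrame, ref: LDReference, n: float,
                     p_enter: float = 5e-8, max_signals: int = 10
                     ) -> ConditionalScan:
    """Stepwise forward selection of independent signals within a locus.

    Starts from the smallest-p variant (the lead).  At each step every
    remaining variant is test-fitted jointly with the selected set; the
    candidate with the smallest conditional p is admitted while that p is
    below ``p_enter``.  Candidates with panel r2 > 0.9 against any
    selected variant are skipped.  Ties are broken deterministically by
    (p, position, alleles).
    """
    df = locus.sort_values(["pval", "pos", "effect_allele", "other_allele"],
                           kind="mergesort").reset_index(drop=True)
    if df.empty:
        raise ConditionalError("empty locus")
    selected = [0]
    trajectory = [{"step": 0, "pos": int(df.iloc[0]["pos"]),
                   "pval_marginal": float(df.iloc[0]["pval"]),
                   "pval_conditional": float(df.iloc[0]["pval"])}]
    skipped = 0
    remaining = list(range(1, len(df)))
    while remaining and len(selected) < max_signals:
        best = None
        for cand in remaining:
            sub = df.iloc[selected + [cand]]
            try:
                jm = joint_fit(sub, ref, n)
            except ConditionalError:
                continue
            if np.abs(jm.r_matrix[-1, :-1]).max() ** 2 > R2_COLLINEAR:
                skipped += 1
                continue
            p_cond = float(jm.pval_joint[-1])
            key = (p_cond, int(df.iloc[cand]["pos"]),
                   df.iloc[cand]["effect_allele"])
            if best is None or key < best[0]:
                best = (key, cand, jm)
        if best is None or best[0][0] >= p_enter:
            break
        _, cand, jm = best
        selected.append(cand)
        remaining.remove(cand)
        trajectory.append({"step": len(selected) - 1,
                           "pos": int(df.iloc[cand]["pos"]),
                           "pval_marginal": float(df.iloc[cand]["pval"]),
                           "pval_conditional": float(jm.pval_joint[-1])})
    model = joint_fit(df.iloc[selected], ref, n) if selected else None
    sel = df.iloc[selected].reset_index(drop=True).copy()
    if model is not None:
        sel["beta_joint"] = model.beta_joint
        sel["se_joint"] = model.se_joint
        sel["pval_joint"] = model.pval_joint
    sel["pval_conditional"] = [t["pval_conditional"] for t in trajectory]
    return ConditionalScan(sel, model, trajectory, skipped)
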