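"""End-to-end driver: meta-analysis through MR and enrichment.

Runs the full post-cohort pipeline on file inputs: per-cohort protein
GWAS tables, an LD reference VCF, a binary-outcome GWAS and annotation
BED tracks.  Stages: cross-cohort IVW meta-analysis (autosomes; X
per-sex then combined) -> genomic-control lambda QC -> genome-wide
clumping -> per-locus conditional scan -> pQTL variance-explained
partition -> cis and genome-wide MR (bidirectional) -> leave-one-
cohort-out subtraction check -> annotation enrichment scan.  Everything
is written to a machine-readable JSON report plus a Markdown summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conditional import ConditionalError, conditional_scan
from .enrichment import enrichment_scan, read_bed
from .ld import clump, ld_scores, read_panel_vcf
from .meta import (genomic_lambda, ivw_meta, meta_subtract,
                   variance_explained, x_chrom_meta)
from .mr import MRError, bidirectional_mr, ivw_mr, select_instruments
from .sumstats import SumStatsTable, read_sumstats

log = logging.getLogger("pqtlmeta")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    cohort_paths: tuple[str, ...]
    panel_path: str
    outcome_path: str
    annotation_paths: tuple[str, ...] = ()
    h2_input: float = 0.16
    p_gw: float = 5e-8
    maf_min: float = 0.01
    clump_r2_cis: float = 0.001
    clump_r2_genomewide: float = 0.05
    cis_window: tuple[str, int, int] | None = None
    conditional_window_kb: float = 500.0
    seed: int = 0
    outdir: str = "pipeline_out"

    def __post_init__(self):
        for thr in (self.p_gw, self.maf_min, self.clump_r2_cis,
                    self.clump_r2_genomewide):
            if not 0 < thr < 1:
                raise ConfigError("thresholds must lie in (0, 1)")
        if not self.cohort_paths:
            raise ConfigError("at least one cohort table required")

    def validate_paths(self):
        paths = [*self.cohort_paths, self.panel_path, self.outcome_path,
                 *self.annotation_paths]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise ConfigError(f"missing input files: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        d = yaml.safe_load(Path(path).read_text())
        for k in ("cohort_paths", "annotation_paths"):
            if k in d:
                d[k] = tuple(d[k])
        if d.get("cis_window"):
            d["cis_window"] = tuple(d["cis_window"])
        return cls(**d)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the report dict."""
    cfg.validate_paths()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    report: dict = {"stages": {}}

    # --- read cohorts -----------------------------------------------------
    cohorts, qc = [], {}
    for p in cfg.cohort_paths:
        t, q = read_sumstats(p)
        cohorts.append(t)
        qc[str(p)] = {"n_read": q.n_read, "n_kept": q.n_kept,
                      "rejects": q.rejects}
        log.info("read %s: %d/%d rows kept", p, q.n_kept, q.n_read)
    report["stages"]["read"] = qc

    # --- meta-analysis ----------------------------------------------------
    auto_tabs = [SumStatsTable(t.df[t.df["stratum"] == "all"]) for t in
                 cohorts]
    meta_auto = ivw_meta(auto_tabs, maf_min=cfg.maf_min)
    x_meta_by_sex = {}
    for s in ("male", "female"):
        tabs = [SumStatsTable(t.df[t.df["stratum"] == s])
                for t in cohorts if (t.df["stratum"] == s).any()]
        if tabs:
            x_meta_by_sex[s] = ivw_meta(tabs, maf_min=cfg.maf_min)
    if set(x_meta_by_sex) == {"male", "female"}:
        meta_x = x_chrom_meta(x_meta_by_sex["male"], x_meta_by_sex["female"],
                              maf_min=cfg.maf_min)
        meta_all = pd.concat([meta_auto, meta_x], ignore_index=True)
    else:
        meta_all = meta_auto
    meta_all = meta_all.sort_values(["chrom", "pos"],
                                    kind="mergesort").reset_index(drop=True)
    meta_path = outdir / "meta.tsv"
    meta_all.to_csv(meta_path, sep="\t", index=False)
    report["stages"]["meta"] = {
        "n_variants": int(len(meta_all)),
        "n_autosomal": int(len(meta_auto)),
        "n_x": int(len(meta_all)) - int(len(meta_auto)),
        "lambda_gc": genomic_lambda(meta_auto),
    }
    log.info("meta-analysis: %d variants, lambda=%.3f", len(meta_all),
             report["stages"]["meta"]["lambda_gc"])

    # --- LD panel ---------------------------------------------------------
    panel = read_panel_vcf(cfg.panel_path)
    scores = ld_scores(panel)

    # --- clumping ---------------------------------------------------------
    clumped = clump(meta_all, panel, p_threshold=cfg.p_gw,
                    r2_threshold=cfg.clump_r2_genomewide, window_kb=1000)
    leads = clumped.index
    report["stages"]["clump"] = {
        "n_significant": int((meta_all["pval"] < cfg.p_gw).sum()),
        "n_loci": clumped.n_index,
        "leads": leads[["chrom", "pos", "rsid", "beta", "se",
                        "pval", "eaf"]].to_dict(orient="records"),
    }
    log.info("clumping: %d loci", clumped.n_index)

    # --- conditional scan per locus ---------------------------------------
    cond_rows = []
    win = cfg.conditional_window_kb * 1000
    n_eff = float(meta_all["n"].max())
    lead_keys = {(r.chrom, int(r.pos)) for r in leads.itertuples()}
    for lead in leads.itertuples(index=False):
        locus = meta_all[(meta_all["chrom"] == lead.chrom)
                         & (meta_all["pos"].between(lead.pos - win,
                                                    lead.pos + win))]
        try:
            scan = conditional_scan(locus, panel, n=n_eff,
                                    p_enter=cfg.p_gw)
        except ConditionalError as e:
            log.warning("conditional scan failed at %s:%d: %s",
                        lead.chrom, lead.pos, e)
            continue
        for t in scan.trajectory:
            # neighbouring clump indices inside the window re-enter the
            # model; only signals that are not already a locus lead count
            # as newly discovered secondaries
            novel = (lead.chrom, t["pos"]) not in lead_keys
            cond_rows.append({"locus": f"{lead.chrom}:{lead.pos}",
                              "novel": bool(novel), **t})
    report["stages"]["conditional"] = {
        "n_signals": len(cond_rows),
        "signals": cond_rows,
        "n_secondary": sum(1 for r in cond_rows
                           if r["step"] > 0 and r["novel"]),
    }

    # --- variance explained -----------------------------------------------
    ve = variance_explained(leads, h2_input=cfg.h2_input)
    report["stages"]["variance_explained"] = {
        "total": ve.total, "h2_input": ve.h2_input,
        "fraction": ve.fraction, "n_leads": len(ve.per_variant)}

    # --- MR ----------------------------------------------------------------
    outcome, out_qc = read_sumstats(cfg.outcome_path,
                                    require_x_stratified=False)
    mr_report = {}
    if cfg.cis_window is not None:
        try:
            inst = select_instruments(meta_all, outcome, panel, mode="cis",
                                      gene_window=cfg.cis_window,
                                      p_threshold=cfg.p_gw,
                                      r2_threshold=cfg.clump_r2_cis)
            res = ivw_mr(inst)
            mr_report["cis"] = dict(res.to_dict(),
                                    diagnostics=inst.diagnostics)
            log.info("cis MR: OR=%.3f (%.3f-%.3f), p=%.3g, k=%d",
                     res.odds_ratio, *res.ci95, res.pval, res.n_instruments)
        except MRError as e:
            mr_report["cis"] = {"error": str(e)}
    bidir = bidirectional_mr(meta_all, outcome, panel, mode="genomewide",
                             p_threshold=cfg.p_gw)
    mr_report["genomewide_forward"] = (
        bidir.forward.to_dict() if bidir.forward
        else {"error": bidir.forward_error})
    mr_report["reverse"] = (
        bidir.reverse.to_dict() if bidir.reverse
        else {"error": bidir.reverse_error})
    report["stages"]["mr"] = mr_report

    # --- leave-one-cohort-out subtraction check ---------------------------
    if len(cohorts) > 1:
        sub = meta_subtract(meta_auto, auto_tabs[0])
        direct = ivw_meta(auto_tabs[1:], maf_min=0.0)
        j = sub.merge(direct, on=["chrom", "pos"], suffixes=("_sub", "_dir"))
        max_diff = float(np.max(np.abs(j["beta_sub"] - j["beta_dir"]))) \
            if len(j) else float("nan")
        report["stages"]["loco_subtract"] = {
            "cohort_removed": str(cfg.cohort_paths[0]),
            "max_abs_beta_diff_vs_direct": max_diff}

    # --- enrichment --------------------------------------------------------
    if cfg.annotation_paths:
        # align LD scores to meta variants via the panel key order
        key = ["chrom", "pos", "effect_allele", "other_allele"]
        panel_scores = panel.keys.assign(ell=scores)
        snp_tab = meta_all.merge(
            panel_scores[key + ["ell"]], on=key, how="left")
        tracks = {Path(p).stem: read_bed(p) for p in cfg.annotation_paths}
        scan = enrichment_scan(snp_tab, tracks, snp_tab["ell"],
                               alpha_gw=cfg.p_gw)
        scan_path = outdir / "enrichment.tsv"
        scan.to_csv(scan_path, sep="\t", index=False)
        report["stages"]["enrichment"] = scan.to_dict(orient="records")

    # --- manifest & outputs -------------------------------------------------
    report["manifest"] = {
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "input_hashes": {str(p): _sha256(p) for p in
                         [*cfg.cohort_paths, cfg.panel_path,
                          cfg.outcome_path, *cfg.annotation_paths]},
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   default=float))
    (outdir / "summary.md").write_text(_summary_md(report))
    return report


def _summary_md(report: dict) -> str:
    s = report["stages"]
    lines = ["# Pipeline summary", ""]
    m = s.get("meta", {})
    lines += [f"- Meta-analysis: {m.get('n_variants')} variants "
              f"({m.get('n_x')} on X), lambda_GC = "
              f"{m.get('lambda_gc', float('nan')):.3f}"]
    c = s.get("clump", {})
    lines += [f"- Genome-wide significant loci after clumping: "
              f"{c.get('n_loci')}"]
    cond = s.get("conditional", {})
    lines += [f"- Conditional analysis signals: {cond.get('n_signals')} "
              f"({cond.get('n_secondary')} secondary)"]
    ve = s.get("variance_explained", {})
    if ve:
        lines += [f"- Lead pQTL capture V = {ve['total']:.4f} of phenotypic "
                  f"variance (h2 input {ve['h2_input']}; ratio "
                  f"{ve['fraction']:.3f})"]
    mr = s.get("mr", {})
    for k, v in mr.items():
        if "error" in v:
            lines += [f"- MR [{k}]: not estimable ({v['error']})"]
        else:
            lo, hi = v["ci95"]
            lines += [f"- MR [{k}]: OR {v['odds_ratio']:.2f} "
                      f"(95% CI {lo:.2f}-{hi:.2f}; P={v['pval']:.3g}; "
                      f"{v['n_instruments']} instruments)"]
    enr = s.get("enrichment")
    if enr:
        n_hit = sum(1 for r in enr if r.get("significant_fdr"))
        lines += [f"- Enrichment: {n_hit}/{len(enr)} tracks significant "
                  "at FDR 5%"]
    return "\n".join(lines) + "\n"
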