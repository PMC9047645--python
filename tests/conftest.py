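"""Shared fixtures: one small synthetic study reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from pqtlmeta import meta as M
from pqtlmeta import simulate as sim
from pqtlmeta.sumstats import SumStatsTable


@pytest.fixture(scope="session")
def small_cfg() -> sim.SimConfig:
    """Compact study: 3 cohorts x 1500, 360 SNPs, all loci discoverable."""
    return sim.SimConfig(
        seed=7,
        n_per_cohort=(1500, 1500, 1500),
        m_autosomal=300, m_x=60,
        trans_effects=((2, 0.30, 0.25), (8, 0.20, 0.22)),
        cis_x_effects=((0, 0.30, 0.25), (1, 0.10, 0.28), (2, 0.20, 0.20)),
        outcome_direct_effects=((5, 0.40, 0.50),),
        h2_target=0.16, n_background=50,
        n_outcome=8000, n_ref=8000,
    )


@pytest.fixture(scope="session")
def small_variants(small_cfg):
    return sim.variant_table(small_cfg)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return sim.simulate_ld_panel(small_cfg)


@pytest.fixture(scope="session")
def small_cohorts(small_cfg, small_variants):
    return [sim.simulate_cohort_gwas(small_cfg, i, small_variants)
            for i in range(small_cfg.n_cohorts)]


@pytest.fixture(scope="session")
def small_meta(small_cohorts):
    """Combined meta-analysis frame (autosomes + X combined across sexes)."""
    auto = [SumStatsTable(t.df[t.df["stratum"] == "all"])
            for t in small_cohorts]
    male = [SumStatsTable(t.df[t.df["stratum"] == "male"])
            for t in small_cohorts]
    female = [SumStatsTable(t.df[t.df["stratum"] == "female"])
              for t in small_cohorts]
    meta_auto = M.ivw_meta(auto)
    meta_x = M.x_chrom_meta(M.ivw_meta(male), M.ivw_meta(female))
    return pd.concat([meta_auto, meta_x], ignore_index=True)


def make_assoc_frame(rows) -> pd.DataFrame:
    """Helper: build a sumstats frame from (chrom,pos,ea,oa,eaf,beta,se,
    pval,n,stratum) tuples."""
    df = pd.DataFrame(rows, columns=[
        "chrom", "pos", "effect_allele", "other_allele", "eaf", "beta",
        "se", "pval", "n", "stratum"])
    df["rsid"] = [f"v{i}" for i in range(len(df))]
    return df
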