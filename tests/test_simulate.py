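"""The synthetic-study generator: LD structure, phenotype model,
outcome model, annotations, determinism."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from pqtlmeta import assoc, simulate as sim
from pqtlmeta.meta import genomic_lambda, ivw_meta
from pqtlmeta.sumstats import SumStatsTable


def null_cfg(seed, m_autosomal=200, m_x=20, **kw):
    kw.setdefault("trans_effects", ())
    kw.setdefault("cis_x_effects", ((0, 0.3, 0.0),))
    kw.setdefault("outcome_direct_effects", ())
    kw.setdefault("h2_target", 0.0)
    kw.setdefault("n_background", 0)
    return sim.SimConfig(seed=seed, m_autosomal=m_autosomal, m_x=m_x, **kw)


class TestConfig:
    def test_declared_variance_cannot_exceed_h2(self):
        with pytest.raises(ValueError, match="exceeds h2_target"):
            sim.SimConfig(h2_target=0.01)

    def test_yaml_round_trip(self, tmp_path, small_cfg):
        p = tmp_path / "cfg.yaml"
        small_cfg.to_yaml(p)
        back = sim.SimConfig.from_yaml(p)
        assert back == small_cfg


class TestPanel:
    def test_deterministic_given_seed(self, small_cfg):
        a = sim.simulate_ld_panel(small_cfg)
        b = sim.simulate_ld_panel(small_cfg)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_zero_rho_gives_independent_snps(self):
        cfg = null_cfg(0, ld_rho=0.0, n_ref=600)
        panel = sim.simulate_ld_panel(cfg)
        g = panel.genotypes.astype(float)
        r = np.corrcoef(g.T)
        off = np.abs(r[np.triu_indices_from(r, k=1)])
        assert np.nanmean(off) < 0.06

    def test_adjacent_r2_matches_orthant_probability_oracle(self):
        """Empirical adjacent-SNP r2 agrees with the Gaussian-copula
        value computed by numerical integration of the bivariate-normal
        orthant probability."""
        rho, f = 0.9, 0.5
        cfg = null_cfg(1, ld_rho=rho, maf_range=(0.499999, 0.5),
                       n_ref=2000, m_autosomal=40, m_x=20)
        panel = sim.simulate_ld_panel(cfg)
        thr = stats.norm.ppf(1 - f)
        # P(Z1 > thr, Z2 > thr) under correlation rho (orthant probability)
        p11 = stats.multivariate_normal.cdf([-thr, -thr], mean=[0, 0],
                                            cov=[[1, rho], [rho, 1]])
        r_hap = (p11 - f * f) / (f * (1 - f))
        h = panel.haplotypes.astype(float)
        # pool adjacent within-block pairs for precision
        rs, block = [], sim.variant_table(cfg)["block"].to_numpy()
        for j in range(panel.m - 1):
            if block[j] == block[j + 1]:
                rs.append(np.corrcoef(h[:, j], h[:, j + 1])[0, 1])
        mc_se = np.std(rs) / np.sqrt(len(rs))
        assert np.mean(rs) == pytest.approx(r_hap, abs=3 * max(mc_se, 1e-3))

    def test_maf_within_range(self, small_cfg, small_panel):
        freq = small_panel.haplotypes.mean(axis=0)
        declared = sim.variant_table(small_cfg)["maf"].to_numpy()
        # sampling error around the declared frequency
        se = np.sqrt(declared * (1 - declared)
                     / small_panel.haplotypes.shape[0])
        assert np.all(np.abs(freq - declared) < 5 * se + 0.01)


class TestCohortGwas:
    def test_deterministic(self, small_cfg, small_variants):
        a = sim.simulate_cohort_gwas(small_cfg, 0, small_variants)
        b = sim.simulate_cohort_gwas(small_cfg, 0, small_variants)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_cohorts_are_independent(self, small_cfg, small_variants):
        a = sim.simulate_cohort_gwas(small_cfg, 0, small_variants)
        b = sim.simulate_cohort_gwas(small_cfg, 1, small_variants)
        assert not np.allclose(a.df["beta"], b.df["beta"])

    def test_null_gwas_is_calibrated(self):
        """All betas zero and no heritability: lambda_GC near 1 and
        genome-wide significants at the nominal rate."""
        cfg = null_cfg(5, m_autosomal=1000, m_x=0,
                       cis_x_effects=(), n_per_cohort=(2000,) * 3,
                       n_cohorts=3)
        mv = sim.variant_table(cfg)
        tab = sim.simulate_cohort_gwas(cfg, 0, mv)
        lam = genomic_lambda(tab)
        assert 0.93 < lam < 1.07
        assert (tab.df["pval"] < 5e-8).sum() == 0

    def test_ols_recovers_single_causal_effect(self):
        cfg = sim.SimConfig(seed=3, n_cohorts=1, n_per_cohort=(10_000,),
                            m_autosomal=60, m_x=20,
                            trans_effects=((1, 0.3, 0.3),),
                            cis_x_effects=(), outcome_direct_effects=(),
                            h2_target=0.1, n_background=10)
        mv = sim.variant_table(cfg)
        tab = sim.simulate_cohort_gwas(cfg, 0, mv)
        causal = mv[mv["kind"] == "trans"].iloc[0]
        row = tab.df[(tab.df["chrom"] == causal["chrom"])
                     & (tab.df["pos"] == causal["pos"])].iloc[0]
        assert abs(row["beta"] - 0.3) < 3 * row["se"]

    def test_x_strata_sample_sizes_partition_cohort(self, small_cfg,
                                                    small_cohorts):
        df = small_cohorts[0].df
        x = df[df["chrom"] == "X"]
        n_m = x[x["stratum"] == "male"]["n"].iloc[0]
        n_f = x[x["stratum"] == "female"]["n"].iloc[0]
        assert n_m + n_f == small_cfg.n_per_cohort[0]
        assert not (x["stratum"] == "all").any()


class TestOutcomeGwas:
    def test_prevalence_targeted(self, small_cfg, small_variants):
        out = sim.simulate_outcome_gwas(small_cfg, small_variants)
        assert out.meta["prevalence"] == pytest.approx(
            small_cfg.outcome_prevalence, abs=0.01)

    def test_null_theta_centers_outcome_betas_at_zero(self):
        cfg = null_cfg(9, theta_causal=0.0, n_outcome=4000,
                       m_autosomal=300, m_x=0, cis_x_effects=())
        out = sim.simulate_outcome_gwas(cfg)
        z = out.df["beta"] / out.df["se"]
        assert abs(z.mean()) < 3 / np.sqrt(len(z))
        assert np.var(z) == pytest.approx(1.0, abs=0.15)

    def test_logistic_scan_matches_statsmodels(self):
        rng = np.random.default_rng(0)
        n = 800
        g = rng.binomial(2, 0.3, size=(n, 4)).astype(float)
        eta = -1.5 + 0.4 * g[:, 0] - 0.3 * g[:, 2]
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
        beta, se, pval = assoc.logistic_scan(g, y)
        for j in range(4):
            X = sm.add_constant(g[:, j])
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            assert beta[j] == pytest.approx(fit.params[1], abs=1e-6)
            assert se[j] == pytest.approx(fit.bse[1], rel=1e-4)

    def test_direct_outcome_loci_reach_significance(self, small_cfg,
                                                    small_variants):
        out = sim.simulate_outcome_gwas(small_cfg, small_variants)
        direct = small_variants[small_variants["outcome_log_or"] != 0]
        hit = out.df.merge(direct[["chrom", "pos"]], on=["chrom", "pos"])
        assert (hit["pval"] < 5e-8).all()


class TestAnnotations:
    def test_membership_realizes_enrichment_odds(self):
        cfg = sim.SimConfig(seed=13, m_autosomal=4000, m_x=100,
                            ld_block_size=20,
                            trans_effects=tuple((2 * i, 0.3, 0.02)
                                                for i in range(60)),
                            cis_x_effects=((0, 0.3, 0.02),),
                            outcome_direct_effects=(),
                            h2_target=0.12, n_background=0,
                            annotation_enrichment_or=5.0)
        mv = sim.variant_table(cfg)
        causal = mv["kind"].isin(["trans", "cis"]).to_numpy()
        member = mv["annotated"].to_numpy()
        p1 = member[causal].mean()
        p0 = member[~causal].mean()
        odds_ratio = (p1 / (1 - p1)) / (p0 / (1 - p0))
        assert odds_ratio == pytest.approx(5.0, rel=0.5)
        assert p0 == pytest.approx(cfg.annotation_base_rate, abs=0.02)

    def test_bed_intervals_cover_annotated_snps_only(self, small_cfg,
                                                     small_variants):
        bed, member = sim.simulate_annotations(small_cfg, small_variants)
        assert len(bed) == member.sum()
        assert (bed["start"] >= 0).all()
        covered = set(zip(bed["chrom"], bed["name"]))
        expect = set(zip(small_variants.loc[member, "chrom"],
                         small_variants.loc[member, "rsid"]))
        assert covered == expect

    def test_empty_track_when_no_membership(self):
        cfg = null_cfg(2, annotation_base_rate=1e-9,
                       annotation_enrichment_or=1.0)
        bed, member = sim.simulate_annotations(cfg)
        assert len(bed) == 0 and member.sum() == 0


class TestStudyBundle:
    def test_files_written_and_deterministic(self, tmp_path, small_cfg):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = sim.simulate_study(small_cfg, d1)
        p2 = sim.simulate_study(small_cfg, d2)
        for k in p1:
            assert p1[k].read_bytes() == p2[k].read_bytes(), k

    def test_meta_recovers_declared_effects(self, small_cfg,
                                            small_variants, small_cohorts):
        """Parameter recovery: IVW meta beta at each declared autosomal
        locus within 3 pooled SE of the planted per-allele effect."""
        auto = [SumStatsTable(t.df[t.df["stratum"] == "all"])
                for t in small_cohorts]
        res = ivw_meta(auto)
        for _, v in small_variants[small_variants["kind"] == "trans"]\
                .iterrows():
            row = res[(res["chrom"] == v["chrom"])
                      & (res["pos"] == v["pos"])].iloc[0]
            assert abs(row["beta"] - v["beta"]) < 3 * row["se"]
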