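"""LD statistics, LD scores and greedy clumping against oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pqtlmeta import simulate as sim
from pqtlmeta.ld import (LDReference, clump, ld_pair, ld_scores,
                         read_panel_vcf, write_panel_vcf)

from conftest import make_assoc_frame


def panel_from_haplotypes(hap: np.ndarray, chrom="1",
                          spacing=1000) -> LDReference:
    """Build a diploid panel by pairing consecutive haplotypes."""
    geno = (hap[0::2] + hap[1::2]).astype(np.int8)
    m = hap.shape[1]
    keys = pd.DataFrame({
        "chrom": chrom, "pos": np.arange(1, m + 1) * spacing,
        "effect_allele": "A", "other_allele": "G",
        "rsid": [f"s{i}" for i in range(m)]})
    return LDReference(keys, geno, hap.astype(np.int8))


@pytest.fixture(scope="module")
def classic_two_locus():
    """Haplotype table AB=40, Ab=10, aB=10, ab=40 (D=0.15, D'=0.6,
    r2=0.36), paired into individuals without double heterozygotes."""
    blocks = ([(1, 1)] * 40 + [(1, 0)] * 10 + [(0, 1)] * 10 + [(0, 0)] * 40)
    hap = np.array(blocks, dtype=np.int8)
    return panel_from_haplotypes(hap)


class TestLDPair:
    def test_self_ld_is_one(self, classic_two_locus):
        res = ld_pair(classic_two_locus, 0, 0)
        assert res.r2 == pytest.approx(1.0)
        assert res.dprime == pytest.approx(1.0)

    def test_hand_computed_haplotype_example(self, classic_two_locus):
        res = ld_pair(classic_two_locus, 0, 1)
        assert res.r2 == pytest.approx(0.36, abs=1e-12)
        assert res.dprime == pytest.approx(0.6, abs=1e-12)

    def test_em_matches_phased_counting(self, classic_two_locus):
        """EM on the unphased genotypes (paired without double
        heterozygotes) recovers the phased haplotype answer."""
        unphased = LDReference(classic_two_locus.keys.copy(),
                               classic_two_locus.genotypes.copy())
        res = ld_pair(unphased, 0, 1)
        phased = ld_pair(classic_two_locus, 0, 1)
        assert res.dprime == pytest.approx(phased.dprime, abs=1e-6)
        assert res.r2 == pytest.approx(0.36, abs=0.06)  # dosage-based r2

    def test_em_with_double_heterozygotes(self):
        """EM resolves phase ambiguity: strong-LD haplotypes paired
        randomly still give D' close to the phased value."""
        rng = np.random.default_rng(3)
        hap = np.array([(1, 1)] * 45 + [(1, 0)] * 5 + [(0, 1)] * 5
                       + [(0, 0)] * 145, dtype=np.int8)
        rng.shuffle(hap)
        ref = panel_from_haplotypes(hap)
        phased = ld_pair(ref, 0, 1)
        unphased = LDReference(ref.keys.copy(), ref.genotypes.copy())
        res = ld_pair(unphased, 0, 1)
        assert res.dprime == pytest.approx(phased.dprime, abs=0.05)

    def test_symmetry(self, classic_two_locus):
        a = ld_pair(classic_two_locus, 0, 1)
        b = ld_pair(classic_two_locus, 1, 0)
        assert a.r2 == pytest.approx(b.r2)
        assert a.dprime == pytest.approx(b.dprime)

    def test_r2_never_exceeds_dprime(self):
        rng = np.random.default_rng(5)
        for seed in range(20):
            f1, f2 = rng.uniform(0.1, 0.9, 2)
            p11 = rng.uniform(max(0, f1 + f2 - 1), min(f1, f2))
            probs = [p11, f1 - p11, f2 - p11, 1 - f1 - f2 + p11]
            hap = rng.choice(4, size=400, p=np.asarray(probs) / sum(probs))
            hm = np.column_stack([(hap <= 1).astype(np.int8),
                                  ((hap == 0) | (hap == 2)).astype(np.int8)])
            ref = panel_from_haplotypes(hm)
            res = ld_pair(ref, 0, 1)
            if res.ok:
                assert res.r2 <= res.dprime + 1e-9

    def test_monomorphic_returns_error_value(self):
        hap = np.zeros((100, 2), dtype=np.int8)
        hap[:, 1] = np.arange(100) % 2
        ref = panel_from_haplotypes(hap)
        res = ld_pair(ref, 0, 1)
        assert not res.ok and res.reason == "monomorphic"


class TestLDScores:
    def test_independent_snps_score_one(self):
        rng = np.random.default_rng(0)
        hap = (rng.uniform(size=(4000, 10)) < 0.4).astype(np.int8)
        ref = panel_from_haplotypes(hap)
        ell = ld_scores(ref)
        assert np.allclose(ell, 1.0, atol=0.05)

    def test_three_snp_toy_sum(self):
        """With pairwise r2 (0.5, 0.2) to SNP 1 and no small-sample
        correction, ell_1 = 1 + 0.5 + 0.2 = 1.7."""
        rng = np.random.default_rng(1)
        n = 4000
        z = rng.standard_normal((n, 3))
        g1 = z[:, 0]
        g2 = np.sqrt(0.5) * g1 + np.sqrt(0.5) * z[:, 1]
        g3 = np.sqrt(0.2) * g1 + np.sqrt(0.8) * z[:, 2]
        geno = np.column_stack([g1, g2, g3])
        keys = pd.DataFrame({"chrom": "1", "pos": [1000, 2000, 3000],
                             "effect_allele": "A", "other_allele": "G",
                             "rsid": ["a", "b", "c"]})
        ref = LDReference(keys, geno)
        ell = ld_scores(ref)
        # r2(2,3) ~ 0.1 adds to the sum; subtract the empirical cross term
        r23 = np.corrcoef(g2, g3)[0, 1] ** 2
        assert ell[0] == pytest.approx(1.7, abs=0.06)
        assert ell[1] == pytest.approx(1.5 + r23, abs=0.06)

    def test_monotone_in_copula_correlation(self):
        cfgs = [sim.SimConfig(seed=2, m_autosomal=200, m_x=20, n_ref=400,
                              ld_rho=r, trans_effects=(),
                              cis_x_effects=((0, 0.3, 0.1),),
                              outcome_direct_effects=(), n_background=10)
                for r in (0.0, 0.5, 0.9)]
        means = [ld_scores(sim.simulate_ld_panel(c)).mean() for c in cfgs]
        assert means[0] < means[1] < means[2]

    def test_window_restricts_sum(self):
        rng = np.random.default_rng(4)
        hap = (rng.uniform(size=(2000, 5)) < 0.3).astype(np.int8)
        ref = panel_from_haplotypes(hap, spacing=600_000)
        ell_wide = ld_scores(ref, window_kb=10_000)
        ell_narrow = ld_scores(ref, window_kb=100)
        assert np.all(ell_narrow == 1.0)
        # independent SNPs in-window contribute only bias-adjusted noise
        assert np.allclose(ell_wide, 1.0, atol=0.05)


def brute_force_clump(df, r2mat, p_threshold, r2_threshold, window):
    """Independent O(m^2) greedy oracle over explicit r2 matrix."""
    q = df[df["pval"] < p_threshold].copy()
    q = q.sort_values(["pval", "chrom", "pos", "effect_allele",
                       "other_allele"], kind="mergesort")
    taken, removed = [], set()
    for i in q.index:
        if i in removed:
            continue
        taken.append(i)
        for k in q.index:
            if k == i or k in removed or k in taken:
                continue
            same = df.loc[i, "chrom"] == df.loc[k, "chrom"]
            near = abs(df.loc[i, "pos"] - df.loc[k, "pos"]) <= window
            if same and near and r2mat[df.loc[i, "_col"],
                                       df.loc[k, "_col"]] > r2_threshold:
                removed.add(k)
    return sorted(taken)


@pytest.fixture(scope="module")
def clump_panel():
    cfg = sim.SimConfig(seed=11, m_autosomal=180, m_x=20, n_ref=300,
                        trans_effects=(), cis_x_effects=((0, .3, .1),),
                        outcome_direct_effects=(), n_background=10)
    return sim.simulate_ld_panel(cfg)


class TestClump:
    def make_table(self, panel, rng):
        df = panel.keys.copy()
        df["pval"] = 10 ** (-rng.uniform(0, 12, size=len(df)))
        df["beta"] = 0.1
        df["se"] = 0.05
        df["eaf"] = 0.3
        df["n"] = 1000
        df["_col"] = np.arange(len(df))
        return df

    def test_matches_brute_force_oracle(self, clump_panel):
        g = clump_panel.genotypes.astype(float)
        r2mat = np.corrcoef(g.T) ** 2
        for seed in range(50):
            rng = np.random.default_rng(seed)
            df = self.make_table(clump_panel, rng)
            res = clump(df, clump_panel, p_threshold=1e-3,
                        r2_threshold=0.2, window_kb=100)
            expected = brute_force_clump(df, r2mat, 1e-3, 0.2, 100_000)
            got = sorted(
                df.reset_index().merge(
                    res.index[["chrom", "pos"]], on=["chrom", "pos"])
                ["index"].tolist())
            assert got == expected

    def test_independent_variants_all_retained(self):
        rng = np.random.default_rng(0)
        hap = (rng.uniform(size=(2000, 20)) < 0.4).astype(np.int8)
        ref = panel_from_haplotypes(hap)
        df = ref.keys.copy()
        df["pval"] = 1e-9
        res = clump(df, ref, p_threshold=5e-8, r2_threshold=0.05,
                    window_kb=1000)
        assert res.n_index == 20

    def test_greedy_trace_three_snp(self):
        """s1 absorbs s2 (r2=0.5); s3 survives (r2 to s1 ~ 0)."""
        rng = np.random.default_rng(8)
        n = 20000
        z = rng.standard_normal((n, 3))
        h1 = (z[:, 0] > 0).astype(np.int8)
        lat2 = np.sqrt(0.72) * z[:, 0] + np.sqrt(0.28) * z[:, 1]
        h2 = (lat2 > 0).astype(np.int8)
        h3 = (z[:, 2] > 0).astype(np.int8)
        hap = np.column_stack([h1, h2, h3])
        ref = panel_from_haplotypes(hap)
        df = ref.keys.copy()
        df["pval"] = [1e-10, 1e-9, 1e-8]
        res = clump(df, ref, p_threshold=5e-8, r2_threshold=0.05,
                    window_kb=1000)
        assert res.index["rsid"].tolist() == ["s0", "s2"]
        assert res.absorbed.iloc[0]["index_pos"] == 1000

    def test_idempotent(self, clump_panel):
        rng = np.random.default_rng(99)
        df = self.make_table(clump_panel, rng)
        res = clump(df, clump_panel, 1e-3, 0.2, 100)
        again = clump(res.index.drop(columns=["_col"], errors="ignore"),
                      clump_panel, 1e-3, 0.2, 100)
        assert again.n_index == res.n_index
        assert again.absorbed.empty

    def test_row_order_invariance(self, clump_panel):
        rng = np.random.default_rng(5)
        df = self.make_table(clump_panel, rng)
        res1 = clump(df, clump_panel, 1e-3, 0.2, 100)
        shuffled = df.sample(frac=1, random_state=1)
        res2 = clump(shuffled, clump_panel, 1e-3, 0.2, 100)
        pd.testing.assert_frame_equal(
            res1.index.reset_index(drop=True).sort_values("pos")
            .reset_index(drop=True),
            res2.index.reset_index(drop=True).sort_values("pos")
            .reset_index(drop=True))

    def test_variant_missing_from_panel_unlinked(self, clump_panel):
        rng = np.random.default_rng(3)
        df = self.make_table(clump_panel, rng)
        alien = df.iloc[[0]].assign(pos=999_999_999, pval=1e-15)
        df2 = pd.concat([df, alien], ignore_index=True)
        with pytest.warns(UserWarning, match="absent from LD panel"):
            res = clump(df2, clump_panel, 1e-3, 0.2, 100)
        assert (res.index["pos"] == 999_999_999).any()


class TestVcfRoundTrip:
    def test_write_read_preserves_panel(self, tmp_path, small_panel):
        p = tmp_path / "panel.vcf"
        write_panel_vcf(small_panel, p)
        back = read_panel_vcf(p)
        assert np.array_equal(back.genotypes, small_panel.genotypes)
        assert back.haplotypes is not None
        assert np.array_equal(back.haplotypes, small_panel.haplotypes)
        pd.testing.assert_frame_equal(back.keys, small_panel.keys)
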