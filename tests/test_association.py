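"""Tests for SNP filtering, kinship, PCs, the dual-model scans, inflation
diagnostics, peak calling and gene annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seedlong import (
    SimulationConfig,
    annotate_peaks,
    call_peaks,
    compute_kinship,
    compute_pcs,
    filter_snps,
    genomic_inflation,
    glm_scan,
    mlm_scan,
    simulate_genotypes,
)
from seedlong.association import Peak


class TestFilter:
    def test_maf_boundary(self, make_gm):
        # 50 accessions = 100 alleles: 4 alt alleles -> MAF 0.04, 5 -> 0.05
        n = 50
        d = np.zeros((n, 3))
        d[:2, 0] = 2.0                  # MAF 0.04 -> removed
        d[:2, 1] = 2.0
        d[2, 1] = 1.0                   # MAF exactly 0.05 -> retained
        d[:25, 2] = 2.0                 # MAF 0.5 -> retained
        gm = make_gm(d)
        kept = filter_snps(gm, min_maf=0.05)
        assert list(kept.snp_ids) == ["s1", "s2"]

    def test_missingness_boundary(self, make_gm):
        n = 100
        d = np.tile([0.0, 2.0], n // 2)[:, None] * np.ones((1, 3))
        d[:21, 0] = np.nan   # 21 % missing -> removed
        d[:20, 1] = np.nan   # exactly 20 % -> retained
        kept = filter_snps(make_gm(d), max_missing=0.20, min_maf=0.05)
        assert "s0" not in list(kept.snp_ids)
        assert "s1" in list(kept.snp_ids)

    def test_matches_brute_force_recount(self):
        cfg = SimulationConfig(n_accessions=200, n_snps=1000, missing_rate=0.1,
                               maf_range=(0.01, 0.5), rng_seed=20)
        gm = simulate_genotypes(cfg)
        kept = filter_snps(gm, 0.20, 0.05)
        expected = []
        for j in range(gm.n_snps):
            col = gm.dosage[:, j]
            obs = col[~np.isnan(col)]
            miss = 1 - len(obs) / len(col)
            f = obs.sum() / (2 * len(obs))
            maf = min(f, 1 - f)
            if miss <= 0.20 and maf >= 0.05:
                expected.append(gm.snp_ids[j])
        assert list(kept.snp_ids) == expected

    def test_idempotent(self):
        cfg = SimulationConfig(n_accessions=80, n_snps=400, missing_rate=0.1,
                               maf_range=(0.02, 0.5), rng_seed=21)
        gm = simulate_genotypes(cfg)
        once = filter_snps(gm)
        twice = filter_snps(once)
        assert list(once.snp_ids) == list(twice.snp_ids)

    def test_all_removed_error(self, make_gm):
        gm = make_gm(np.zeros((20, 3)))  # all monomorphic
        with pytest.raises(ValueError, match="all SNPs removed"):
            filter_snps(gm)


class TestKinship:
    def test_matches_hand_computation(self, make_gm):
        d = np.array(
            [[0.0, 2.0, 0.0, 2.0],
             [2.0, 0.0, 0.0, 2.0],
             [0.0, 2.0, 2.0, 0.0]]
        )
        gm = make_gm(d)
        k = compute_kinship(gm)
        p = d.mean(axis=0) / 2
        w = d - 2 * p
        expected = w @ w.T / np.sum(2 * p * (1 - p))
        np.testing.assert_allclose(k, expected, atol=1e-12)

    def test_duplicate_accessions_share_diagonal(self, make_gm):
        base = simulate_genotypes(
            SimulationConfig(n_accessions=10, n_snps=100, rng_seed=22)
        )
        d = np.vstack([base.dosage, base.dosage[0]])
        gm = make_gm(d, chrom=base.chrom, pos=base.pos)
        k = compute_kinship(gm)
        assert k[0, 10] == pytest.approx(k[0, 0], rel=1e-12)
        assert k[10, 10] == pytest.approx(k[0, 0], rel=1e-12)

    def test_symmetric_psd(self):
        gm = simulate_genotypes(
            SimulationConfig(n_accessions=30, n_snps=300, missing_rate=0.05,
                             rng_seed=23)
        )
        k = compute_kinship(gm)
        np.testing.assert_allclose(k, k.T)
        assert np.linalg.eigvalsh(k).min() >= -1e-8

    def test_monomorphic_only_error(self, make_gm):
        gm = make_gm(np.full((5, 4), 2.0))
        with pytest.raises(ValueError, match="monomorphic"):
            compute_kinship(gm)


class TestPCs:
    def test_default_count_and_orthogonality(self):
        gm = simulate_genotypes(
            SimulationConfig(n_accessions=40, n_snps=300, rng_seed=24)
        )
        scores = compute_pcs(gm)
        assert scores.shape == (40, 5)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_too_many_components_error(self):
        gm = simulate_genotypes(
            SimulationConfig(n_accessions=5, n_snps=50, rng_seed=25)
        )
        with pytest.raises(ValueError, match="n_pcs"):
            compute_pcs(gm, 5)


class TestGlmScan:
    def test_perfect_association(self):
        cfg = SimulationConfig(n_accessions=120, n_snps=300, n_subpops=1,
                               fst=0.0, rng_seed=26)
        gm = simulate_genotypes(cfg)
        j = 17
        y = 3.0 * gm.dosage[:, j]  # exactly linear, zero noise
        res = glm_scan(gm, y)
        assert res.loc[j, "p"] < 1e-30
        others = res.drop(index=j)["p"]
        assert (others > 1e-6).mean() > 0.98

    def test_null_p_values_uniform(self):
        # ld_block_length=1: independent markers, so KS on the p-values is valid
        cfg = SimulationConfig(n_accessions=150, n_snps=3000, n_subpops=1,
                               fst=0.0, ld_block_length=1, rng_seed=27)
        gm = simulate_genotypes(cfg)
        y = np.random.default_rng(27).normal(size=150)
        res = glm_scan(gm, y)
        ks = stats.kstest(res["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_covariate_absorbs_confounder(self):
        cfg = SimulationConfig(n_accessions=200, n_snps=2000, n_subpops=1,
                               fst=0.0, rng_seed=28)
        gm = simulate_genotypes(cfg)
        rng = np.random.default_rng(28)
        mc = rng.uniform(11, 26, size=200)
        y = mc + rng.normal(scale=0.5, size=200)
        res = glm_scan(gm, y, covariates=pd.DataFrame({"mc": mc}))
        assert (res["p"] < 9.99e-6).sum() == 0

    def test_constant_trait_error(self, make_gm):
        gm = make_gm(np.tile([0.0, 2.0], (4, 1)))
        with pytest.raises(ValueError, match="constant"):
            glm_scan(gm, np.ones(4))

    def test_rank_deficient_covariates_error(self, make_gm):
        rng = np.random.default_rng(0)
        gm = make_gm(rng.choice([0.0, 2.0], size=(30, 5)))
        cov = pd.DataFrame({"a": np.ones(30), "b": np.arange(30.0)})
        with pytest.raises(ValueError, match="rank deficient"):
            glm_scan(gm, rng.normal(size=30), covariates=cov)


def dense_gls_oracle(gm, y, k, gamma, cov=None):
    """Brute-force per-SNP GLS with explicit covariance inversion."""
    n = len(y)
    x0 = np.ones((n, 1)) if cov is None else np.column_stack([np.ones(n), cov])
    out = np.full(gm.n_snps, np.nan)
    v = gamma * k + np.eye(n)
    for j in range(gm.n_snps):
        g = gm.dosage[:, j]
        keep = ~np.isnan(g)
        x = np.column_stack([x0[keep], g[keep]])
        vi = np.linalg.inv(v[np.ix_(keep, keep)])
        xtvx = x.T @ vi @ x
        beta = np.linalg.solve(xtvx, x.T @ vi @ y[keep])
        r = y[keep] - x @ beta
        df = keep.sum() - x.shape[1]
        sig = (r @ vi @ r) / df
        se = np.sqrt(sig * np.linalg.inv(xtvx)[-1, -1])
        out[j] = 2 * stats.t.sf(abs(beta[-1] / se), df)
    return out


class TestMlmScan:
    def test_zero_variance_ratio_collapses_to_glm(self):
        cfg = SimulationConfig(n_accessions=60, n_snps=200, rng_seed=29)
        gm = simulate_genotypes(cfg)
        y = np.random.default_rng(29).normal(size=60)
        k = compute_kinship(gm)
        mlm, vc = mlm_scan(gm, y, k, gamma=0.0)
        glm = glm_scan(gm, y)
        np.testing.assert_allclose(
            -np.log10(mlm["p"]), -np.log10(glm["p"]), atol=1e-8
        )
        assert vc["sigma_g2"] == 0.0

    def test_matches_dense_gls_oracle(self):
        cfg = SimulationConfig(n_accessions=30, n_snps=300, missing_rate=0.05,
                               n_subpops=2, fst=0.3, rng_seed=30)
        gm = simulate_genotypes(cfg)
        k = compute_kinship(gm)
        rng = np.random.default_rng(30)
        y = rng.normal(size=30) + 0.5 * gm.imputed()[:, 5]
        mlm, vc = mlm_scan(gm, y, k)
        oracle = dense_gls_oracle(gm, y, k, vc["gamma"])
        np.testing.assert_allclose(
            -np.log10(mlm["p"]), -np.log10(oracle), atol=1e-8
        )

    def test_non_psd_kinship_error(self, make_gm):
        rng = np.random.default_rng(1)
        gm = make_gm(rng.choice([0.0, 2.0], size=(10, 20)))
        bad = -np.eye(10)
        with pytest.raises(ValueError, match="not PSD"):
            mlm_scan(gm, rng.normal(size=10), bad)

    def test_asymmetric_kinship_error(self, make_gm):
        rng = np.random.default_rng(2)
        gm = make_gm(rng.choice([0.0, 2.0], size=(10, 20)))
        bad = np.eye(10)
        bad[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            mlm_scan(gm, rng.normal(size=10), bad)


class TestInflation:
    def test_all_half_gives_unity(self):
        lam, _ = genomic_inflation(np.full(500, 0.5))
        assert lam == pytest.approx(1.0, abs=1e-12)

    def test_uniform_near_unity(self):
        p = np.random.default_rng(31).uniform(size=10_000)
        lam, qq = genomic_inflation(p)
        assert 0.95 < lam < 1.05
        assert len(qq) == 10_000

    def test_scaling_down_increases_lambda(self):
        p = np.random.default_rng(32).uniform(size=1000)
        lam1, _ = genomic_inflation(p)
        lam2, _ = genomic_inflation(p * 0.5)
        assert lam2 > lam1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="at least 100"):
            genomic_inflation(np.full(10, 0.5))
        with pytest.raises(ValueError, match="in \\(0, 1\\]"):
            genomic_inflation(np.r_[np.full(200, 0.5), 0.0])


def _scan_table(pos, p_glm, p_mlm, chrom=1):
    m = len(pos)
    return pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(m)],
            "chrom": chrom,
            "pos": pos,
            "p_glm": p_glm,
            "p_mlm": p_mlm,
        }
    )


class TestPeaks:
    def test_threshold_boundary(self):
        tab = _scan_table([100, 200], [1.0e-5, 9.9e-6], [1.0e-5, 9.9e-6])
        peaks = call_peaks(tab)
        assert len(peaks) == 1
        assert peaks[0].lead_snp == "s1"

    def test_single_model_significance_is_not_a_peak(self):
        tab = _scan_table([100], [1e-8], [0.5])
        assert call_peaks(tab) == []

    def test_cluster_extent(self):
        pos = [1000, 2000, 3000, 4000, 5000, 6000, 2_000_000]
        sig = [0.5, 1e-7, 1e-9, 1e-7, 0.5, 0.5, 0.5]
        tab = _scan_table(pos, sig, sig)
        peaks = call_peaks(tab, merge_distance=200_000)
        assert len(peaks) == 1
        pk = peaks[0]
        assert (pk.start, pk.end) == (2000, 4000)
        assert pk.lead_snp == "s2"
        assert pk.n_markers == 3

    def test_distant_clusters_split(self):
        pos = [1000, 2000, 500_000, 501_000]
        sig = [1e-7, 1e-8, 1e-9, 1e-7]
        peaks = call_peaks(_scan_table(pos, sig, sig), merge_distance=200_000)
        assert len(peaks) == 2

    def test_invalid_extent_rejected(self):
        with pytest.raises(ValueError, match="start"):
            Peak(chrom=1, start=10, end=5, lead_snp="s", lead_p_glm=1e-7,
                 lead_p_mlm=1e-7, n_markers=1)


GFF = """##gff-version 3
1\ttest\tgene\t500\t900\t.\t+\t.\tID=geneA
1\ttest\tgene\t1500\t1600\t.\t+\t.\tID=geneB
1\ttest\tgene\t5000\t6000\t.\t-\t.\tID=geneC
"""


class TestAnnotation:
    def _peak(self, start, end, chrom=1):
        return Peak(chrom=chrom, start=start, end=end, lead_snp="lead",
                    lead_p_glm=1e-7, lead_p_mlm=1e-7, n_markers=1)

    def test_overlapping_genes_reported(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(GFF)
        genes = annotate_peaks([self._peak(400, 1550)], str(gff))
        ids = {g["gene_id"] for g in genes["lead"]}
        assert ids == {"geneA", "geneB"}

    def test_single_base_overlap_counts(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(GFF)
        genes = annotate_peaks([self._peak(900, 1000)], str(gff))
        assert {g["gene_id"] for g in genes["lead"]} == {"geneA"}

    def test_chromosome_mismatch_error(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(GFF)
        with pytest.raises(ValueError, match="not present"):
            annotate_peaks([self._peak(1, 10, chrom=9)], str(gff))
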