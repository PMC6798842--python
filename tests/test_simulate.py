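"""Tests for the synthetic storage-experiment generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seedlong import (
    SimulationConfig,
    TruePanel,
    simulate_dataset,
    simulate_genotypes,
    simulate_germination,
    simulate_phenotypes,
)


class TestGenotypes:
    def test_inbred_dosages_within_maf_bounds(self):
        cfg = SimulationConfig(n_accessions=10, n_snps=100, n_subpops=2,
                               missing_rate=0.0, rng_seed=1)
        gm = simulate_genotypes(cfg)
        assert gm.dosage.shape == (10, 100)
        vals = np.unique(gm.dosage)
        assert set(vals).issubset({0.0, 2.0})
        maf = gm.maf()
        lo, hi = cfg.maf_range
        assert np.all(maf >= lo - 1e-12) and np.all(maf <= hi + 1e-12)

    def test_missing_fraction_within_exact_binomial_interval(self):
        # 100 x 500 = 50 000 entries at rate 0.2
        cfg = SimulationConfig(n_accessions=100, n_snps=500, missing_rate=0.2,
                               rng_seed=2)
        gm = simulate_genotypes(cfg)
        n_missing = int(np.isnan(gm.dosage).sum())
        lo, hi = stats.binom.interval(0.99, 50_000, 0.2)
        assert lo <= n_missing <= hi

    def test_pc1_separates_divergent_subpopulations(self):
        from seedlong import compute_pcs

        cfg = SimulationConfig(n_accessions=40, n_snps=800, n_subpops=2,
                               fst=0.4, rng_seed=3)
        gm = simulate_genotypes(cfg)
        pc1 = compute_pcs(gm, 2)[:, 0]
        a = pc1[gm.subpop == 0]
        b = pc1[gm.subpop == 1]
        # no overlap between the two clusters on PC1
        assert (a.max() < b.min()) or (b.max() < a.min())

    def test_positions_sorted_within_chromosomes(self):
        gm = simulate_genotypes(SimulationConfig(n_accessions=20, n_snps=600,
                                                 rng_seed=4))
        assert set(np.unique(gm.chrom)) <= set(range(1, 13))
        for c in np.unique(gm.chrom):
            assert np.all(np.diff(gm.pos[gm.chrom == c]) > 0)

    def test_too_many_subpops_error(self):
        cfg = SimulationConfig(n_accessions=5, n_snps=50, n_subpops=10)
        with pytest.raises(ValueError, match="n_subpops"):
            simulate_genotypes(cfg)

    @pytest.mark.parametrize("bad_range", [(0.3, 0.1), (0.0, 0.5), (0.1, 0.6)])
    def test_invalid_maf_range_error(self, bad_range):
        with pytest.raises(ValueError, match="maf_range"):
            SimulationConfig(maf_range=bad_range)


class TestPhenotypes:
    def test_degenerate_model_gives_identical_first_harvest(self):
        cfg = SimulationConfig(n_accessions=25, n_snps=100, qtl_spec=(),
                               heritability=0.0, log_p50_sd=0.0,
                               ki_log_sd=0.0, rng_seed=5)
        gm = simulate_genotypes(cfg)
        panel = simulate_phenotypes(gm, cfg)
        first = panel.lots_at(31)
        for col in ("ki", "sigma", "p50"):
            assert first[col].nunique() == 1

    def test_mc_decline_multiplies_p50(self):
        # exactly 1 % drying between maturities, baseline p50 = 20 d
        cfg = SimulationConfig(
            n_accessions=5, n_snps=50, baseline_ki=2.0, baseline_sigma=10.0,
            heritability=0.0, log_p50_sd=0.0, ki_log_sd=0.0,
            ki_maturity_gain=0.0, mc_effect=0.087,
            dry_prob=1.0, dry_loss=(1.0, 0.0), rng_seed=6,
        )
        gm = simulate_genotypes(cfg)
        panel = simulate_phenotypes(gm, cfg)
        p31 = panel.lots_at(31)["p50"].to_numpy()
        p38 = panel.lots_at(38)["p50"].to_numpy()
        np.testing.assert_allclose(p31, 20.0)
        np.testing.assert_allclose(p38, 21.74)

    def test_planted_qtl_carrier_ratio(self):
        cfg = SimulationConfig(n_accessions=500, n_snps=200, n_subpops=1,
                               fst=0.0, rng_seed=7)
        gm = simulate_genotypes(cfg)
        maf = gm.maf()
        q = int(np.flatnonzero(maf >= 0.3)[0])
        cfg = cfg.with_(qtl_spec=((q, 0.3),))
        panel = simulate_phenotypes(gm, cfg)
        first = panel.lots_at(31)
        d = gm.dosage[:, q]
        carriers = first.loc[d == 2, "p50"].mean()
        non = first.loc[d == 0, "p50"].mean()
        # lognormal noise cancels in expectation; allow ~3 SE of the means
        assert abs(carriers / non - np.exp(0.3)) < 0.1

    def test_ki_sigma_p50_identity(self):
        cfg = SimulationConfig(n_accessions=50, n_snps=100, rng_seed=8)
        gm, panel, _ = simulate_dataset(cfg)
        t = panel.table
        np.testing.assert_allclose(t["ki"] * t["sigma"], t["p50"], rtol=1e-14)
        assert (t["p50"] > 0).all() and (t["sigma"] > 0).all()

    def test_heritability_out_of_range_error(self):
        with pytest.raises(ValueError, match="heritability"):
            SimulationConfig(heritability=1.0)

    def test_qtl_index_out_of_range_error(self):
        cfg = SimulationConfig(n_accessions=10, n_snps=20, qtl_spec=((99, 0.3),))
        gm = simulate_genotypes(cfg)
        with pytest.raises(ValueError, match="QTL index"):
            simulate_phenotypes(gm, cfg)


def _single_lot_panel(ki, sigma, n_lots=1):
    tab = pd.DataFrame(
        {
            "accession": [f"L{i}" for i in range(n_lots)],
            "subpop": 0,
            "maturity": 38,
            "harvest_mc": 15.0,
            "ki": ki,
            "sigma": sigma,
            "p50": ki * sigma,
            "log_p50": np.log(ki * sigma),
        }
    )
    return TruePanel(table=tab, qtl_genotypes=pd.DataFrame(), rng_seed=0)


class TestGermination:
    def test_default_schedule_shape(self):
        cfg = SimulationConfig(n_accessions=4, n_snps=40, rng_seed=9)
        gm, panel, germ = simulate_dataset(cfg)
        # 3 maturities x 10 sampling times (0-63 d step 7), 60 seeds each
        one = germ[(germ.accession == "ACC0000") & (germ.dah == 38)]
        assert list(one["storage_day"]) == list(range(0, 64, 7))
        assert (germ["n_sown"] == 60).all()
        assert len(germ) == 4 * 3 * 10

    def test_counts_follow_survival_curve(self):
        # law of large numbers: 10 000 replicate lots with Ki=3, sigma=10
        panel = _single_lot_panel(3.0, 10.0, n_lots=10_000)
        cfg = SimulationConfig(n_accessions=4, n_snps=40,
                               storage_times=(0, 30, 60), rng_seed=10)
        germ = simulate_germination(panel, cfg, np.random.default_rng(10))
        for t in (0, 30, 60):
            frac = germ.loc[germ.storage_day == t, "n_germ"].mean() / 60
            p = stats.norm.cdf(3.0 - t / 10.0)
            se = np.sqrt(p * (1 - p) / (60 * 10_000))
            assert abs(frac - p) < 3 * se
        # t = p50 = 30 d: expected germination exactly one half
        assert abs(stats.norm.cdf(3.0 - 30 / 10.0) - 0.5) < 1e-15

    def test_negative_storage_time_error(self):
        panel = _single_lot_panel(2.0, 10.0)
        cfg = SimulationConfig(n_accessions=2, n_snps=20)
        cfg.storage_times = (-5, 0, 7)  # bypass constructor validation
        with pytest.raises(ValueError, match="non-negative"):
            simulate_germination(panel, cfg)

    def test_reproducible_under_seed(self):
        cfg = SimulationConfig(n_accessions=6, n_snps=60, rng_seed=11)
        _, _, g1 = simulate_dataset(cfg)
        _, _, g2 = simulate_dataset(cfg)
        pd.testing.assert_frame_equal(g1, g2)
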