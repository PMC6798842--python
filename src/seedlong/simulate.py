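"""Synthetic genebank storage experiments with known genetic architecture.

Emulates, at desk scale, the data a seed-longevity GWAS consumes: an
inbred accession panel with subpopulation structure and LD blocks,
longevity parameters (Ki, sigma, p50) with planted QTLs and a polygenic
background confounded with structure, a declining harvest-moisture
trajectory over three harvest maturities whose change feeds back on p50,
and binomial germination counts sampled on the storage schedule of the
phenotyping protocol (60 seeds at 7-day intervals from 0 to 63 days at
each harvest maturity).

All randomness flows from one integer seed via ``numpy`` SeedSequence
spawning, so every stage is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "TruePanel",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_germination",
    "simulate_dataset",
]

N_CHROMOSOMES = 12


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic storage experiment.

    Defaults mirror the real phenotyping design: a 299-accession inbred
    panel, germination tests of 60 seeds at 7-day intervals from 0 to
    63 days of experimental storage, three harvest maturities (31/38/45
    days after heading), harvest MC spanning 11.5-25.7 % fresh weight,
    and an 8.7 % proportional change in p50 per 1 % harvest-MC decline.
    Panel size and marker density are desk-scale stand-ins for the real
    genotype set.
    """

    n_accessions: int = 299
    n_snps: int = 5000
    n_subpops: int = 3
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    ld_block_length: int = 10
    qtl_spec: tuple[tuple[int, float], ...] = ()
    heritability: float = 0.5
    baseline_ki: float = 2.7
    baseline_sigma: float = 7.4
    mc_effect: float = 0.087
    storage_times: tuple[int, ...] = tuple(range(0, 64, 7))
    seeds_per_time: int = 60
    rng_seed: int = 0
    # population-genetic nuisance parameters
    fst: float = 0.15
    recomb_rate: float = 0.1
    het_rate: float = 0.0
    # phenotype dispersion (log p50 scale) and confounding share
    log_p50_sd: float = 0.35
    subpop_share: float = 0.5
    ki_log_sd: float = 0.2
    ki_maturity_gain: float = 0.3
    # harvest moisture trajectory
    maturities: tuple[int, ...] = (31, 38, 45)
    mc_range: tuple[float, float] = (11.5, 25.7)
    dry_prob: float = 0.75
    dry_loss: tuple[float, float] = (2.5, 1.5)
    wet_gain: tuple[float, float] = (1.5, 1.0)

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        t = np.asarray(self.storage_times, dtype=float)
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("storage_times must be non-negative and strictly increasing")
        if self.seeds_per_time <= 0:
            raise ValueError("seeds_per_time must be positive")
        if not 0 <= self.heritability < 1:
            raise ValueError("heritability must be in [0, 1)")
        if self.n_accessions <= 0 or self.n_snps <= 0:
            raise ValueError("panel dimensions must be positive")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class TruePanel:
    """Generative truth: one row per accession x harvest maturity.

    ``table`` columns: accession, subpop, maturity, harvest_mc, ki,
    sigma, p50, log_p50.  ``Ki * sigma == p50`` holds by construction.
    ``qtl_genotypes`` carries the planted-QTL dosages per accession.
    """

    table: pd.DataFrame
    qtl_genotypes: pd.DataFrame
    rng_seed: int

    def lots_at(self, maturity: int) -> pd.DataFrame:
        return self.table[self.table["maturity"] == maturity].reset_index(drop=True)


def _assign_positions(
    n_snps: int, block_of_snp: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Chromosome and position per SNP; whole LD blocks stay on one
    chromosome, block spans < 200 kb, inter-block gaps 0.25-0.8 Mb."""
    blocks = np.unique(block_of_snp)
    n_blocks = len(blocks)
    chrom_of_block = 1 + (np.arange(n_blocks) * N_CHROMOSOMES) // n_blocks
    chrom = np.empty(n_snps, dtype=int)
    pos = np.empty(n_snps, dtype=int)
    for c in range(1, N_CHROMOSOMES + 1):
        cursor = 1
        for b in blocks[chrom_of_block == c]:
            idx = np.flatnonzero(block_of_snp == b)
            gap = int(rng.integers(250_000, 800_000))
            offsets = np.cumsum(rng.integers(500, 19_000, size=len(idx)))
            chrom[idx] = c
            pos[idx] = cursor + gap + offsets
            cursor = pos[idx].max()
    return chrom, pos


def _enforce_maf(
    dosage: np.ndarray,
    maf_range: tuple[float, float],
    rng: np.random.Generator,
) -> None:
    """Flip a minimal number of homozygote calls so every SNP's sample
    MAF (non-missing) lands inside the configured bounds.  In place."""
    lo, hi = maf_range
    n, m = dosage.shape
    for j in range(m):
        col = dosage[:, j]
        obs = ~np.isnan(col)
        n_obs = int(obs.sum())
        if n_obs == 0:
            continue
        f = float(np.nansum(col)) / (2 * n_obs)
        maf = min(f, 1 - f)
        minor_val = 2.0 if f <= 0.5 else 0.0
        major_val = 2.0 - minor_val
        # counts of the minor homozygote needed to sit inside [lo, hi]
        need_min = math.ceil(lo * n_obs)
        need_max = math.floor(hi * n_obs)
        cur = int(np.sum(col[obs] == minor_val))
        if maf < lo:
            deficit = need_min - cur
            pool = np.flatnonzero(obs & (col == major_val))
            pick = rng.choice(pool, size=deficit, replace=False)
            dosage[pick, j] = minor_val
        elif maf > hi and need_max >= 0:
            excess = cur - need_max
            if excess > 0:
                pool = np.flatnonzero(obs & (col == minor_val))
                pick = rng.choice(pool, size=excess, replace=False)
                dosage[pick, j] = major_val


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Inbred accession panel with subpopulation divergence and LD blocks.

    Allele frequencies diverge between subpopulations under a
    Balding-Nichols drift model (Fst = ``config.fst``); SNPs within an
    LD block share a latent allele with per-SNP recombination
    probability ``config.recomb_rate``.  Dosages are {0, 2} (inbred) by
    default; ``het_rate`` introduces heterozygote calls.  Sample MAFs
    are nudged into ``maf_range`` by minimal homozygote flips.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n, m, k = config.n_accessions, config.n_snps, config.n_subpops
    if k > n:
        raise ValueError("n_subpops cannot exceed n_accessions")
    if k < 1:
        raise ValueError("need at least one subpopulation")
    subpop = np.arange(n) % k
    rng.shuffle(subpop)
    lo, hi = config.maf_range
    ancestral = rng.uniform(lo, hi, size=m)
    if k > 1 and config.fst > 0:
        f = config.fst
        a = ancestral * (1 - f) / f
        b = (1 - ancestral) * (1 - f) / f
        freqs = np.clip(rng.beta(a[None, :], b[None, :], size=(k, m)), 1e-3, 1 - 1e-3)
    else:
        freqs = np.tile(ancestral, (k, 1))
    block_of_snp = np.arange(m) // config.ld_block_length
    dosage = np.empty((n, m), dtype=float)
    acc_freq = freqs[subpop]  # (n, m)
    for b in np.unique(block_of_snp):
        idx = np.flatnonzero(block_of_snp == b)
        latent = rng.uniform(size=(n, 1))
        fresh = rng.uniform(size=(n, len(idx)))
        recomb = rng.uniform(size=(n, len(idx))) < config.recomb_rate
        u = np.where(recomb, fresh, latent)
        allele = (u < acc_freq[:, idx]).astype(float)
        dosage[:, idx] = 2.0 * allele
    if config.het_rate > 0:
        het = rng.uniform(size=(n, m)) < config.het_rate
        dosage[het] = 1.0
    if config.missing_rate > 0:
        miss = rng.uniform(size=(n, m)) < config.missing_rate
        dosage[miss] = np.nan
    _enforce_maf(dosage, config.maf_range, rng)
    chrom, pos = _assign_positions(m, block_of_snp, rng)
    snp_ids = np.array([f"c{c}_{p}" for c, p in zip(chrom, pos)], dtype=object)
    return GenotypeMatrix(
        dosage=dosage,
        accessions=np.array([f"ACC{i:04d}" for i in range(n)], dtype=object),
        snp_ids=snp_ids,
        chrom=chrom,
        pos=pos,
        ref=np.full(m, "A", dtype=object),
        alt=np.full(m, "G", dtype=object),
        subpop=subpop,
    )


def _mc_step(
    mc: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """One maturity step of the harvest-MC trajectory: most accessions
    dry on the plant, some re-wet."""
    n = len(mc)
    dries = rng.uniform(size=n) < config.dry_prob
    loss = np.abs(rng.normal(config.dry_loss[0], config.dry_loss[1], size=n))
    gain = np.abs(rng.normal(config.wet_gain[0], config.wet_gain[1], size=n))
    new = np.where(dries, mc - loss, mc + gain)
    return np.clip(new, 5.0, 35.0)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TruePanel:
    """True longevity parameters per accession x maturity.

    log p50 at the first maturity = log(baseline Ki x baseline sigma)
    + planted QTL effects (per favourable allele, dosage/2) + a polygenic
    term with subpopulation mean shifts scaled to ``heritability`` +
    residual noise.  Between maturities p50 responds linearly to the
    harvest-MC change: p50_later = p50_earlier * (1 + mc_effect * MC
    decline).  Ki varies log-normally per accession and rises with
    maturity; sigma is back-derived so Ki * sigma = p50 exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    n = genotypes.n_accessions
    for j, _ in config.qtl_spec:
        if not 0 <= j < genotypes.n_snps:
            raise ValueError(f"QTL index {j} outside the SNP range")
    subpop = (
        genotypes.subpop
        if genotypes.subpop is not None
        else np.zeros(n, dtype=int)
    )
    qtl = np.zeros(n)
    qtl_cols = {}
    for j, beta in config.qtl_spec:
        d = genotypes.dosage[:, j]
        d = np.where(np.isnan(d), np.nanmean(d), d)
        qtl += beta * d / 2.0
        qtl_cols[genotypes.snp_ids[j]] = d
    h2, total_sd = config.heritability, config.log_p50_sd
    sd_g = math.sqrt(h2) * total_sd
    sd_e = math.sqrt(1 - h2) * total_sd
    sd_shift = math.sqrt(config.subpop_share) * sd_g
    sd_poly = math.sqrt(1 - config.subpop_share) * sd_g
    shifts = rng.normal(0.0, 1.0, size=int(subpop.max()) + 1) * sd_shift
    poly = rng.normal(0.0, sd_poly if sd_poly > 0 else 0.0, size=n)
    noise = rng.normal(0.0, sd_e if sd_e > 0 else 0.0, size=n)
    log_p50 = (
        math.log(config.baseline_ki * config.baseline_sigma)
        + qtl
        + shifts[subpop]
        + poly
        + noise
    )
    p50 = np.exp(log_p50)
    ki_acc = config.baseline_ki * np.exp(rng.normal(0.0, config.ki_log_sd, size=n))
    mc = np.clip(
        rng.uniform(config.mc_range[0], config.mc_range[1], size=n), 0.1, 99.9
    )
    rows = []
    qtl_df = pd.DataFrame(
        qtl_cols, index=list(genotypes.accessions)
    ).rename_axis("accession")
    for mi, maturity in enumerate(config.maturities):
        if mi > 0:
            new_mc = _mc_step(mc, config, rng)
            factor = np.maximum(1.0 + config.mc_effect * (mc - new_mc), 0.05)
            p50 = p50 * factor
            mc = new_mc
        ki = np.maximum(ki_acc + config.ki_maturity_gain * mi, 0.2)
        sigma = p50 / ki
        rows.append(
            pd.DataFrame(
                {
                    "accession": genotypes.accessions,
                    "subpop": subpop,
                    "maturity": maturity,
                    "harvest_mc": mc,
                    "ki": ki,
                    "sigma": sigma,
                    "p50": ki * sigma,
                    "log_p50": np.log(ki * sigma),
                }
            )
        )
    return TruePanel(
        table=pd.concat(rows, ignore_index=True),
        qtl_genotypes=qtl_df,
        rng_seed=config.rng_seed,
    )


def simulate_germination(
    panel: TruePanel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Binomial germination counts on the storage schedule.

    For each lot and storage time ``t`` the germinated count is
    Binomial(seeds_per_time, Phi(Ki - t/sigma)).  Returns a tidy table
    (accession, dah, storage_day, n_sown, n_germ).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 2)
    times = np.asarray(config.storage_times, dtype=float)
    if np.any(times < 0):
        raise ValueError("storage times must be non-negative")
    tab = panel.table
    if np.any(tab["sigma"] <= 0):
        raise ValueError("all sigma values must be positive")
    ki = tab["ki"].to_numpy()[:, None]
    sigma = tab["sigma"].to_numpy()[:, None]
    prob = stats.norm.cdf(ki - times[None, :] / sigma)
    counts = rng.binomial(config.seeds_per_time, prob)
    n_lots = len(tab)
    out = pd.DataFrame(
        {
            "accession": np.repeat(tab["accession"].to_numpy(), len(times)),
            "dah": np.repeat(tab["maturity"].to_numpy(), len(times)),
            "storage_day": np.tile(times.astype(int), n_lots),
            "n_sown": config.seeds_per_time,
            "n_germ": counts.ravel(),
        }
    )
    return out


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, TruePanel, pd.DataFrame]:
    """Generate genotypes, truth panel and germination counts from one seed."""
    ss = np.random.SeedSequence(config.rng_seed)
    r_geno, r_pheno, r_germ = (np.random.default_rng(s) for s in ss.spawn(3))
    gm = simulate_genotypes(config, r_geno)
    panel = simulate_phenotypes(gm, config, r_pheno)
    germ = simulate_germination(panel, config, r_germ)
    return gm, panel, germ
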