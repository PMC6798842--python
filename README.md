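# seedlong

Seed-lot viability modelling, genome-wide association and haplotype-effect
estimation for genebank storage experiments.

Genebanks monitor stored accessions by periodic germination tests and must
decide when to regenerate a seed lot. The quantitative backbone of that
decision is the seed viability equation: on the probit scale, viability
declines linearly with storage time,

    v(t) = Ki − t/σ,

where `v` is viability in normal equivalent deviates (NED), `Ki` is the
initial viability of the lot (NED) and `σ` is the time (days) for viability
to fall by one NED, so the survival-curve slope is `−σ⁻¹`. The storage time
at which viability reaches 50 % (0 NED) is `p50 = Ki·σ`. Both `Ki` and `σ`
vary between rice accessions, and the longevity of a lot also depends on the
seed moisture content (MC) at harvest: lots that dry on the plant between
sequential harvests gain longevity roughly in proportion to the MC decline.

`seedlong` implements the full analysis chain for an inbred crop panel:

* **Viability fitting** — binomial probit maximum likelihood per seed lot
  (`ProbitSurvival` → `SurvivalFit`), with the declining-phase truncation
  rule, delta-method standard errors for `p50`, a common-slope constrained
  model across harvest maturities judged by an approximate F-test
  (`CommonSlopeProbit`), and maximum-`p50` lot selection.
* **Association scans** — SNP filtering (missingness > 20 %, MAF < 5 %),
  VanRaden kinship, principal components, and a dual scan per trait:
  fixed-effects GLM with PCs and an EMMAX-style kinship mixed linear model
  (`AssociationStudy` → `AssociationResults`), with genomic-control λ
  diagnostics, dual-model peak calling at `P < 9.99e−6` and GFF3 gene
  annotation of peak intervals.
* **Haplotype effects** — favourable-allele classification at peak lead SNPs
  and combination-group enhancement ratios of `p50` against the
  all-unfavourable reference, plus per-locus allele effects.
* **Summary statistics** — trait descriptive tables (range, mean, sd, CV),
  sequential-harvest ΔMC→Δp50 regressions, pairwise correlations and paired
  maturity t-tests.
* **Synthetic data** — a generator for inbred panels with subpopulation
  structure, LD blocks, planted longevity QTLs, harvest-MC trajectories and
  binomial germination counts on the 0–63 d storage schedule, so the whole
  pipeline is testable without any external data.

## Worked example

```python
import pandas as pd
from seedlong import (SimulationConfig, simulate_dataset, fit_probit_survival,
                      AssociationStudy, filter_snps)

cfg = SimulationConfig(n_accessions=200, n_snps=2000,
                       qtl_spec=((940, 0.5),), rng_seed=7)
gm, panel, germ = simulate_dataset(cfg)

sub = germ[(germ.accession == "ACC0003") & (germ.dah == 38)]
fit = fit_probit_survival(sub.storage_day, sub.n_sown, sub.n_germ,
                          accession="ACC0003", maturity=38)
print(fit.summary())
```

```
Probit survival fit (viability equation)
--------------------------------------------
accession: ACC0003    maturity (DAH): 38
Ki         2.9138 NED   (se 0.2312)
slope     -0.0637 /d    (se 0.0052)
sigma     15.6961 d
p50       45.7355 d     (se 1.1101)
residual deviance 17.5030 on 6 df (8 points, truncated from day 14.0)
status: ok   converged: True
```

The lot starts at `Ki ≈ 2.9` NED (≈ 99.8 % germination), loses one NED every
`σ ≈ 15.7` days at 45 °C, and is expected to cross 50 % viability after
`p50 ≈ 45.7` days of experimental storage. The scan then recovers the
planted QTL:

```python
lots38 = panel.lots_at(38)
study = AssociationStudy(
    filter_snps(gm), lots38.p50.to_numpy(), trait_name="p50_38dah",
    covariates=pd.DataFrame({"harvest_mc": lots38.harvest_mc.to_numpy()}))
res = study.fit()
print(res.summary())
for p in res.call_peaks():
    print(f"peak chr{p.chrom}:{p.start}-{p.end} lead {p.lead_snp}")
```

```
Association scan: p50_38dah
--------------------------------------------
SNPs tested: 2000   covariates: ['PC1..PC5', 'harvest_mc']
lambda_GC  GLM+PCs 1.081   MLM 0.929
variance components: sigma_g2 123.6, sigma_e2 196.4 (gamma 0.629)
dual-model significant markers at P < 9.99e-06: 2
peak chr6:7401115-7429543 lead c6_7401115
```

The called peak's lead marker is exactly the planted causal SNP
(`c6_7401115`). λ values near 1 for both models indicate well-calibrated
scans.

A CLI mirrors the library (`seedlong simulate / fit / gwas / haplotypes /
stats / run`); `seedlong run` executes the whole pipeline from a germination
CSV, a phenotype CSV and a VCF or TSV genotype file, writing tidy result
tables and a run manifest.

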