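# Methods

## The viability equation and its fitting

Seed-lot survival in storage is modelled on the probit scale:
`v(t) = Ki − t/σ`, with `v` the viability in normal equivalent deviates
(NED) after `t` days, `Ki` the initial viability (NED) and `σ` the days for
viability to fall by one NED. The germinated count at time `t` is treated as
Binomial(n, Φ(Ki − t/σ)), with the two replicate dishes of 30 seeds pooled
into n = 60 trials (no dish random effect). Fitting maximises the binomial
probit log-likelihood via iteratively reweighted least squares
(statsmodels GLM, convergence tolerance 1e−10, up to 200 iterations).
Reported quantities: `Ki` (intercept), slope `b = −σ⁻¹`, `σ = −1/b`,
`p50 = −Ki/b = Ki·σ`, standard errors from the observed information, and the
`p50` SE by the delta method with gradient `(−1/b, Ki/b²)`. Observed
proportions of exactly 0 or 1 at individual times stay in the likelihood
without continuity correction.

**Truncation.** Lots often hold ~100 % germination (or apparently improve)
before declining; only the declining phase identifies the survival line.
The rule: sort by time, drop leading points up to — but keeping — the last
time at which the observed proportion attains its running maximum. A series
with all proportions equal is flagged `no-decline`; fewer than three
retained points is `unfittable`; a fit with no intermediate proportions is
`separation`; a non-negative fitted slope is `non-declining`. Flagged lots
are excluded from trait tables, mirroring how a storage-experiment protocol
discards lots that show no measurable deterioration inside the 63-day
window.

**Common-slope constraint.** For one accession's harvest maturities the
joint model has lot-specific intercepts and one shared slope. The constraint
is judged by an approximate F-test on the residual-deviance increase:

    F = [(D_c − D_u)/Δdf] / h,   h = max(D_u/df_u, 1),

compared with F(Δdf, df_u); the constraint is accepted when P > 0.05. The
heterogeneity factor `h` follows the classical probit-analysis convention of
scaling by the dispersion estimate only when it signals overdispersion.
With 60-seed binomial counts, cells in the tails of the survival curve have
near-zero expected failures and contribute almost nothing to the deviance
(or to Pearson X²), biasing the raw `D_u/df_u` well below 1; dividing by it
unconditionally makes the test anti-conservative, while the thresholded
factor restores close-to-nominal acceptance under a true common slope and
still deflates the statistic for genuinely overdispersed data. The
convention is recorded in the run manifest. For accessions whose lots cannot
be constrained, maturity-specific traits always use the per-lot
unconstrained slope.

**Best-lot selection.** Per accession, the maturity with the greatest
fitted `p50` among converged fits; ties break toward the earlier maturity.

## Association scans

SNPs are filtered before any scan: missing fraction > 0.20 or MAF < 0.05
(MAF on non-missing dosages; a MAF exactly 0.05 is retained). Kinship is
the centred cross-product (VanRaden) matrix `K = WW′/Σ2p(1−p)` on per-SNP
mean-imputed dosages; principal components come from the SVD of the centred
imputed matrix. Mean imputation is used only for these decompositions —
the scans themselves drop accessions with a missing dosage per SNP
(casewise deletion), avoiding imputation bias in the tests.

Two models run per trait:

* **GLM + PCs** — ordinary least squares of trait on dosage, an intercept,
  the top five PCs and any extra covariates; two-sided t test on the dosage
  coefficient (df = n − p).
* **Kinship MLM (EMMAX-style)** — the null model
  `y = Xβ + g + e, g ~ N(0, σ_g² K)` is fitted once by REML through the
  spectral decomposition of `K` (the variance ratio γ = σ_g²/σ_e² is
  profiled on a log grid and refined by bounded scalar minimisation, with
  the γ→0 OLS boundary checked explicitly); each SNP is then tested by
  generalized least squares with γ held fixed (Wald t). SNPs with missing
  dosages are handled exactly by a per-SNP Cholesky GLS on the subsetted
  covariance.

Harvest moisture content is a covariate for the `Ki` and `p50` traits but
not for the slope trait (configurable). Calibration is summarised by the
genomic-control factor λ_GC = median χ²₁ quantile of the p-values divided by
the χ²₁ median, plus expected-vs-observed −log₁₀p QQ tables.

**Peaks.** Markers with `P < 9.99e−6` in *both* models are candidates;
candidates within 200 kb (configurable) on one chromosome cluster into a
peak spanning the first to the last candidate, with the smallest-GLM-p
marker as lead. Gene annotation reports every GFF3 `gene` feature
overlapping a peak interval by at least 1 bp (1-based inclusive coordinates
throughout).

## Haplotype effects

At each peak's lead SNP the homozygote class with the higher mean trait
value defines the favourable allele (determined from the data, not from
external annotation); homozygous carriers are favourable, other classified
genotypes unfavourable, missing calls unknown. Fully classified accessions
form combination groups; enhancement % of a group is
`100·(mean p50 − reference mean)/reference mean` with the all-unfavourable
combination as reference. Groups smaller than `min_group_n = 3` are
suppressed (single-accession means are not reported); the reference is
always kept. Per-locus allele effect % uses the unfavourable-class mean as
denominator, and the favourable-allele frequency is the percentage of
classified accessions in the favourable state. A multi-SNP mode was
considered and deliberately not implemented: with peak marker sets
unspecified, the lead-SNP state is the reproducible operationalisation.

## Summary statistics

Descriptive tables report min, max, mean, sample sd (n−1) and
CV = 100·sd/mean, sign-preserving so the all-negative slope trait has a
negative CV. Correlations are Pearson with two-sided t tests on
pairwise-complete observations (assay traits may cover a subset of
accessions), starred at 0.05/0.001. Paired maturity comparisons are
two-sided paired t-tests (df = n−1); with zero variance of differences the
documented convention is t = 0, p = 1 when all differences are zero and
t = ±∞, p = 0 otherwise. The sequential-harvest regression takes, per
accession and maturity pair (31→38, 38→45 days after heading), the MC
change and the p50 change as a proportion of the earlier harvest's p50,
splits points by the sign of ΔMC into dried and wetted branches and fits
ordinary least squares per branch.

## The synthetic-data generator

The generator emulates the study conditions a desk-scale analysis needs:

* **Genotypes** — an inbred panel (dosages {0, 2}; a heterozygosity rate
  exists but defaults to 0) of 299 accessions × 5 000 SNPs by default, in
  three subpopulations whose allele frequencies diverge from a shared
  ancestral frequency (uniform on the MAF range 0.05–0.5) under a
  Balding–Nichols model with Fst 0.15. SNPs fall in LD blocks of 10 that
  share a latent allele with per-SNP recombination probability 0.1; whole
  blocks are laid on 12 chromosomes with intra-block spacing under 20 kb
  and inter-block gaps of 0.25–0.8 Mb, so block mates cluster into one
  called peak while distinct blocks do not merge. Sample MAFs are nudged
  into the configured bounds by minimal homozygote flips. Missingness is a
  parameter (default 0: the analysed marker sets of interest are
  post-filter) and is tested at 0.2 against the exact binomial interval.
* **Phenotypes** — log p50 at the first maturity is the log of
  baseline Ki × baseline σ (2.7 NED × 7.4 d ≈ 20 d, matching the observed
  trait means) plus planted QTL effects (per favourable allele), a
  polygenic term with subpopulation mean shifts (total non-QTL sd 0.35 on
  the log scale, heritability 0.5, half of the genetic variance between
  subpopulations — this deliberately confounds structure with the trait so
  that GLM-vs-MLM calibration is testable), and residual noise. Harvest MC
  starts uniform on 11.5–25.7 % and steps per maturity: 75 % of accessions
  dry (loss |N(2.5, 1.5)| %) and the rest re-wet (gain |N(1.5, 1)| %),
  reproducing the two-branch dried/wetted structure. p50 responds linearly
  to the MC change, `p50_later = p50_earlier·(1 + 0.087·(MC decline))`; the
  linear-in-ΔMC form is what a proportional-change-vs-ΔMC regression slope
  of 0.087 per 1 % means, and the round-trip test recovers it exactly. Ki
  varies log-normally across accessions (sd 0.2) and gains 0.3 NED per
  maturity step (matching the observed rise of mean Ki with maturity); σ is
  back-derived so Ki·σ = p50 holds to machine precision. The relative
  within-accession variability of Ki versus σ is not observable in the
  source data, so both are free parameters rather than a fixed ratio.
* **Germination counts** — Binomial(60, Φ(Ki − t/σ)) at t = 0, 7, …, 63 d
  for each accession × maturity, the storage-experiment schedule.

All randomness flows from one integer seed through spawned NumPy
generators, and outputs record the seed. What the generator does **not**
emulate: realistic LD decay (block structure is rectangular), the
988 k-SNP / 18 M-SNP scale, dormancy or germination-speed dynamics,
dish-level variation, and any genotype–MC interaction. Passing tests
therefore demonstrate the correctness and calibration of the machinery
under a faithful but idealised sampling model, not field-data performance.

## Problem sizes and numerical choices

The test suite runs the calibration studies at sizes chosen to estimate
each property precisely while keeping the suite quick on one CPU: 200
simulated lots for parameter recovery (median relative errors and CI
coverage over the observed Ki 0.5–6 / σ 2–33 ranges), 500 replicate
two-lot accessions for the F-test acceptance rate (judged against exact
binomial 99 % bounds around 0.95), 30 × 300 for the dense-GLS oracle
(agreement to 1e−8 in −log₁₀p), 10 000 null SNPs for λ calibration, and 50
replicates of a 300 × 5 000 panel with one planted QTL (~20 % of trait
variance) for end-to-end peak and haplotype-effect recovery.

Other numerical conventions: kinship PSD tolerance −1e−8 (scaled), REML
profile on log γ ∈ [−12, 12] with the OLS boundary compared explicitly,
p-values from t references with exact residual df, λ_GC computed against
the exact χ²₁ median, and all coordinates 1-based inclusive (VCF/GFF3
convention). Degenerate inputs are first-class: monomorphic kinship input,
rank-deficient covariates, constant traits, empty filter results, empty
haplotype reference groups and non-positive earlier p50 in the harvest
regression all raise informative errors rather than propagating NaNs.

## Known limitations

* The EMMAX approximation holds the null variance ratio fixed across SNPs;
  for very large single-SNP effects the per-SNP REML ratio would differ
  (standard speed/accuracy trade-off at this panel scale).
* The delta-method p50 interval is symmetric and can undercover for lots
  with near-boundary `Ki` or very shallow slopes; coverage is monitored in
  the acceptance suite rather than corrected.
* Peak extent depends on the 200 kb merge default; no LD-based block
  estimation is attempted.
* The F-test heterogeneity convention is approximate; with severely
  overdispersed real data a dish-level random effect would be the better
  model and is out of scope.
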