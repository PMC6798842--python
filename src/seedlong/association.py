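"""Genome-wide association scans for seed-longevity traits.

Two per-SNP models are run side by side, mirroring routine practice on
structured crop panels:

* a fixed-effects regression (GLM) of trait on dosage plus covariates —
  typically the top principal components and harvest moisture content;
* a kinship mixed linear model (MLM) with a single polygenic variance
  component estimated once by REML under the null model and then held
  fixed for every SNP test (EMMAX-style generalized least squares).

SNPs significant at the threshold in BOTH models form peaks; peak extent
is the physical span of the clustered sub-threshold markers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .genotypes import GenotypeMatrix, compute_kinship, compute_pcs, filter_snps

__all__ = [
    "AssociationStudy",
    "AssociationResults",
    "Peak",
    "glm_scan",
    "mlm_scan",
    "genomic_inflation",
    "call_peaks",
    "annotate_peaks",
]

#: genome-wide significance threshold on per-SNP p-values
DEFAULT_THRESHOLD = 9.99e-6
#: markers closer than this (bp) on one chromosome merge into one peak
DEFAULT_MERGE_DISTANCE = 200_000

_CHI2_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549...


def _design(n: int, covariates: np.ndarray | pd.DataFrame | None) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    if isinstance(covariates, pd.DataFrame):
        cols = list(covariates.columns)
        c = covariates.to_numpy(dtype=float)
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        cols = [f"x{j}" for j in range(c.shape[1])]
    x = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(
            f"covariate matrix is rank deficient (columns: {['const'] + cols})"
        )
    return x


def _ols_block(g: np.ndarray, y: np.ndarray, x: np.ndarray):
    """Exact per-SNP OLS of y on [x, g_j] via residualization (Frisch-Waugh).

    ``g`` is (n, m) with no missing values.  Returns beta, se, p arrays
    using a t reference with df = n - x.shape[1] - 1.
    """
    n = len(y)
    q, _ = np.linalg.qr(x)
    yr = y - q @ (q.T @ y)
    gr = g - q @ (q.T @ g)
    gg = np.einsum("ij,ij->j", gr, gr)
    df = n - x.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (gr.T @ yr) / gg
        rss = (yr @ yr) - beta**2 * gg
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / df / gg)
        tval = beta / se
    p = 2.0 * stats.t.sf(np.abs(tval), df)
    bad = ~np.isfinite(tval)
    beta[bad] = np.nan
    se[bad] = np.nan
    p[bad] = np.nan
    return beta, se, p


def glm_scan(
    genotypes: GenotypeMatrix,
    trait: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fixed-effects per-SNP regression: trait ~ dosage + covariates.

    Accessions with a missing dosage are dropped for that SNP (casewise
    deletion).  Returns a per-SNP table with effect, SE and two-sided
    p-value for the dosage coefficient.
    """
    y = np.asarray(trait, dtype=float)
    if np.nanstd(y) == 0:
        raise ValueError("trait is constant; nothing to scan")
    x = _design(len(y), covariates)
    g = genotypes.dosage
    m = g.shape[1]
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    p = np.full(m, np.nan)
    complete = ~np.isnan(g).any(axis=0)
    if complete.any():
        b, s, pv = _ols_block(g[:, complete], y, x)
        beta[complete], se[complete], p[complete] = b, s, pv
    for j in np.flatnonzero(~complete):
        keep = ~np.isnan(g[:, j])
        if keep.sum() <= x.shape[1] + 1:
            continue
        b, s, pv = _ols_block(g[keep, j][:, None], y[keep], x[keep])
        beta[j], se[j], p[j] = b[0], s[0], pv[0]
    return pd.DataFrame(
        {
            "snp": genotypes.snp_ids,
            "chrom": genotypes.chrom,
            "pos": genotypes.pos,
            "beta": beta,
            "se": se,
            "p": p,
        }
    )


def _reml_gamma(
    s: np.ndarray, yt: np.ndarray, ct: np.ndarray
) -> tuple[float, float, float]:
    """REML estimate of gamma = sigma_g^2 / sigma_e^2 on the eigenbasis of K.

    ``s`` are kinship eigenvalues, ``yt``/``ct`` the rotated trait and
    covariates.  Returns (gamma, sigma_g2, sigma_e2).
    """
    n, p = ct.shape
    ctc_logdet = np.linalg.slogdet(ct.T @ ct)[1]

    def neg_reml(log_gamma: float) -> float:
        gamma = math.exp(log_gamma)
        w = gamma * s + 1.0
        wi = 1.0 / w
        a = ct.T @ (ct * wi[:, None])
        b = ct.T @ (yt * wi)
        beta = np.linalg.solve(a, b)
        r = yt - ct @ beta
        rss = float(r @ (r * wi))
        sig_e = rss / (n - p)
        ll = -0.5 * (
            (n - p) * math.log(2 * math.pi * sig_e)
            + (n - p)
            + float(np.sum(np.log(w)))
            + np.linalg.slogdet(a)[1]
            - ctc_logdet
        )
        return -ll

    grid = np.linspace(-12.0, 12.0, 49)
    vals = [neg_reml(lg) for lg in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(
            f"REML did not converge (trace: grid minimum {grid[i]:.2f} -> "
            f"{vals[i]:.4f}, refine status {res.message})"
        )
    log_gamma = float(res.x)
    # collapse to the OLS boundary when the optimum sits on the grid edge
    if neg_reml(-12.0) <= res.fun:
        log_gamma = -math.inf
    gamma = math.exp(log_gamma) if np.isfinite(log_gamma) else 0.0
    w = gamma * s + 1.0
    wi = 1.0 / w
    a = ct.T @ (ct * wi[:, None])
    beta = np.linalg.solve(a, ct.T @ (yt * wi))
    r = yt - ct @ beta
    sig_e = float(r @ (r * wi)) / (n - p)
    return gamma, gamma * sig_e, sig_e


def mlm_scan(
    genotypes: GenotypeMatrix,
    trait: np.ndarray | pd.Series,
    kinship: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    gamma: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """EMMAX-style kinship mixed-model scan.

    The null model ``y = X b + g + e`` with ``g ~ N(0, sigma_g^2 K)`` is
    fitted once by REML through the spectral decomposition of ``K``; each
    SNP is then tested by generalized least squares with the variance
    ratio held fixed (Wald t test).  ``gamma`` forces the ratio
    ``sigma_g^2/sigma_e^2`` (0 collapses the scan to plain OLS).

    Returns the per-SNP table and a dict of variance components.
    """
    y = np.asarray(trait, dtype=float)
    n = len(y)
    k = np.asarray(kinship, dtype=float)
    if k.shape != (n, n):
        raise ValueError("kinship shape does not match the trait length")
    if not np.allclose(k, k.T, atol=1e-8):
        raise ValueError("kinship matrix is not symmetric")
    s, u = np.linalg.eigh(k)
    tol = 1e-8 * max(1.0, float(np.max(np.abs(s))))
    if np.min(s) < -tol:
        raise ValueError(
            f"kinship matrix is not PSD (min eigenvalue {np.min(s):.3e})"
        )
    s = np.clip(s, 0.0, None)
    x = _design(n, covariates)
    yt = u.T @ y
    ct = u.T @ x
    if gamma is None:
        gamma, sig_g, sig_e = _reml_gamma(s, yt, ct)
    else:
        w = gamma * s + 1.0
        wi = 1.0 / w
        a = ct.T @ (ct * wi[:, None])
        beta = np.linalg.solve(a, ct.T @ (yt * wi))
        r = yt - ct @ beta
        sig_e = float(r @ (r * wi)) / (n - x.shape[1])
        sig_g = gamma * sig_e
    # whitening transform: rows scaled by 1/sqrt(gamma*s + 1)
    wh = 1.0 / np.sqrt(gamma * s + 1.0)
    ys = wh * yt
    xs = ct * wh[:, None]
    g = genotypes.dosage
    m = g.shape[1]
    beta_a = np.full(m, np.nan)
    se_a = np.full(m, np.nan)
    p_a = np.full(m, np.nan)
    complete = ~np.isnan(g).any(axis=0)
    if complete.any():
        gs = (u.T @ g[:, complete]) * wh[:, None]
        b, sse, pv = _ols_block(gs, ys, xs)
        beta_a[complete], se_a[complete], p_a[complete] = b, sse, pv
    v_full = gamma * k + np.eye(n)
    for j in np.flatnonzero(~complete):
        keep = ~np.isnan(g[:, j])
        nk = int(keep.sum())
        if nk <= x.shape[1] + 1:
            continue
        vi = v_full[np.ix_(keep, keep)]
        cf = linalg.cho_factor(vi)
        xg = np.column_stack([x[keep], g[keep, j]])
        vx = linalg.cho_solve(cf, xg)
        vy = linalg.cho_solve(cf, y[keep])
        xtvx = xg.T @ vx
        xtvy = xg.T @ vy
        bhat = np.linalg.solve(xtvx, xtvy)
        r = y[keep] - xg @ bhat
        df = nk - xg.shape[1]
        sig = float(r @ linalg.cho_solve(cf, r)) / df
        cov = sig * np.linalg.inv(xtvx)
        tval = bhat[-1] / math.sqrt(cov[-1, -1])
        beta_a[j] = bhat[-1]
        se_a[j] = math.sqrt(cov[-1, -1])
        p_a[j] = 2.0 * stats.t.sf(abs(tval), df)
    table = pd.DataFrame(
        {
            "snp": genotypes.snp_ids,
            "chrom": genotypes.chrom,
            "pos": genotypes.pos,
            "beta": beta_a,
            "se": se_a,
            "p": p_a,
        }
    )
    vc = {"gamma": gamma, "sigma_g2": sig_g, "sigma_e2": sig_e}
    return table, vc


def genomic_inflation(p_values: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Genomic-control inflation factor and QQ table.

    lambda_GC is the median chi-square(1 df) quantile of the observed
    p-values divided by the null median (~0.455).  The QQ table pairs
    expected against observed -log10 p for plotting.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) < 100:
        raise ValueError("need at least 100 p-values for inflation diagnostics")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    lam = float(np.median(chi) / _CHI2_MEDIAN)
    obs = np.sort(p)
    n = len(obs)
    expected = (np.arange(1, n + 1) - 0.5) / n
    qq = pd.DataFrame(
        {
            "expected_neglog10p": -np.log10(expected),
            "observed_neglog10p": -np.log10(obs),
        }
    )
    return lam, qq


@dataclass
class Peak:
    """A dual-model association peak."""

    chrom: int
    start: int
    end: int
    lead_snp: str
    lead_p_glm: float
    lead_p_mlm: float
    n_markers: int
    trait: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("peak start must not exceed end")


def call_peaks(
    table: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    merge_distance: int = DEFAULT_MERGE_DISTANCE,
    trait: str | None = None,
) -> list[Peak]:
    """Call peaks from a merged scan table with ``p_glm`` and ``p_mlm``.

    Candidate markers are significant (p < threshold) in both models;
    candidates within ``merge_distance`` bp on one chromosome cluster
    into one peak spanning first to last candidate.  The lead SNP is the
    smallest GLM p-value in the cluster.
    """
    cand = table[(table["p_glm"] < threshold) & (table["p_mlm"] < threshold)]
    cand = cand.sort_values(["chrom", "pos"])
    peaks: list[Peak] = []
    for chrom, grp in cand.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > merge_distance)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, len(pos) - 1]
        for a, b in zip(starts, ends):
            cluster = grp.iloc[a:b + 1]
            lead = cluster.loc[cluster["p_glm"].idxmin()]
            peaks.append(
                Peak(
                    chrom=int(chrom),
                    start=int(cluster["pos"].min()),
                    end=int(cluster["pos"].max()),
                    lead_snp=str(lead["snp"]),
                    lead_p_glm=float(lead["p_glm"]),
                    lead_p_mlm=float(lead["p_mlm"]),
                    n_markers=len(cluster),
                    trait=trait,
                )
            )
    return peaks


def annotate_peaks(peaks: list[Peak], gff3_path: str) -> dict[str, list[dict]]:
    """Genes overlapping each peak interval by >= 1 bp (1-based inclusive).

    Returns a mapping lead-SNP id -> list of gene records (gene_id,
    chrom, start, end).  Raises when a peak chromosome has no counterpart
    among the GFF3 seqids.
    """
    import gffutils

    db = gffutils.create_db(
        gff3_path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = [
        {
            "gene_id": f.id,
            "chrom": f.seqid.removeprefix("chr").removeprefix("Chr"),
            "start": f.start,
            "end": f.end,
        }
        for f in db.features_of_type("gene")
    ]
    seqids = {g["chrom"] for g in genes}
    unmatched = sorted({str(p.chrom) for p in peaks} - seqids)
    if unmatched:
        raise ValueError(
            f"peak chromosomes {unmatched} not present in GFF3 seqids {sorted(seqids)}"
        )
    out: dict[str, list[dict]] = {}
    for p in peaks:
        out[p.lead_snp] = [
            g
            for g in genes
            if g["chrom"] == str(p.chrom) and g["start"] <= p.end and g["end"] >= p.start
        ]
    return out


@dataclass
class AssociationResults:
    """Dual-model scan results for one trait."""

    trait: str
    table: pd.DataFrame  # snp, chrom, pos, beta/se/p per model
    lambda_glm: float
    lambda_mlm: float
    qq_glm: pd.DataFrame
    qq_mlm: pd.DataFrame
    variance_components: dict
    covariate_names: list = field(default_factory=list)
    threshold: float = DEFAULT_THRESHOLD

    def call_peaks(
        self,
        threshold: float | None = None,
        merge_distance: int = DEFAULT_MERGE_DISTANCE,
    ) -> list[Peak]:
        return call_peaks(
            self.table,
            threshold=self.threshold if threshold is None else threshold,
            merge_distance=merge_distance,
            trait=self.trait,
        )

    def summary(self) -> str:
        n_sig = int(
            ((self.table["p_glm"] < self.threshold)
             & (self.table["p_mlm"] < self.threshold)).sum()
        )
        vc = self.variance_components
        return (
            f"Association scan: {self.trait}\n"
            + "-" * 44 + "\n"
            f"SNPs tested: {len(self.table)}   covariates: {self.covariate_names}\n"
            f"lambda_GC  GLM+PCs {self.lambda_glm:.3f}   MLM {self.lambda_mlm:.3f}\n"
            f"variance components: sigma_g2 {vc['sigma_g2']:.4g}, "
            f"sigma_e2 {vc['sigma_e2']:.4g} (gamma {vc['gamma']:.4g})\n"
            f"dual-model significant markers at P < {self.threshold:g}: {n_sig}"
        )


class AssociationStudy:
    """Dual-model genome-wide association study of one quantitative trait.

    Builds the design shared by both scans: the GLM uses the top
    ``n_pcs`` principal components plus any extra covariates (harvest
    moisture content for the longevity traits); the MLM uses the kinship
    matrix plus the extra covariates.

    Parameters
    ----------
    genotypes : GenotypeMatrix
        Filtered panel (use :func:`filter_snps` first, or pass
        ``prefilter=True``).
    trait : array or Series aligned with the accession order.
    covariates : optional DataFrame of extra fixed covariates.
    n_pcs : PCs used for structure correction in the GLM.
    kinship : precomputed matrix; derived from the genotypes when absent.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        trait,
        trait_name: str = "trait",
        covariates: pd.DataFrame | None = None,
        n_pcs: int = 5,
        kinship: np.ndarray | None = None,
        prefilter: bool = False,
        max_missing: float = 0.20,
        min_maf: float = 0.05,
    ) -> None:
        if prefilter:
            genotypes = filter_snps(genotypes, max_missing, min_maf)
        self.genotypes = genotypes
        self.trait = np.asarray(trait, dtype=float)
        self.trait_name = trait_name
        self.covariates = covariates
        self.n_pcs = n_pcs
        self.kinship = (
            compute_kinship(genotypes) if kinship is None else np.asarray(kinship)
        )

    def fit(self, gamma: float | None = None) -> AssociationResults:
        pcs = compute_pcs(self.genotypes, self.n_pcs)
        pc_df = pd.DataFrame(
            pcs, columns=[f"PC{i+1}" for i in range(self.n_pcs)]
        )
        if self.covariates is not None:
            cov = self.covariates.reset_index(drop=True)
            glm_cov = pd.concat([pc_df, cov], axis=1)
            mlm_cov = cov
            names = list(cov.columns)
        else:
            glm_cov, mlm_cov, names = pc_df, None, []
        glm = glm_scan(self.genotypes, self.trait, glm_cov)
        mlm, vc = mlm_scan(
            self.genotypes, self.trait, self.kinship, mlm_cov, gamma=gamma
        )
        table = glm.rename(columns={"beta": "beta_glm", "se": "se_glm", "p": "p_glm"})
        table["beta_mlm"] = mlm["beta"]
        table["se_mlm"] = mlm["se"]
        table["p_mlm"] = mlm["p"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lam_glm, qq_glm = genomic_inflation(table["p_glm"].to_numpy())
            lam_mlm, qq_mlm = genomic_inflation(table["p_mlm"].to_numpy())
        return AssociationResults(
            trait=self.trait_name,
            table=table,
            lambda_glm=lam_glm,
            lambda_mlm=lam_mlm,
            qq_glm=qq_glm,
            qq_mlm=qq_mlm,
            variance_components=vc,
            covariate_names=[f"PC1..PC{self.n_pcs}"] + names,
        )
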