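"""Descriptive and relational statistics for seed-lot trait tables.

Covers the routine reporting around the longevity analysis: trait
summaries (range, mean, sd, CV), the sequential-harvest regressions of
proportional p50 change on harvest-moisture change, pairwise Pearson
correlations with significance stars, and paired t-tests between harvest
maturities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "descriptive_table",
    "correlation_matrix",
    "maturity_paired_tests",
    "sequential_harvest_regression",
    "HarvestRegression",
]


def descriptive_table(data: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Range, mean, sample sd and coefficient of variation per column.

    CV = 100 * sd / mean is sign-preserving, so an all-negative trait
    (the survival-curve slope) reports a negative CV.
    """
    if isinstance(data, pd.Series):
        data = data.to_frame()
    rows = []
    for col in data.columns:
        x = data[col].dropna().to_numpy(dtype=float)
        if len(x) < 2:
            raise ValueError(f"column {col!r} needs at least 2 values")
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        rows.append(
            {
                "trait": col,
                "n": len(x),
                "min": float(np.min(x)),
                "max": float(np.max(x)),
                "mean": mean,
                "sd": sd,
                "cv": 100.0 * sd / mean,
            }
        )
    return pd.DataFrame(rows)


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""


def correlation_matrix(
    data: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p-values and stars.

    Uses pairwise-complete observations (assay traits may cover only a
    subset of accessions).  Constant columns yield an undefined (NaN)
    correlation.  Returns (r, p, stars) DataFrames; the diagonal is
    r = 1, p = 0.
    """
    cols = list(data.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                r[i, i], p[i, i] = 1.0, 0.0
                continue
            pair = data[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"fewer than 3 complete pairs for {cols[i]!r} vs {cols[j]!r}"
                )
            x = pair.iloc[:, 0].to_numpy(dtype=float)
            y = pair.iloc[:, 1].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue  # undefined, stays NaN
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    stars = p_df.map(_stars)
    return r_df, p_df, stars


def maturity_paired_tests(
    lots: pd.DataFrame,
    value_cols: tuple[str, ...] = ("harvest_mc", "hundred_seed_weight"),
    maturity_col: str = "maturity",
    accession_col: str = "accession",
    pairs: tuple[tuple[int, int], ...] = ((31, 38), (38, 45)),
) -> pd.DataFrame:
    """Paired t-tests between sequential harvest maturities.

    Pairs accessions present at both maturities; df = n - 1, two-sided p.
    Degenerate cases (zero variance of the differences) follow the
    convention: all differences zero -> t = 0, p = 1; constant non-zero
    differences -> t = +/-inf, p = 0 (flagged in the ``degenerate``
    column).
    """
    rows = []
    for early, late in pairs:
        a = lots[lots[maturity_col] == early].set_index(accession_col)
        b = lots[lots[maturity_col] == late].set_index(accession_col)
        common = a.index.intersection(b.index)
        for col in value_cols:
            if col not in lots.columns:
                continue
            d = (b.loc[common, col] - a.loc[common, col]).dropna()
            n = len(d)
            if n < 2:
                raise ValueError(
                    f"need >= 2 paired accessions for {col} {early} vs {late}"
                )
            diffs = d.to_numpy(dtype=float)
            degenerate = np.std(diffs, ddof=1) == 0
            if degenerate:
                if np.allclose(diffs, 0):
                    t, p = 0.0, 1.0
                else:
                    t = np.inf * np.sign(diffs.mean())
                    p = 0.0
            else:
                res = stats.ttest_rel(
                    b.loc[common, col].astype(float), a.loc[common, col].astype(float)
                )
                t, p = float(res.statistic), float(res.pvalue)
            rows.append(
                {
                    "variable": col,
                    "pair": f"{early}v{late}",
                    "n": n,
                    "mean_diff": float(diffs.mean()),
                    "t": t,
                    "df": n - 1,
                    "p": p,
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class HarvestRegression:
    """Sequential-harvest moisture/longevity regression results."""

    points: pd.DataFrame  # accession, pair, delta_mc, prop_delta_p50, branch
    dried: dict | None    # slope, intercept, r2, p, n
    wetted: dict | None

    def summary(self) -> str:
        def fmt(name: str, fit: dict | None) -> str:
            if fit is None:
                return f"{name}: no points"
            return (
                f"{name}: slope {fit['slope']:+.4f} per %MC, intercept "
                f"{fit['intercept']:+.4f}, r2 {fit['r2']:.3f}, "
                f"P {fit['p']:.3g} (n={fit['n']})"
            )
        return (
            "Sequential-harvest regression of proportional p50 change on dMC\n"
            + "-" * 44 + "\n"
            + fmt("dried (dMC < 0)", self.dried) + "\n"
            + fmt("wetted (dMC > 0)", self.wetted)
        )


def _branch_fit(sub: pd.DataFrame) -> dict | None:
    if len(sub) < 3:
        return None
    res = stats.linregress(sub["delta_mc"], sub["prop_delta_p50"])
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "se_slope": float(res.stderr),
        "n": len(sub),
    }


def sequential_harvest_regression(
    lots: pd.DataFrame,
    maturity_col: str = "maturity",
    accession_col: str = "accession",
    mc_col: str = "harvest_mc",
    p50_col: str = "p50",
    pairs: tuple[tuple[int, int], ...] = ((31, 38), (38, 45)),
) -> HarvestRegression:
    """Proportional p50 change against harvest-MC change between harvests.

    For each sequential maturity pair: delta MC = later - earlier MC, and
    the p50 change as a proportion of the earlier harvest's p50.  Points
    split by the sign of delta MC into dried and wetted branches, each
    fitted by ordinary least squares.  Pairs with non-positive earlier
    p50 are excluded with a warning.
    """
    rows = []
    for early, late in pairs:
        a = lots[lots[maturity_col] == early].set_index(accession_col)
        b = lots[lots[maturity_col] == late].set_index(accession_col)
        common = a.index.intersection(b.index)
        for acc in common:
            p50_early = float(a.loc[acc, p50_col])
            p50_late = float(b.loc[acc, p50_col])
            if not np.isfinite(p50_early) or not np.isfinite(p50_late):
                continue
            if p50_early <= 0:
                warnings.warn(
                    f"pair {acc} {early}->{late} excluded: earlier p50 <= 0",
                    stacklevel=2,
                )
                continue
            dmc = float(b.loc[acc, mc_col]) - float(a.loc[acc, mc_col])
            prop = (p50_late - p50_early) / p50_early
            if dmc == 0:
                continue
            rows.append(
                {
                    "accession": acc,
                    "pair": f"{early}v{late}",
                    "delta_mc": dmc,
                    "prop_delta_p50": prop,
                    "branch": "dried" if dmc < 0 else "wetted",
                }
            )
    points = pd.DataFrame(
        rows, columns=["accession", "pair", "delta_mc", "prop_delta_p50", "branch"]
    )
    dried = _branch_fit(points[points["branch"] == "dried"])
    wetted = _branch_fit(points[points["branch"] == "wetted"])
    return HarvestRegression(points=points, dried=dried, wetted=wetted)
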