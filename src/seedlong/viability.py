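"""Probit survival modelling of germination time-courses.

The viability equation describes the loss of seed viability in storage as
a straight line on the probit scale:

    v(t) = Ki - t / sigma

where ``v`` is viability in normal equivalent deviates (NED), ``Ki`` the
initial viability of the seed lot, and ``sigma`` the time (days) for
viability to fall by one NED, so the survival-line slope is ``-1/sigma``.
The storage time at which viability reaches 50 % (0 NED) is
``p50 = Ki * sigma``.

Fits maximise the binomial likelihood of germinated counts with success
probability ``Phi(Ki + slope * t)``.  A common-slope model constrains the
survival lines of several seed lots (harvest maturities) of one accession
to one shared slope and judges the constraint by an approximate F-test on
the residual-deviance increase.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SurvivalFit",
    "CommonSlopeFit",
    "ProbitSurvival",
    "CommonSlopeProbit",
    "truncate_to_decline",
    "fit_probit_survival",
    "fit_common_slope",
    "select_best_lot",
]

#: status codes a single-lot fit can carry
STATUS_OK = "ok"
STATUS_NO_DECLINE = "no-decline"
STATUS_UNFITTABLE = "unfittable"
STATUS_SEPARATION = "separation"
STATUS_NON_DECLINING = "non-declining"


@dataclass
class SurvivalFit:
    """Fitted viability-equation parameters for one seed lot.

    Only ``slope`` is required; ``sigma = -1/slope`` and ``p50 = Ki*sigma``
    are derived when not given, so a fit can also be constructed directly
    from a known slope.
    """

    slope: float
    ki: float = math.nan
    sigma: float = None  # type: ignore[assignment]
    p50: float = None  # type: ignore[assignment]
    se_ki: float = math.nan
    se_slope: float = math.nan
    se_p50: float = math.nan
    residual_deviance: float = math.nan
    df: int = 0
    n_points_used: int = 0
    truncated_from: float | None = None
    converged: bool = True
    status: str = STATUS_OK
    accession: str | None = None
    maturity: int | None = None

    def __post_init__(self) -> None:
        if self.sigma is None:
            self.sigma = -1.0 / self.slope if self.slope != 0 else math.nan
        if self.p50 is None:
            self.p50 = self.ki * self.sigma

    def p50_confint(self, alpha: float = 0.05) -> tuple[float, float]:
        """Delta-method (Wald) confidence interval for p50."""
        z = stats.norm.ppf(1 - alpha / 2)
        return (self.p50 - z * self.se_p50, self.p50 + z * self.se_p50)

    def summary(self) -> str:
        lines = [
            "Probit survival fit (viability equation)",
            "-" * 44,
            f"accession: {self.accession}    maturity (DAH): {self.maturity}",
            f"Ki     {self.ki:10.4f} NED   (se {self.se_ki:.4f})",
            f"slope  {self.slope:10.4f} /d    (se {self.se_slope:.4f})",
            f"sigma  {self.sigma:10.4f} d",
            f"p50    {self.p50:10.4f} d     (se {self.se_p50:.4f})",
            f"residual deviance {self.residual_deviance:.4f} on {self.df} df "
            f"({self.n_points_used} points, truncated from day "
            f"{self.truncated_from})",
            f"status: {self.status}   converged: {self.converged}",
        ]
        return "\n".join(lines)


@dataclass
class CommonSlopeFit:
    """Joint fit of several lots with lot-specific Ki and one shared slope."""

    labels: list
    ki: np.ndarray
    shared_slope: float
    p50: np.ndarray
    se_ki: np.ndarray
    se_slope: float
    deviance_constrained: float
    deviance_unconstrained: float
    df_constrained: int
    df_unconstrained: int
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    constraint_accepted: bool
    excluded: list = field(default_factory=list)
    lot_fits: dict = field(default_factory=dict)

    @property
    def shared_sigma(self) -> float:
        return -1.0 / self.shared_slope

    def summary(self) -> str:
        rows = "\n".join(
            f"  lot {lab}: Ki {k:.4f} (se {s:.4f}), p50 {p:.4f} d"
            for lab, k, s, p in zip(self.labels, self.ki, self.se_ki, self.p50)
        )
        verdict = "accepted" if self.constraint_accepted else "rejected"
        return (
            "Common-slope probit fit\n"
            + "-" * 44 + "\n"
            f"shared slope {self.shared_slope:.4f} /d (se {self.se_slope:.4f}), "
            f"sigma {self.shared_sigma:.4f} d\n"
            f"{rows}\n"
            f"deviance constrained {self.deviance_constrained:.4f} "
            f"(df {self.df_constrained}) vs unconstrained "
            f"{self.deviance_unconstrained:.4f} (df {self.df_unconstrained})\n"
            f"approx F({self.df_num},{self.df_den}) = {self.f_statistic:.4f}, "
            f"P = {self.p_value:.4g} -> constraint {verdict}"
        )


def truncate_to_decline(
    storage_days: Sequence[float],
    n_sown: Sequence[int],
    n_germinated: Sequence[int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float | None, str]:
    """Restrict a time-course to the period of declining viability.

    Seed lots commonly show an initial plateau (or apparent improvement)
    before viability declines; only the declining phase carries
    information about the survival line.  The rule drops leading time
    points up to, but keeping, the last time at which the observed
    germination proportion attains its running maximum.

    Returns ``(days, sown, germinated, truncated_from, status)`` where
    ``status`` is ``'ok'``, ``'no-decline'`` (all proportions equal) or
    ``'unfittable'`` (fewer than 3 points retained).
    """
    t = np.asarray(storage_days, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    if np.any(t < 0):
        raise ValueError("storage times must be non-negative")
    order = np.argsort(t)
    t = t[order]
    sown = np.asarray(n_sown, dtype=int)[order]
    germ = np.asarray(n_germinated, dtype=int)[order]
    if np.any(germ > sown) or np.any(germ < 0):
        raise ValueError("counts must satisfy 0 <= germinated <= sown")
    prop = germ / sown
    if np.all(prop == prop[0]):
        return t, sown, germ, None, STATUS_NO_DECLINE
    running_max = np.maximum.accumulate(prop)
    start = int(np.max(np.flatnonzero(prop >= running_max)))
    t, sown, germ = t[start:], sown[start:], germ[start:]
    status = STATUS_OK if len(t) >= 3 else STATUS_UNFITTABLE
    return t, sown, germ, float(t[0]), status


class ProbitSurvival:
    """Binomial probit model for a single seed lot's survival curve.

    Parameters
    ----------
    storage_days, n_sown, n_germinated : sequences
        One germination test per storage time (replicate dishes pooled).
    truncate : bool
        Apply the declining-phase truncation rule before fitting.
    accession, maturity : optional labels carried into the result.
    """

    def __init__(
        self,
        storage_days: Sequence[float],
        n_sown: Sequence[int],
        n_germinated: Sequence[int],
        truncate: bool = True,
        accession: str | None = None,
        maturity: int | None = None,
    ) -> None:
        self.storage_days = np.asarray(storage_days, dtype=float)
        self.n_sown = np.asarray(n_sown, dtype=int)
        self.n_germinated = np.asarray(n_germinated, dtype=int)
        self.truncate = truncate
        self.accession = accession
        self.maturity = maturity

    @classmethod
    def from_records(cls, records: pd.DataFrame, **kwargs) -> "ProbitSurvival":
        """Build from a tidy table with storage_day / n_sown / n_germ columns."""
        return cls(
            records["storage_day"].to_numpy(),
            records["n_sown"].to_numpy(),
            records["n_germ"].to_numpy(),
            **kwargs,
        )

    def _failed(self, status: str, truncated_from=None, n_used=0) -> SurvivalFit:
        return SurvivalFit(
            slope=math.nan,
            sigma=math.nan,
            p50=math.nan,
            n_points_used=n_used,
            truncated_from=truncated_from,
            converged=False,
            status=status,
            accession=self.accession,
            maturity=self.maturity,
        )

    def fit(self) -> SurvivalFit:
        if self.truncate:
            t, sown, germ, trunc_from, status = truncate_to_decline(
                self.storage_days, self.n_sown, self.n_germinated
            )
            if status != STATUS_OK:
                return self._failed(status, trunc_from, len(t))
        else:
            t, sown, germ = self.storage_days, self.n_sown, self.n_germinated
            trunc_from = float(np.min(t)) if len(t) else None
        # complete separation: every observed proportion is 0 or 1
        if not np.any((germ > 0) & (germ < sown)):
            return self._failed(STATUS_SEPARATION, trunc_from, len(t))
        x = sm.add_constant(t)
        endog = np.column_stack([germ, sown - germ])
        family = sm.families.Binomial(link=sm.families.links.Probit())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(endog, x, family=family).fit(tol=1e-10, maxiter=200)
            except Exception:
                return self._failed(STATUS_SEPARATION, trunc_from, len(t))
        a, b = res.params
        cov = np.asarray(res.cov_params())
        se_a, se_b = np.sqrt(np.diag(cov))
        if not np.all(np.isfinite([a, b, se_a, se_b])):
            return self._failed(STATUS_SEPARATION, trunc_from, len(t))
        if b >= 0:
            fit = self._failed(STATUS_NON_DECLINING, trunc_from, len(t))
            fit.ki, fit.slope = float(a), float(b)
            return fit
        sigma = -1.0 / b
        p50 = -a / b
        # delta method: p50 = -a/b, gradient (-1/b, a/b^2)
        grad = np.array([-1.0 / b, a / b**2])
        se_p50 = float(np.sqrt(grad @ cov @ grad))
        return SurvivalFit(
            slope=float(b),
            ki=float(a),
            sigma=float(sigma),
            p50=float(p50),
            se_ki=float(se_a),
            se_slope=float(se_b),
            se_p50=se_p50,
            residual_deviance=float(res.deviance),
            df=len(t) - 2,
            n_points_used=len(t),
            truncated_from=trunc_from,
            converged=bool(res.converged),
            status=STATUS_OK,
            accession=self.accession,
            maturity=self.maturity,
        )


def fit_probit_survival(
    storage_days: Sequence[float],
    n_sown: Sequence[int],
    n_germinated: Sequence[int],
    **kwargs,
) -> SurvivalFit:
    """Functional wrapper around :class:`ProbitSurvival`."""
    return ProbitSurvival(storage_days, n_sown, n_germinated, **kwargs).fit()


class CommonSlopeProbit:
    """Joint probit model for several lots with a shared survival slope.

    ``lots`` maps a label (harvest maturity) to a ``(storage_days, n_sown,
    n_germinated)`` triple.  ``fit()`` fits each lot unconstrained, then a
    joint model with lot-specific intercepts and one slope, and compares
    them by the approximate deviance-ratio F-test:

        F = [(D_c - D_u)/ddf] / [D_u/df_u]

    with D_c/D_u the constrained/unconstrained residual deviances.  The
    unconstrained deviance supplies the denominator scale (recorded in the
    result so the convention is explicit).  The constraint is accepted
    when P > 0.05.
    """

    alpha = 0.05

    def __init__(self, lots: Mapping, truncate: bool = True) -> None:
        if len(lots) < 2:
            raise ValueError("need at least 2 lots for a common-slope fit")
        self.lots = dict(lots)
        self.truncate = truncate

    def fit(self) -> CommonSlopeFit:
        lot_fits: dict = {}
        data: dict = {}
        excluded: list = []
        for label, (t, sown, germ) in self.lots.items():
            model = ProbitSurvival(t, sown, germ, truncate=self.truncate)
            single = model.fit()
            if single.status != STATUS_OK:
                excluded.append((label, single.status))
                lot_fits[label] = single
                continue
            td, sd, gd, _, _ = (
                truncate_to_decline(t, sown, germ)
                if self.truncate
                else (np.asarray(t, float), np.asarray(sown), np.asarray(germ),
                      None, STATUS_OK)
            )
            data[label] = (td, sd, gd)
            lot_fits[label] = single
        if len(data) < 2:
            raise ValueError(
                f"fewer than 2 fittable lots (excluded: {excluded})"
            )
        labels = list(data)
        t_all = np.concatenate([data[l][0] for l in labels])
        sown_all = np.concatenate([data[l][1] for l in labels])
        germ_all = np.concatenate([data[l][2] for l in labels])
        n_lots = len(labels)
        dummies = np.zeros((len(t_all), n_lots))
        offset = 0
        for j, l in enumerate(labels):
            k = len(data[l][0])
            dummies[offset:offset + k, j] = 1.0
            offset += k
        x = np.column_stack([dummies, t_all])
        endog = np.column_stack([germ_all, sown_all - germ_all])
        family = sm.families.Binomial(link=sm.families.links.Probit())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(endog, x, family=family).fit(tol=1e-10, maxiter=200)
        ki = np.asarray(res.params[:n_lots])
        slope = float(res.params[n_lots])
        cov = np.asarray(res.cov_params())
        se_ki = np.sqrt(np.diag(cov)[:n_lots])
        se_slope = float(np.sqrt(cov[n_lots, n_lots]))
        d_c = float(res.deviance)
        df_c = len(t_all) - (n_lots + 1)
        d_u = float(sum(lot_fits[l].residual_deviance for l in labels))
        df_u = int(sum(lot_fits[l].df for l in labels))
        df_num = n_lots - 1
        # nesting guard: rounding can push the difference fractionally negative
        diff = max(d_c - d_u, 0.0)
        if df_u > 0:
            # classical probit-analysis heterogeneity factor: scale by the
            # unconstrained deviance/df only when it signals overdispersion
            # (> 1); binomial sampling with sparse tail cells biases the
            # raw ratio below 1, which would make the test anti-conservative
            h = max(d_u / df_u, 1.0)
            f_stat = (diff / df_num) / h
            p_value = float(stats.f.sf(f_stat, df_num, df_u))
        else:
            f_stat, p_value = math.inf, 0.0
        return CommonSlopeFit(
            labels=labels,
            ki=ki,
            shared_slope=slope,
            p50=-ki / slope,
            se_ki=se_ki,
            se_slope=se_slope,
            deviance_constrained=d_c,
            deviance_unconstrained=d_u,
            df_constrained=df_c,
            df_unconstrained=df_u,
            f_statistic=float(f_stat),
            df_num=df_num,
            df_den=df_u,
            p_value=p_value,
            constraint_accepted=p_value > self.alpha,
            excluded=excluded,
            lot_fits=lot_fits,
        )


def fit_common_slope(lots: Mapping, truncate: bool = True) -> CommonSlopeFit:
    """Functional wrapper around :class:`CommonSlopeProbit`."""
    return CommonSlopeProbit(lots, truncate=truncate).fit()


def select_best_lot(fits: Mapping[int, SurvivalFit]) -> tuple[int, SurvivalFit]:
    """Pick the harvest maturity with maximum p50 among converged fits.

    Ties break toward the earlier maturity.  Warns when some maturities
    had to be ignored because their fits did not converge.
    """
    usable = {m: f for m, f in fits.items() if f.status == STATUS_OK}
    if not usable:
        raise ValueError("no converged fits to select from")
    if len(usable) < len(fits):
        skipped = sorted(set(fits) - set(usable))
        warnings.warn(
            f"maturities {skipped} skipped (fit did not converge)",
            stacklevel=2,
        )
    best = min(usable.items(), key=lambda kv: (-kv[1].p50, kv[0]))
    return best
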