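"""Poisson-regression gap estimation and Monte Carlo interval machinery.

A Poisson GLM of recruited case count on the natural log of county
population, fitted to reference counties only, supplies the expected case
count of every county.  For target counties the positive part of
(expected - recruited) is the estimated number of unrecruited cases.
Uncertainty is propagated by sampling the linear predictor on the log scale
and exponentiating, which keeps every sampled expected count positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .records import STRATA, CountyStratumRecord

__all__ = [
    "GapEstimationError",
    "PoissonFit",
    "CountyEstimate",
    "IntervalEstimate",
    "fit_poisson",
    "predict_expected",
    "monte_carlo_interval",
    "round_half_up",
    "summarize_strata",
    "summarize_results",
]


class GapEstimationError(ValueError):
    """Gap estimation could not proceed on this input."""


@dataclass(frozen=True)
class PoissonFit:
    """Fitted Poisson regression ``log mu = b0 + b1 * ln(population)``."""

    b0: float
    b1: float
    se_b0: float
    se_b1: float
    cov_b0b1: float
    null_deviance: float
    df_null: int
    residual_deviance: float
    df_resid: int
    aic: float
    n_reference: int
    intercept: bool = True


@dataclass(frozen=True)
class CountyEstimate:
    """Model-based expected count and unrecruited-case estimate for one county."""

    county_id: str
    stratum: str
    is_target: bool
    recruited: int
    ln_pop: float
    eta: float  # linear (log-scale) prediction
    link_se: float
    mu: float  # expected case count, exp(eta)
    unrecruited: float  # max(mu - recruited, 0) for targets, else 0


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with empirical 95% Monte Carlo percentile interval."""

    point: float
    lower: float
    upper: float
    n_draws: int
    seed: int

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise GapEstimationError(
                f"interval lower {self.lower} > upper {self.upper}"
            )


def fit_poisson(
    reference: Sequence[CountyStratumRecord], intercept: bool = True
) -> PoissonFit:
    """Fit the reference-county Poisson model by IRLS maximum likelihood."""
    if len(reference) < 3:
        raise GapEstimationError(
            f"need at least 3 reference counties, got {len(reference)}"
        )
    counts = np.array([r.recruited_cases for r in reference], dtype=float)
    lnpop = np.array([math.log(r.population) for r in reference])
    if np.ptp(lnpop) == 0:
        raise GapEstimationError(
            "all reference populations equal: degenerate design matrix"
        )
    X = sm.add_constant(lnpop) if intercept else lnpop[:, None]
    model = sm.GLM(counts, X, family=sm.families.Poisson())
    res = model.fit(maxiter=200, tol=1e-10)
    if not res.converged:
        raise GapEstimationError("Poisson IRLS did not converge")
    cov = np.asarray(res.cov_params())
    if intercept:
        b0, b1 = float(res.params[0]), float(res.params[1])
        se_b0, se_b1 = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
        cov_b0b1 = float(cov[0, 1])
    else:
        b0, se_b0, cov_b0b1 = 0.0, 0.0, 0.0
        b1, se_b1 = float(res.params[0]), float(np.sqrt(cov[0, 0]))
    return PoissonFit(
        b0=b0,
        b1=b1,
        se_b0=se_b0,
        se_b1=se_b1,
        cov_b0b1=cov_b0b1,
        null_deviance=float(res.null_deviance),
        df_null=len(reference) - 1,
        residual_deviance=float(res.deviance),
        df_resid=int(res.df_resid),
        aic=float(res.aic),
        n_reference=len(reference),
        intercept=intercept,
    )


def predict_expected(
    fit: PoissonFit,
    records: Sequence[CountyStratumRecord],
    target_ids: Iterable[str],
) -> list[CountyEstimate]:
    """Expected counts, link-scale standard errors, and unrecruited estimates.

    ``link_se`` is ``sqrt(x' V x)`` with ``x = (1, ln population)`` and ``V``
    the coefficient covariance; unrecruited estimates are nonzero only for
    counties in ``target_ids``.
    """
    targets = set(target_ids)
    out: list[CountyEstimate] = []
    for r in records:
        x = math.log(r.population)
        eta = fit.b0 + fit.b1 * x
        var = fit.se_b1**2 * x * x
        if fit.intercept:
            var += fit.se_b0**2 + 2.0 * fit.cov_b0b1 * x
        link_se = math.sqrt(max(var, 0.0))
        mu = math.exp(eta)
        is_target = r.county_id in targets
        unrec = max(mu - r.recruited_cases, 0.0) if is_target else 0.0
        out.append(
            CountyEstimate(
                county_id=r.county_id,
                stratum=r.stratum,
                is_target=is_target,
                recruited=r.recruited_cases,
                ln_pop=x,
                eta=eta,
                link_se=link_se,
                mu=mu,
                unrecruited=unrec,
            )
        )
    return out


def _target_draws(
    estimates: Sequence[CountyEstimate],
    n_draws: int,
    seed: int,
    fits: Mapping[str, PoissonFit] | None = None,
) -> dict[str, tuple[list[CountyEstimate], np.ndarray]]:
    """Per-stratum matrices of unrecruited-case draws, (n_draws, n_targets).

    Each county's linear predictor is marginally ``Normal(eta, link_se)``.
    When the stratum's :class:`PoissonFit` is supplied the draws come from a
    single coefficient draw per replicate, so counties within a stratum are
    correlated exactly as the shared fitted model implies — without this the
    parameter uncertainty common to all counties would average out of the
    totals and their intervals would be spuriously narrow.  Without a fit, a
    single standard-normal factor per replicate scales every county's
    link_se (the perfect-correlation limit).

    Draw order is fixed (strata sorted, targets sorted by county id) so the
    same seed always yields the same draws regardless of the quantity asked
    for, letting the grand total reuse the per-stratum draws.
    """
    rng = np.random.default_rng(seed)
    result: dict[str, tuple[list[CountyEstimate], np.ndarray]] = {}
    for stratum in sorted({e.stratum for e in estimates}):
        targets = sorted(
            (e for e in estimates if e.stratum == stratum and e.is_target),
            key=lambda e: e.county_id,
        )
        if not targets:
            result[stratum] = ([], np.zeros((n_draws, 0)))
            continue
        eta = np.array([e.eta for e in targets])
        se = np.array([e.link_se for e in targets])
        recruited = np.array([e.recruited for e in targets], dtype=float)
        fit = (fits or {}).get(stratum)
        if fit is not None:
            cov = np.array(
                [[fit.se_b0**2, fit.cov_b0b1], [fit.cov_b0b1, fit.se_b1**2]]
            )
            # svd handles the PSD cases (no-intercept and zero-variance fits)
            coefs = rng.multivariate_normal(
                [fit.b0, fit.b1], cov, size=n_draws, method="svd"
            )
            x = np.array([e.ln_pop for e in targets])
            draws = coefs[:, [0]] + coefs[:, [1]] * x[None, :]
        else:
            z = rng.standard_normal((n_draws, 1))
            draws = eta[None, :] + z * se[None, :]
        u = np.maximum(np.exp(draws) - recruited, 0.0)
        result[stratum] = (targets, u)
    return result


def monte_carlo_interval(
    estimates: Sequence[CountyEstimate],
    quantity: str = "per_stratum_total",
    n_draws: int = 10_000,
    seed: int = 0,
    fits: Mapping[str, PoissonFit] | None = None,
):
    """Empirical 95% intervals for unrecruited-case quantities.

    Per draw and per target county the linear predictor is sampled as
    ``Normal(eta, link_se)`` on the log scale, exponentiated, and truncated
    at the recruited count.  ``quantity`` selects the return shape:

    - ``"per_county"`` -> ``{(county_id, stratum): IntervalEstimate}``
    - ``"per_stratum_total"`` -> ``{stratum: IntervalEstimate}``
    - ``"grand_total"`` -> a single :class:`IntervalEstimate` whose draws are
      the per-stratum draws summed within each draw.
    """
    if n_draws < 100:
        raise GapEstimationError(f"n_draws must be >= 100, got {n_draws}")
    per_stratum = _target_draws(estimates, n_draws, seed, fits=fits)

    def interval(point: float, draws: np.ndarray) -> IntervalEstimate:
        lo, hi = np.percentile(draws, [2.5, 97.5])
        return IntervalEstimate(
            point=point, lower=float(lo), upper=float(hi), n_draws=n_draws, seed=seed
        )

    if quantity == "per_county":
        out: dict[tuple[str, str], IntervalEstimate] = {}
        for stratum, (targets, u) in per_stratum.items():
            for j, est in enumerate(targets):
                out[(est.county_id, stratum)] = interval(est.unrecruited, u[:, j])
        return out
    if quantity == "per_stratum_total":
        return {
            stratum: interval(
                sum(e.unrecruited for e in targets), u.sum(axis=1)
            )
            for stratum, (targets, u) in per_stratum.items()
        }
    if quantity == "grand_total":
        total_point = sum(
            e.unrecruited for targets, _ in per_stratum.values() for e in targets
        )
        total_draws = np.zeros(n_draws)
        for _, u in per_stratum.values():
            total_draws += u.sum(axis=1)
        return interval(total_point, total_draws)
    raise GapEstimationError(f"unknown quantity {quantity!r}")


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves away from zero (upward)."""
    return int(math.floor(x + 0.5))


def summarize_strata(
    rows: Mapping[str, tuple[int, int, float]]
) -> pd.DataFrame:
    """Summary table from per-stratum (recruited_in_target, recruited_total,
    fractional unrecruited) triples.

    Per stratum: the rounded integer ``R`` is half-up; the percentage of
    unrecruited cases among target-county cases is ``R / (recruited_in_target
    + R) * 100`` and among all cases ``R / (recruited_total + R) * 100``.
    The total row's rounded integer is the SUM of the per-stratum rounded
    integers, not the rounding of the summed fraction.
    """
    data = []
    tot_target = tot_all = tot_frac = 0.0
    tot_round = 0
    for stratum in sorted(rows):
        rec_target, rec_all, frac = rows[stratum]
        r = round_half_up(frac)
        data.append(
            {
                "stratum": stratum,
                "recruited_in_target": rec_target,
                "recruited_total": rec_all,
                "unrecruited": frac,
                "unrecruited_rounded": r,
                "pct_of_target_cases": _pct(r, rec_target),
                "pct_of_all_cases": _pct(r, rec_all),
            }
        )
        tot_target += rec_target
        tot_all += rec_all
        tot_frac += frac
        tot_round += r
    data.append(
        {
            "stratum": "total",
            "recruited_in_target": int(tot_target),
            "recruited_total": int(tot_all),
            "unrecruited": tot_frac,
            "unrecruited_rounded": tot_round,
            "pct_of_target_cases": _pct(tot_round, tot_target),
            "pct_of_all_cases": _pct(tot_round, tot_all),
        }
    )
    return pd.DataFrame(data).set_index("stratum")


def _pct(rounded: int, recruited: float) -> float:
    denom = recruited + rounded
    return 100.0 * rounded / denom if denom > 0 else 0.0


def summarize_results(
    estimates: Sequence[CountyEstimate],
    adjustments: Sequence["AdjustmentOutcome"] | None = None,  # noqa: F821
) -> pd.DataFrame:
    """Per-stratum and total summary of estimated unrecruited cases.

    When spatial ``adjustments`` are supplied their final unrecruited counts
    replace the purely statistical estimates.
    """
    final: dict[tuple[str, str], float] = {
        (e.county_id, e.stratum): e.unrecruited for e in estimates
    }
    if adjustments is not None:
        for a in adjustments:
            final[(a.county_id, a.stratum)] = a.final_unrecruited
    rows: dict[str, tuple[int, int, float]] = {}
    for stratum in sorted({e.stratum for e in estimates}):
        strat = [e for e in estimates if e.stratum == stratum]
        rec_target = sum(e.recruited for e in strat if e.is_target)
        rec_all = sum(e.recruited for e in strat)
        frac = sum(final[(e.county_id, stratum)] for e in strat)
        rows[stratum] = (rec_target, rec_all, frac)
    return summarize_strata(rows)
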