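"""Spatial outlier detection and locally weighted rate smoothing.

Raw small-area rates are unstable when counts or populations are small, so
rates are first transformed to Empirical Bayes standardized deviations
(Assunção & Reis) whose variance accounts for population size.  Local
Moran's I on those deviations, with conditional permutation inference,
flags spatial outliers: a county high amid low neighbours (HL) or low amid
high neighbours (LH).  Flagged target counties have their rate replaced by
the population-weighted average of their neighbours' rates, and their
estimated case count adjusted accordingly.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .records import RATE_SCALE, AdjacencyList
from .gap import CountyEstimate

__all__ = [
    "SpatialAdjustmentError",
    "EBStandardization",
    "LocalMoranResult",
    "AdjustmentOutcome",
    "eb_standardize",
    "local_moran",
    "smooth_outlier",
    "apply_adjustment",
]

log = logging.getLogger(__name__)


class SpatialAdjustmentError(ValueError):
    """Spatial adjustment could not proceed on this input."""


@dataclass(frozen=True)
class EBStandardization:
    """Empirical Bayes rate standardization.

    ``beta`` is the overall rate (total cases / total population) on the raw
    per-person scale, ``alpha`` the between-county variance component, and
    ``z[i] = (r_i - beta) / sqrt(alpha + beta / pop_i)``.
    """

    county_ids: tuple[str, ...]
    beta: float
    alpha: float
    z: tuple[float, ...]

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.county_ids, self.z))


@dataclass(frozen=True)
class LocalMoranResult:
    """Local Moran's I for one county on the EB deviations."""

    county_id: str
    z: float  # EB standardized deviation
    lag: float  # row-standardized spatial lag of centered deviations
    local_i: float
    pseudo_p: float
    quadrant: str  # HH | LL | HL | LH | NS


@dataclass(frozen=True)
class AdjustmentOutcome:
    """Result of (possibly) smoothing one county's estimated count."""

    county_id: str
    stratum: str
    pre_rate: float
    smoothed_rate: float
    pre_count: float
    adjusted_count: float
    delta_unrecruited: float
    final_unrecruited: float


def eb_standardize(
    counts: Mapping[str, float], pops: Mapping[str, float]
) -> EBStandardization:
    """Assunção–Reis EB standardization of county rates.

    ``beta = sum(counts) / sum(pops)``; the variance component is
    ``alpha = max(0, s2 - beta / mean(pop))`` with ``s2`` the
    population-weighted variance of the raw rates around ``beta``.
    """
    ids = tuple(sorted(counts))
    if set(ids) != set(pops):
        raise SpatialAdjustmentError("counts and pops must cover the same counties")
    c = np.array([counts[i] for i in ids], dtype=float)
    p = np.array([pops[i] for i in ids], dtype=float)
    if p.sum() <= 0:
        raise SpatialAdjustmentError("total population must be positive")
    r = c / p
    beta = float(c.sum() / p.sum())
    s2 = float((p * (r - beta) ** 2).sum() / p.sum())
    alpha = max(0.0, s2 - beta / float(p.mean()))
    denom = np.sqrt(alpha + beta / p)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(denom > 0, (r - beta) / denom, 0.0)
    return EBStandardization(
        county_ids=ids, beta=beta, alpha=alpha, z=tuple(float(v) for v in z)
    )


def _quadrant(y: float, lag: float, significant: bool) -> str:
    if not significant or y == 0 or lag == 0:
        return "NS"
    if y > 0:
        return "HH" if lag > 0 else "HL"
    return "LH" if lag > 0 else "LL"


def local_moran(
    eb: EBStandardization,
    adjacency: AdjacencyList,
    n_perm: int = 999,
    seed: int = 0,
    significance: float = 0.05,
    exact: bool = False,
) -> list[LocalMoranResult]:
    """Local Moran's I with conditional permutation pseudo-significance.

    With centered deviations ``y_i = z_i - mean(z)`` and ``m2 = sum(y^2)/n``,
    ``I_i = (y_i / m2) * sum_j w_ij y_j`` with row-standardized weights.  The
    permutation test holds ``y_i`` fixed and reassigns the remaining values
    to the neighbour positions; the pseudo p-value is one-sided in the
    direction of the observed lag.  ``exact=True`` enumerates every distinct
    assignment instead of sampling (only sensible for tiny graphs).

    Counties without neighbours are reported NS with a logged warning.
    """
    if not exact and n_perm < 99:
        raise SpatialAdjustmentError(
            f"n_perm must be >= 99 for a stable pseudo p-value, got {n_perm}"
        )
    ids = eb.county_ids
    adjacency.check_ids(ids)
    n = len(ids)
    index = {cid: k for k, cid in enumerate(ids)}
    z = np.array(eb.z)
    y = z - z.mean()
    m2 = float((y**2).sum()) / n
    rng = np.random.default_rng(seed)

    results: list[LocalMoranResult] = []
    for k, cid in enumerate(ids):
        nbrs = [index[j] for j in adjacency.neighbors[cid]]
        if not nbrs:
            log.warning("county %s has no neighbors; reported NS", cid)
            results.append(
                LocalMoranResult(cid, float(z[k]), 0.0, 0.0, 1.0, "NS")
            )
            continue
        lag = float(y[nbrs].mean())
        if m2 == 0:
            results.append(LocalMoranResult(cid, float(z[k]), lag, 0.0, 1.0, "NS"))
            continue
        local_i = float(y[k] * lag / m2)
        others = np.delete(y, k)
        d = len(nbrs)
        if exact:
            perms = np.array(
                list(itertools.permutations(range(n - 1), d)), dtype=int
            )
            perm_lags = others[perms].mean(axis=1)
        else:
            order = np.argsort(rng.random((n_perm, n - 1)), axis=1)[:, :d]
            perm_lags = others[order].mean(axis=1)
        if lag >= 0:
            extreme = int((perm_lags >= lag).sum())
        else:
            extreme = int((perm_lags <= lag).sum())
        pseudo_p = (extreme + 1) / (len(perm_lags) + 1)
        results.append(
            LocalMoranResult(
                county_id=cid,
                z=float(z[k]),
                lag=lag,
                local_i=local_i,
                pseudo_p=pseudo_p,
                quadrant=_quadrant(float(y[k]), lag, pseudo_p <= significance),
            )
        )
    return results


def smooth_outlier(
    county_id: str,
    rates: Mapping[str, float],
    pops: Mapping[str, float],
    adjacency: AdjacencyList,
    include_self: bool = False,
) -> float:
    """Population-weighted average rate over a county's contiguity neighbours.

    The focal county is excluded by default; ``include_self=True`` adds it to
    its own neighbourhood.
    """
    nbrs = sorted(adjacency.neighbors[county_id])
    if include_self:
        nbrs = sorted(set(nbrs) | {county_id})
    if not nbrs:
        raise SpatialAdjustmentError(f"county {county_id!r} has no neighbors")
    w = np.array([pops[j] for j in nbrs], dtype=float)
    r = np.array([rates[j] for j in nbrs], dtype=float)
    if w.sum() <= 0:
        raise SpatialAdjustmentError(f"zero total neighbor population at {county_id!r}")
    return float((w * r).sum() / w.sum())


def apply_adjustment(
    estimates: Sequence[CountyEstimate],
    moran: Sequence[LocalMoranResult],
    rates: Mapping[str, float],
    pops: Mapping[str, float],
    adjacency: AdjacencyList,
    rate_scale: float = RATE_SCALE,
    include_self: bool = False,
) -> list[AdjustmentOutcome]:
    """Adjust significant outlier target counties by neighbourhood smoothing.

    Only target counties flagged LH or HL are touched.  An LH county (low
    amid high) gains unrecruited cases when the smoothed count exceeds its
    current expected count; an HL county (high amid low) loses them when the
    smoothed count is lower, floored so the expected count never drops below
    the recruited count.  Every other county passes through unchanged.
    """
    quadrants = {m.county_id: m.quadrant for m in moran}
    out: list[AdjustmentOutcome] = []
    for e in estimates:
        pre_count = e.recruited + e.unrecruited
        pre_rate = rates[e.county_id]
        quad = quadrants.get(e.county_id, "NS")
        if not e.is_target or quad not in ("LH", "HL") or not adjacency.neighbors[e.county_id]:
            out.append(
                AdjustmentOutcome(
                    county_id=e.county_id,
                    stratum=e.stratum,
                    pre_rate=pre_rate,
                    smoothed_rate=pre_rate,
                    pre_count=pre_count,
                    adjusted_count=pre_count,
                    delta_unrecruited=0.0,
                    final_unrecruited=e.unrecruited,
                )
            )
            continue
        smoothed = smooth_outlier(
            e.county_id, rates, pops, adjacency, include_self=include_self
        )
        candidate = smoothed * pops[e.county_id] / rate_scale
        if quad == "LH" and candidate > pre_count:
            new_count = candidate
        elif quad == "HL" and candidate < pre_count:
            new_count = max(candidate, float(e.recruited))
        else:
            new_count = pre_count
        final_unrec = max(new_count - e.recruited, 0.0)
        out.append(
            AdjustmentOutcome(
                county_id=e.county_id,
                stratum=e.stratum,
                pre_rate=pre_rate,
                smoothed_rate=smoothed,
                pre_count=pre_count,
                adjusted_count=new_count,
                delta_unrecruited=final_unrec - e.unrecruited,
                final_unrecruited=final_unrec,
            )
        )
    return out
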