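"""Reference-county selection on the ranked incidence-rate series.

Reference counties are those whose recruited-case incidence rate sits in a
"normal" middle band of the ranked rate series: counties above the band are
suspected hotspot members, counties below it (target counties) are suspected
of under-recruitment or of being true cold spots.  Three exploratory methods
delimit the band — a z-score band around the mean rate, the longest flat
("straight") section of the ranked series, and Jenks natural-breaks
classification — and a consensus rule combines them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .records import IncidenceRate

__all__ = [
    "ReferenceSelectionError",
    "RankedRateSeries",
    "ReferenceRange",
    "JenksPartition",
    "rank_by_rate",
    "zscore_reference_range",
    "straight_section",
    "jenks_breaks",
    "jenks_reference_range",
    "consensus_reference",
]


class ReferenceSelectionError(ValueError):
    """Reference selection could not be completed on this input."""


@dataclass(frozen=True)
class RankedRateSeries:
    """Counties ranked by incidence rate, descending.

    ``diffs[k] = rate[k] - rate[k+1]`` and ``ratios[k] = rate[k] / rate[k+1]``
    (NaN where the lower rate is zero) describe the local steepness of the
    ranked series.
    """

    entries: tuple[tuple[str, float], ...]
    diffs: tuple[float, ...]
    ratios: tuple[float, ...]


@dataclass(frozen=True)
class ReferenceRange:
    """An incidence-rate interval plus the counties it admits.

    ``lower`` and ``upper`` are observed rates (the extremes among admitted
    counties), not analytic band ends.
    """

    method: str  # zscore | straight_section | jenks | consensus
    lower: float
    upper: float
    members: frozenset[str]
    z_level: float | None = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ReferenceSelectionError(
                f"reference range lower {self.lower} > upper {self.upper}"
            )


@dataclass(frozen=True)
class JenksPartition:
    """Optimal contiguous partition of sorted rates into ``k`` sections.

    ``sections`` are tuples of values in ascending order; ``breaks`` are the
    smallest value of each section after the first; ``gvf`` is the total
    within-section sum of squared deviations (lower is better) and is the
    global minimum over all contiguous partitions.
    """

    k: int
    breaks: tuple[float, ...]
    sections: tuple[tuple[float, ...], ...]
    gvf: float

    @property
    def intervals(self) -> tuple[tuple[float, float], ...]:
        return tuple((s[0], s[-1]) for s in self.sections)


def rank_by_rate(rates: Sequence[IncidenceRate]) -> RankedRateSeries:
    """Rank counties by rate descending; rate ties broken by county id."""
    if not rates:
        raise ReferenceSelectionError("cannot rank an empty rate sequence")
    ordered = sorted(rates, key=lambda r: (-r.rate, r.county_id))
    entries = tuple((r.county_id, r.rate) for r in ordered)
    values = [r for _, r in entries]
    diffs = tuple(values[k] - values[k + 1] for k in range(len(values) - 1))
    ratios = tuple(
        values[k] / values[k + 1] if values[k + 1] > 0 else math.nan
        for k in range(len(values) - 1)
    )
    return RankedRateSeries(entries=entries, diffs=diffs, ratios=ratios)


def _members_in(
    rates: Sequence[IncidenceRate], lower: float, upper: float
) -> frozenset[str]:
    return frozenset(r.county_id for r in rates if lower <= r.rate <= upper)


def zscore_reference_range(
    rates: Sequence[IncidenceRate], z_level: float
) -> ReferenceRange:
    """Counties within ``z_level`` sample standard deviations of the mean rate.

    The mean and standard deviation are computed over all counties, zero
    rates included.  The reported bounds are the minimum and maximum observed
    rates among admitted counties (never below zero), not the analytic band.
    """
    if z_level <= 0:
        raise ReferenceSelectionError(f"z_level must be positive, got {z_level}")
    values = np.array([r.rate for r in rates], dtype=float)
    if values.size < 2:
        raise ReferenceSelectionError("z-score selection needs at least 2 counties")
    mu = float(values.mean())
    sigma = float(values.std(ddof=1))
    if sigma == 0:
        raise ReferenceSelectionError(
            "all rates identical: zero standard deviation gives no discrimination"
        )
    admitted = [r for r in rates if abs(r.rate - mu) / sigma < z_level]
    if not admitted:
        raise ReferenceSelectionError(
            f"no county within |z| < {z_level}; increase z_level"
        )
    lo = max(0.0, min(r.rate for r in admitted))
    hi = max(r.rate for r in admitted)
    return ReferenceRange(
        method="zscore",
        z_level=z_level,
        lower=lo,
        upper=hi,
        members=frozenset(r.county_id for r in admitted),
    )


def straight_section(
    series: RankedRateSeries,
    max_diff: float | None = None,
    max_ratio: float = 1.15,
    min_length: int = 8,
) -> ReferenceRange:
    """Longest flat run of the ranked non-zero rate series.

    A run is a maximal stretch of consecutive entries where every step has
    difference <= ``max_diff`` and ratio <= ``max_ratio``.  ``max_diff``
    defaults to twice the median step of the non-zero series.  Among equally
    long runs the one whose median rate is closest to the mean rate of the
    non-zero series wins.  The range spans the observed rates of the run.
    """
    nonzero = [(cid, r) for cid, r in series.entries if r > 0]
    if len(nonzero) < 2:
        raise ReferenceSelectionError(
            "straight-section selection needs at least 2 non-zero rates"
        )
    values = [r for _, r in nonzero]
    diffs = [values[k] - values[k + 1] for k in range(len(values) - 1)]
    ratios = [values[k] / values[k + 1] for k in range(len(values) - 1)]
    if max_diff is None:
        max_diff = 2.0 * float(np.median(diffs))
    if max_diff <= 0 or max_ratio < 1:
        raise ReferenceSelectionError(
            f"invalid flatness thresholds max_diff={max_diff}, max_ratio={max_ratio}"
        )
    if min_length < 2:
        raise ReferenceSelectionError(f"min_length must be >= 2, got {min_length}")

    ok = [d <= max_diff and q <= max_ratio for d, q in zip(diffs, ratios)]
    runs: list[tuple[int, int]] = []  # [start, end) index ranges over entries
    start = 0
    for k, flat in enumerate(ok + [False]):
        if not flat:
            if k + 1 - start >= 2:
                runs.append((start, k + 1))
            start = k + 1
    runs = [r for r in runs if r[1] - r[0] >= min_length]
    if not runs:
        raise ReferenceSelectionError(
            f"no flat run of length >= {min_length} with max_diff={max_diff:g}, "
            f"max_ratio={max_ratio:g}; loosen the thresholds"
        )
    mean_rate = float(np.mean(values))
    best = max(
        runs,
        key=lambda r: (
            r[1] - r[0],
            -abs(float(np.median(values[r[0] : r[1]])) - mean_rate),
            -r[0],
        ),
    )
    segment = nonzero[best[0] : best[1]]
    return ReferenceRange(
        method="straight_section",
        lower=min(r for _, r in segment),
        upper=max(r for _, r in segment),
        members=frozenset(cid for cid, _ in segment),
    )


def _sse(prefix: np.ndarray, prefix2: np.ndarray, i: int, j: int) -> float:
    """Sum of squared deviations of sorted values[i:j] via prefix sums."""
    n = j - i
    s = prefix[j] - prefix[i]
    s2 = prefix2[j] - prefix2[i]
    return max(0.0, s2 - s * s / n)


def jenks_breaks(values: Iterable[float], k: int) -> JenksPartition:
    """Exact Jenks natural breaks by Fisher's optimal-partitioning DP.

    Partitions the sorted values into ``k`` contiguous sections minimising
    the total within-section sum of squared deviations; ties are broken by
    preferring the partition with the lowest first break.
    """
    vals = sorted(float(v) for v in values)
    n = len(vals)
    if n == 0:
        raise ReferenceSelectionError("cannot partition an empty value set")
    distinct = len(set(vals))
    if k < 1 or k > distinct:
        raise ReferenceSelectionError(
            f"k must be between 1 and the number of distinct values ({distinct}), got {k}"
        )
    arr = np.array(vals)
    prefix = np.concatenate(([0.0], np.cumsum(arr)))
    prefix2 = np.concatenate(([0.0], np.cumsum(arr * arr)))

    # suffix[m][i] = minimal cost of partitioning vals[i:] into m sections
    inf = math.inf
    suffix = [[inf] * (n + 1) for _ in range(k + 1)]
    suffix[0][n] = 0.0
    for m in range(1, k + 1):
        # need at least m values remaining and at most enough to fill sections
        for i in range(n - m, -1, -1):
            best = inf
            for j in range(i + 1, n - m + 2):
                tail = suffix[m - 1][j]
                if tail == inf:
                    continue
                cost = _sse(prefix, prefix2, i, j) + tail
                if cost < best:
                    best = cost
            suffix[m][i] = best

    # Reconstruct left-to-right, taking the shortest first section that is
    # still optimal: this yields the lowest possible first break.
    cuts = [0]
    i, m = 0, k
    while m > 1:
        target = suffix[m][i]
        for j in range(i + 1, n - m + 2):
            if _sse(prefix, prefix2, i, j) + suffix[m - 1][j] == target:
                cuts.append(j)
                i, m = j, m - 1
                break
        else:  # pragma: no cover - DP consistency guard
            raise AssertionError("jenks reconstruction failed")
    cuts.append(n)

    sections = tuple(tuple(vals[a:b]) for a, b in zip(cuts, cuts[1:]))
    breaks = tuple(s[0] for s in sections[1:])
    return JenksPartition(k=k, breaks=breaks, sections=sections, gvf=suffix[k][0])


def jenks_reference_range(
    partition: JenksPartition, rates: Sequence[IncidenceRate]
) -> ReferenceRange:
    """Reference range from the Jenks section containing the mean rate.

    The unweighted mean rate over all counties selects the section whose
    observed [min, max] interval contains it; a mean falling on a break or in
    a gap between sections selects the higher section.
    """
    mean_rate = float(np.mean([r.rate for r in rates]))
    chosen: tuple[float, ...] | None = None
    for section in partition.sections:
        lo, hi = section[0], section[-1]
        if lo <= mean_rate <= hi:
            chosen = section
            # keep scanning: a mean exactly on a break (== next section's min)
            # must select the higher section
            continue
        if chosen is not None:
            if lo == mean_rate:
                chosen = section
            break
        if mean_rate < lo:  # mean in the gap below this section
            chosen = section
            break
    if chosen is None:  # mean above every section (cannot happen with real data)
        chosen = partition.sections[-1]
    lo, hi = chosen[0], chosen[-1]
    return ReferenceRange(
        method="jenks", lower=lo, upper=hi, members=_members_in(rates, lo, hi)
    )


def consensus_reference(
    ranges: Sequence[ReferenceRange],
    rates: Sequence[IncidenceRate],
    rule: str = "intersection",
) -> ReferenceRange:
    """Combine per-method reference ranges into the final range.

    ``intersection`` (default) intersects the three rate intervals and
    recomputes members from the rates; ``majority`` admits counties accepted
    by at least two of the three methods.
    """
    if len(ranges) != 3:
        raise ReferenceSelectionError(
            f"consensus expects exactly 3 ranges, got {len(ranges)}"
        )
    if rule == "intersection":
        lo = max(r.lower for r in ranges)
        hi = min(r.upper for r in ranges)
        if lo > hi:
            raise ReferenceSelectionError(
                "the three reference ranges have an empty intersection; "
                "consider the majority consensus rule"
            )
        return ReferenceRange(
            method="consensus", lower=lo, upper=hi, members=_members_in(rates, lo, hi)
        )
    if rule == "majority":
        counts: dict[str, int] = {}
        for r in ranges:
            for cid in r.members:
                counts[cid] = counts.get(cid, 0) + 1
        members = frozenset(cid for cid, c in counts.items() if c >= 2)
        if not members:
            raise ReferenceSelectionError(
                "no county admitted by at least two methods"
            )
        admitted = [r.rate for r in rates if r.county_id in members]
        return ReferenceRange(
            method="consensus",
            lower=min(admitted),
            upper=max(admitted),
            members=members,
        )
    raise ReferenceSelectionError(f"unknown consensus rule {rule!r}")
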