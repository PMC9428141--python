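"""End-to-end orchestration: reference selection -> Poisson gap estimation ->
spatial adjustment -> reporting and validation, per sex stratum.

Strata are processed independently end to end and merged only in reporting;
"total" rows are always derived by summation, never modelled directly.  All
randomness flows from one top-level seed split deterministically per stratum
and per consumer (Monte Carlo intervals, permutation inference).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .records import (
    RATE_SCALE,
    AdjacencyList,
    CountyStratumRecord,
    compute_rates,
)
from .reference import (
    ReferenceRange,
    ReferenceSelectionError,
    consensus_reference,
    jenks_breaks,
    jenks_reference_range,
    rank_by_rate,
    straight_section,
    zscore_reference_range,
)
from .gap import (
    CountyEstimate,
    IntervalEstimate,
    PoissonFit,
    fit_poisson,
    monte_carlo_interval,
    predict_expected,
    summarize_results,
)
from .spatial import (
    AdjustmentOutcome,
    LocalMoranResult,
    apply_adjustment,
    eb_standardize,
    local_moran,
)
from .validation import ValidationTable, validation_table

__all__ = ["RunConfig", "StratumResult", "PipelineResult", "run_stratum", "run_all"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Validated knobs for the whole pipeline."""

    rate_scale: float = RATE_SCALE
    z_levels: tuple[float, ...] = (0.25, 0.5, 0.75)
    consensus_z_level: float = 0.5
    jenks_k: int = 5
    straight_max_diff: float | None = None
    straight_max_ratio: float = 1.15
    straight_min_length: int = 8
    consensus_rule: str = "intersection"
    intercept: bool = True
    n_draws: int = 10_000
    n_perm: int = 999
    significance: float = 0.05
    include_self: bool = False
    moran_input: str = "post_estimation"  # or "recruited"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.moran_input not in ("post_estimation", "recruited"):
            raise ValueError(f"unknown moran_input {self.moran_input!r}")
        if self.consensus_rule not in ("intersection", "majority"):
            raise ValueError(f"unknown consensus_rule {self.consensus_rule!r}")
        if self.consensus_z_level not in self.z_levels:
            raise ValueError(
                f"consensus_z_level {self.consensus_z_level} must be one of z_levels"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("z_levels",):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic sub-seeds below 2^31 derived from one top-level seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


@dataclass(frozen=True)
class StratumResult:
    """Everything the pipeline produced for one sex stratum."""

    stratum: str
    ranges: tuple[ReferenceRange, ...]  # per-method ranges (all z levels too)
    consensus: ReferenceRange
    target_ids: frozenset[str]
    fit: PoissonFit
    estimates: tuple[CountyEstimate, ...]
    interval: IntervalEstimate  # stratum-total unrecruited
    moran: tuple[LocalMoranResult, ...]
    adjustments: tuple[AdjustmentOutcome, ...]

    @property
    def final_unrecruited(self) -> dict[str, float]:
        return {a.county_id: a.final_unrecruited for a in self.adjustments}


@dataclass(frozen=True)
class PipelineResult:
    config: RunConfig
    strata: Mapping[str, StratumResult]
    grand_interval: IntervalEstimate
    summary: pd.DataFrame
    validation: ValidationTable | None

    def final_unrecruited(self) -> dict[tuple[str, str], float]:
        return {
            (a.county_id, s.stratum): a.final_unrecruited
            for s in self.strata.values()
            for a in s.adjustments
        }


def select_references(
    records: Sequence[CountyStratumRecord], config: RunConfig
) -> tuple[list[ReferenceRange], ReferenceRange]:
    """Run the three selection methods and the consensus for one stratum.

    The operations keep their strict contracts, but an unattended pipeline
    needs deterministic fallbacks where the original procedure relied on a
    human: if no flat run exists at the configured thresholds the flatness
    bound is doubled (at most three times, with the run-length floor relaxed
    on the last try), and if the interval intersection of the three methods
    is empty — or admits too few counties to fit a two-parameter model — the
    consensus falls back to the majority rule.  Every fallback is logged.
    """
    rates = compute_rates(records, config.rate_scale)
    series = rank_by_rate(rates)
    ranges = [zscore_reference_range(rates, z) for z in config.z_levels]

    straight = None
    max_diff = config.straight_max_diff
    min_length = config.straight_min_length
    for attempt in range(4):
        try:
            straight = straight_section(
                series,
                max_diff=max_diff,
                max_ratio=config.straight_max_ratio,
                min_length=min_length,
            )
            break
        except ReferenceSelectionError as exc:
            if attempt == 3:
                raise
            if max_diff is None:
                nonzero = [r for _, r in series.entries if r > 0]
                diffs = [a - b for a, b in zip(nonzero, nonzero[1:])]
                max_diff = 2.0 * float(np.median(diffs))
            max_diff *= 2.0
            if attempt == 2:
                min_length = max(4, min_length // 2)
            log.warning(
                "straight-section fallback: %s; retrying with max_diff=%.4g, "
                "min_length=%d",
                exc,
                max_diff,
                min_length,
            )

    jenks = jenks_reference_range(
        jenks_breaks([r.rate for r in rates], config.jenks_k), rates
    )
    consensus_inputs = [
        next(r for r in ranges if r.z_level == config.consensus_z_level),
        straight,
        jenks,
    ]
    rule = config.consensus_rule
    try:
        consensus = consensus_reference(consensus_inputs, rates, rule=rule)
        if rule == "intersection" and len(consensus.members) < 3:
            raise ReferenceSelectionError(
                f"intersection admits only {len(consensus.members)} county(ies)"
            )
    except ReferenceSelectionError as exc:
        if rule != "intersection":
            raise
        log.warning("consensus fallback to majority rule: %s", exc)
        consensus = consensus_reference(consensus_inputs, rates, rule="majority")
    return ranges + [straight, jenks], consensus


def run_stratum(
    records: Sequence[CountyStratumRecord],
    adjacency: AdjacencyList,
    config: RunConfig,
    seed: int,
) -> StratumResult:
    """Both estimation phases for one stratum's records."""
    if not records:
        raise ValueError("no records for stratum")
    stratum = records[0].stratum
    if any(r.stratum != stratum for r in records):
        raise ValueError("run_stratum expects records from a single stratum")
    adjacency.check_ids(r.county_id for r in records)
    mc_seed, moran_seed = _child_seeds(seed, 2)

    rates = compute_rates(records, config.rate_scale)
    rate_of = {r.county_id: r.rate for r in rates}
    ranges, consensus = select_references(records, config)

    target_ids = frozenset(
        r.county_id for r in rates if r.rate < consensus.lower
    )
    reference = [r for r in records if r.county_id in consensus.members]
    log.info(
        "%s: reference range [%.4f, %.4f], %d reference, %d target counties",
        stratum,
        consensus.lower,
        consensus.upper,
        len(reference),
        len(target_ids),
    )

    fit = fit_poisson(reference, intercept=config.intercept)
    estimates = predict_expected(fit, records, target_ids)
    interval = monte_carlo_interval(
        estimates,
        "per_stratum_total",
        n_draws=config.n_draws,
        seed=mc_seed,
        fits={stratum: fit},
    )[stratum]

    pops = {r.county_id: float(r.population) for r in records}
    if config.moran_input == "post_estimation":
        counts = {e.county_id: e.recruited + e.unrecruited for e in estimates}
    else:
        counts = {r.county_id: float(r.recruited_cases) for r in records}
    post_rates = {
        cid: counts[cid] / pops[cid] * config.rate_scale for cid in counts
    }
    eb = eb_standardize(counts, pops)
    moran = local_moran(
        eb,
        adjacency,
        n_perm=config.n_perm,
        seed=moran_seed,
        significance=config.significance,
    )
    outliers = [m for m in moran if m.quadrant in ("HL", "LH")]
    if outliers:
        log.info(
            "%s: %d significant spatial outlier(s): %s",
            stratum,
            len(outliers),
            ", ".join(f"{m.county_id}({m.quadrant})" for m in outliers),
        )
    adjustments = apply_adjustment(
        estimates,
        moran,
        post_rates,
        pops,
        adjacency,
        rate_scale=config.rate_scale,
        include_self=config.include_self,
    )
    for a in adjustments:
        if a.delta_unrecruited != 0:
            log.info(
                "%s: county %s adjusted by %+.3f unrecruited cases",
                stratum,
                a.county_id,
                a.delta_unrecruited,
            )
    return StratumResult(
        stratum=stratum,
        ranges=tuple(ranges),
        consensus=consensus,
        target_ids=target_ids,
        fit=fit,
        estimates=tuple(estimates),
        interval=interval,
        moran=tuple(moran),
        adjustments=tuple(adjustments),
    )


def run_all(
    records: Sequence[CountyStratumRecord],
    adjacency: AdjacencyList,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run both phases for every stratum, then merge reporting.

    Mortality-based validation is included when the records carry mortality
    counts.  When ``out_dir`` is given, per-county estimates, LISA results,
    reference ranges, the summary table, and the validation grid are written
    there as CSV.
    """
    config = config or RunConfig()
    strata = sorted({r.stratum for r in records})
    seeds = dict(zip(strata, _child_seeds(config.seed, len(strata))))
    results: dict[str, StratumResult] = {}
    all_estimates: list[CountyEstimate] = []
    all_adjustments: list[AdjustmentOutcome] = []
    for stratum in strata:
        strat_records = [r for r in records if r.stratum == stratum]
        res = run_stratum(strat_records, adjacency, config, seeds[stratum])
        results[stratum] = res
        all_estimates.extend(res.estimates)
        all_adjustments.extend(res.adjustments)

    mc_seeds = {
        stratum: _child_seeds(seeds[stratum], 2)[0] for stratum in strata
    }
    grand = _grand_interval(results, config, mc_seeds)
    summary = summarize_results(all_estimates, all_adjustments)

    mortality = {
        (r.county_id, r.stratum): r.mortality_cases
        for r in records
        if r.mortality_cases is not None
    }
    validation = None
    if mortality:
        validation = validation_table(
            all_estimates,
            all_adjustments,
            mortality,
            {s: set(results[s].target_ids) for s in strata},
        )

    result = PipelineResult(
        config=config,
        strata=results,
        grand_interval=grand,
        summary=summary,
        validation=validation,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _grand_interval(
    results: Mapping[str, StratumResult],
    config: RunConfig,
    mc_seeds: Mapping[str, int],
) -> IntervalEstimate:
    """Grand-total interval reusing each stratum's own draw stream."""
    from .gap import _target_draws

    total = np.zeros(config.n_draws)
    point = 0.0
    for stratum in sorted(results):
        res = results[stratum]
        point += sum(e.unrecruited for e in res.estimates)
        draws = _target_draws(
            res.estimates, config.n_draws, mc_seeds[stratum], fits={stratum: res.fit}
        )
        _, u = draws[stratum]
        total += u.sum(axis=1)
    lo, hi = np.percentile(total, [2.5, 97.5])
    return IntervalEstimate(
        point=point,
        lower=float(lo),
        upper=float(hi),
        n_draws=config.n_draws,
        seed=config.seed,
    )


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    est_rows, lisa_rows, range_rows = [], [], []
    for stratum, res in sorted(result.strata.items()):
        final = res.final_unrecruited
        for e in res.estimates:
            est_rows.append(
                {
                    "county_id": e.county_id,
                    "stratum": stratum,
                    "is_target": e.is_target,
                    "recruited": e.recruited,
                    "expected": e.mu,
                    "link_se": e.link_se,
                    "unrecruited_statistical": e.unrecruited,
                    "unrecruited_final": final[e.county_id],
                }
            )
        for m in res.moran:
            lisa_rows.append(
                {
                    "county_id": m.county_id,
                    "stratum": stratum,
                    "eb_z": m.z,
                    "lag": m.lag,
                    "local_i": m.local_i,
                    "pseudo_p": m.pseudo_p,
                    "quadrant": m.quadrant,
                }
            )
        for r in list(res.ranges) + [res.consensus]:
            range_rows.append(
                {
                    "stratum": stratum,
                    "method": r.method,
                    "z_level": r.z_level,
                    "lower": r.lower,
                    "upper": r.upper,
                    "n_members": len(r.members),
                    "members": ";".join(sorted(r.members)),
                }
            )
    pd.DataFrame(est_rows).to_csv(out_dir / "estimates.csv", index=False)
    pd.DataFrame(lisa_rows).to_csv(out_dir / "lisa.csv", index=False)
    pd.DataFrame(range_rows).to_csv(out_dir / "reference_ranges.csv", index=False)
    result.summary.to_csv(out_dir / "summary.csv")
    intervals = pd.DataFrame(
        [
            {
                "stratum": s,
                "point": res.interval.point,
                "lower": res.interval.lower,
                "upper": res.interval.upper,
            }
            for s, res in sorted(result.strata.items())
        ]
        + [
            {
                "stratum": "total",
                "point": result.grand_interval.point,
                "lower": result.grand_interval.lower,
                "upper": result.grand_interval.upper,
            }
        ]
    )
    intervals.to_csv(out_dir / "intervals.csv", index=False)
    if result.validation is not None:
        result.validation.to_frame().to_csv(out_dir / "validation.csv", index=False)
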