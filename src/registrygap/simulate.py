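"""Synthetic county registries with known ground truth.

Counties live on a square lattice with queen contiguity, so the spatial
statistics stay analytically tractable and no geometry files are needed.
Populations are log-normal (heavy right tail, as real county populations
are), true case counts are Poisson draws from a base incidence rate with
optional planted contiguous hotspot/coldspot multipliers, under-recruited
counties binomially thin their true counts, and mortality is a binomial
thinning of the TRUE counts — mortality reflects all cases, recruited or
not, which is what makes it usable for validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import (
    RATE_SCALE,
    AdjacencyList,
    CountyStratumRecord,
    STRATA,
    write_county_table,
    write_gal,
)

__all__ = [
    "Block",
    "ScenarioConfig",
    "SyntheticScenario",
    "generate_lattice_adjacency",
    "generate_scenario",
    "scenario_to_files",
    "recovery_report",
]


@dataclass(frozen=True)
class Block:
    """A rectangular lattice block with a rate multiplier (>1 hot, <1 cold)."""

    row: int
    col: int
    height: int
    width: int
    multiplier: float

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError(f"block multiplier must be positive, got {self.multiplier}")

    def contains(self, r: int, c: int) -> bool:
        return self.row <= r < self.row + self.height and self.col <= c < self.col + self.width


@dataclass(frozen=True)
class ScenarioConfig:
    """Generator settings; the defaults are the study conditions.

    ``base_rate`` is cases per 100,000 persons per study period and applies
    to each sex stratum.  A randomly chosen ``underrecruited_fraction`` of
    counties report only a ``Binomial(true, recruitment_prob)`` subset of
    their cases; everyone else reports completely.  ``mortality_prob`` thins
    the true counts into the validation mortality series.
    """

    n_side: int = 8
    pop_lognormal_mu: float = 11.5129  # median stratum population ~ 100,000
    pop_lognormal_sigma: float = 0.5
    base_rate: float = 5.0
    hotspot_blocks: tuple[Block, ...] = ()
    coldspot_blocks: tuple[Block, ...] = ()
    underrecruited_fraction: float = 0.3
    recruitment_prob: float = 0.4
    mortality_prob: float = 0.8
    clustered_underrecruitment: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_side < 2:
            raise ValueError("n_side must be >= 2")
        if not 0 <= self.underrecruited_fraction <= 1:
            raise ValueError("underrecruited_fraction must be in [0, 1]")
        if not 0 < self.recruitment_prob <= 1:
            raise ValueError("recruitment_prob must be in (0, 1]")
        if not 0 < self.mortality_prob <= 1:
            raise ValueError("mortality_prob must be in (0, 1]")
        if self.base_rate < 0:
            raise ValueError("base_rate must be nonnegative")
        for b in self.hotspot_blocks:
            if b.multiplier <= 1:
                raise ValueError("hotspot multipliers must exceed 1")
        for b in self.coldspot_blocks:
            if b.multiplier >= 1:
                raise ValueError("coldspot multipliers must be below 1")


@dataclass(frozen=True)
class SyntheticScenario:
    """Generated registry plus the ground truth needed to score estimates."""

    config: ScenarioConfig
    records: tuple[CountyStratumRecord, ...]
    adjacency: AdjacencyList
    #: per (county_id, stratum): true count, true rate (per 100k),
    #: under-recruited flag, and true missing = true - recruited
    truth: pd.DataFrame

    def true_missing_total(self, stratum: str | None = None) -> float:
        t = self.truth
        if stratum is not None:
            t = t[t["stratum"] == stratum]
        return float(t["missing"].sum())


def _county_id(n_side: int, r: int, c: int) -> str:
    width = len(str(n_side * n_side - 1))
    return f"C{r * n_side + c:0{width}d}"


def generate_lattice_adjacency(n_side: int) -> AdjacencyList:
    """Queen contiguity on an n_side x n_side lattice."""
    if n_side < 2:
        raise ValueError("n_side must be >= 2")
    neighbors: dict[str, set[str]] = {}
    for r in range(n_side):
        for c in range(n_side):
            nbrs = {
                _county_id(n_side, rr, cc)
                for rr in range(max(0, r - 1), min(n_side, r + 2))
                for cc in range(max(0, c - 1), min(n_side, c + 2))
                if (rr, cc) != (r, c)
            }
            neighbors[_county_id(n_side, r, c)] = nbrs
    return AdjacencyList.from_dict(neighbors)


def _pick_underrecruited(
    config: ScenarioConfig, ids: Sequence[str], adjacency: AdjacencyList, rng
) -> set[str]:
    n_under = int(round(config.underrecruited_fraction * len(ids)))
    if n_under == 0:
        return set()
    if not config.clustered_underrecruitment:
        return set(rng.choice(ids, size=n_under, replace=False))
    # Grow a contiguous region from a random seed county (the hard case for
    # reference selection, which assumes under-recruitment is not clustered).
    seed_county = str(rng.choice(ids))
    region = [seed_county]
    chosen = {seed_county}
    frontier = set(adjacency.neighbors[seed_county])
    while len(chosen) < n_under and frontier:
        nxt = str(rng.choice(sorted(frontier)))
        chosen.add(nxt)
        region.append(nxt)
        frontier = (frontier | set(adjacency.neighbors[nxt])) - chosen
    return chosen


def generate_scenario(config: ScenarioConfig) -> SyntheticScenario:
    """Draw one synthetic registry; all randomness flows from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_side
    adjacency = generate_lattice_adjacency(n)
    ids = sorted(adjacency.neighbors)

    # one base population per county x stratum
    pops = np.maximum(
        np.round(
            rng.lognormal(
                config.pop_lognormal_mu, config.pop_lognormal_sigma, (n * n, 2)
            )
        ),
        1000,
    ).astype(int)

    mult = np.ones(n * n)
    for r in range(n):
        for c in range(n):
            k = r * n + c
            for b in config.hotspot_blocks + config.coldspot_blocks:
                if b.contains(r, c):
                    mult[k] *= b.multiplier

    under = _pick_underrecruited(config, ids, adjacency, rng)

    records: list[CountyStratumRecord] = []
    truth_rows: list[dict] = []
    for k, cid in enumerate(ids):
        for si, stratum in enumerate(STRATA):
            spop = int(pops[k, si])
            lam = config.base_rate * mult[k] * spop / RATE_SCALE
            true = int(rng.poisson(lam))
            if cid in under:
                recruited = int(rng.binomial(true, config.recruitment_prob))
            else:
                recruited = true
            mortality = int(rng.binomial(true, config.mortality_prob))
            records.append(
                CountyStratumRecord(
                    county_id=cid,
                    stratum=stratum,
                    population=spop,
                    recruited_cases=recruited,
                    mortality_cases=mortality,
                )
            )
            truth_rows.append(
                {
                    "county_id": cid,
                    "stratum": stratum,
                    "true_count": true,
                    "true_rate": true / spop * RATE_SCALE,
                    "underrecruited": cid in under,
                    "missing": true - recruited,
                }
            )
    return SyntheticScenario(
        config=config,
        records=tuple(records),
        adjacency=adjacency,
        truth=pd.DataFrame(truth_rows),
    )


def scenario_to_files(scenario: SyntheticScenario, out_dir: str | Path) -> dict[str, Path]:
    """Write counties.csv, adjacency.gal and truth.csv; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counties": out / "counties.csv",
        "gal": out / "adjacency.gal",
        "truth": out / "truth.csv",
    }
    write_county_table(scenario.records, paths["counties"])
    write_gal(scenario.adjacency, paths["gal"])
    scenario.truth.to_csv(paths["truth"], index=False)
    return paths


def recovery_report(
    scenario: SyntheticScenario,
    estimated_unrecruited: Mapping[tuple[str, str], float],
) -> pd.DataFrame:
    """Score estimated unrecruited counts against the scenario's ground truth.

    ``estimated_unrecruited`` maps (county_id, stratum) to the pipeline's
    final per-county unrecruited estimate.  Per stratum the report gives the
    true and estimated totals, bias, relative error, and the Spearman rank
    correlation between estimate and truth across under-recruited counties.
    """
    from scipy import stats

    rows = []
    for stratum in STRATA:
        t = scenario.truth[scenario.truth["stratum"] == stratum]
        true_total = float(t["missing"].sum())
        est_total = float(
            sum(estimated_unrecruited.get((cid, stratum), 0.0) for cid in t["county_id"])
        )
        under = t[t["underrecruited"]]
        if len(under) >= 3 and under["missing"].nunique() > 1:
            est_vec = [
                estimated_unrecruited.get((cid, stratum), 0.0)
                for cid in under["county_id"]
            ]
            if len(set(est_vec)) > 1:
                rank_corr = float(
                    stats.spearmanr(est_vec, under["missing"]).statistic
                )
            else:
                rank_corr = float("nan")
        else:
            rank_corr = float("nan")
        rows.append(
            {
                "stratum": stratum,
                "true_missing": true_total,
                "estimated_missing": est_total,
                "bias": est_total - true_total,
                "relative_error": (est_total - true_total) / true_total
                if true_total > 0
                else float("nan"),
                "rank_corr_underrecruited": rank_corr,
            }
        )
    total_true = sum(r["true_missing"] for r in rows)
    total_est = sum(r["estimated_missing"] for r in rows)
    rows.append(
        {
            "stratum": "total",
            "true_missing": total_true,
            "estimated_missing": total_est,
            "bias": total_est - total_true,
            "relative_error": (total_est - total_true) / total_true
            if total_true > 0
            else float("nan"),
            "rank_corr_underrecruited": float("nan"),
        }
    )
    return pd.DataFrame(rows).set_index("stratum")
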