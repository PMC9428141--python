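"""County-level registry tables, incidence rates, and contiguity structures.

The estimation pipeline works on one row per county x sex stratum: a base
population, the number of cases the registry recruited, and (optionally) a
mortality count used for validation.  Spatial neighbourhood structure is
exchanged in the plain-text GAL spatial-weights format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "STRATA",
    "RATE_SCALE",
    "RegistryDataError",
    "CountyStratumRecord",
    "IncidenceRate",
    "AdjacencyList",
    "read_county_table",
    "write_county_table",
    "read_gal",
    "write_gal",
    "compute_rates",
]

log = logging.getLogger(__name__)

#: Recognised sex strata.  "total" is never stored; it is derived by summation.
STRATA = ("female", "male")

#: Default rate denominator: cases per 100,000 persons per study period.
RATE_SCALE = 100_000.0

#: Canonical county-table columns.
CANONICAL_COLUMNS = (
    "county_id",
    "county_name",
    "stratum",
    "population",
    "recruited_cases",
    "mortality_cases",
)
REQUIRED_COLUMNS = ("county_id", "stratum", "population", "recruited_cases")


class RegistryDataError(ValueError):
    """Malformed or invariant-violating registry input."""


@dataclass(frozen=True)
class CountyStratumRecord:
    """One county x sex stratum observation.

    Parameters
    ----------
    county_id:
        Opaque string token identifying the county (FIPS codes recommended).
    stratum:
        ``"female"`` or ``"male"``.
    population:
        Base population of the stratum in the county; must be positive for
        any county included in estimation.
    recruited_cases:
        Number of cases the registry recruited in this stratum.
    county_name:
        Optional human-readable name.
    mortality_cases:
        Optional death count used for validation; ``None`` when unavailable.
    """

    county_id: str
    stratum: str
    population: int
    recruited_cases: int
    county_name: str = ""
    mortality_cases: int | None = None

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise RegistryDataError(
                f"stratum must be one of {STRATA}, got {self.stratum!r}"
            )
        if self.population <= 0:
            raise RegistryDataError(
                f"population must be positive for county {self.county_id!r} "
                f"({self.stratum}), got {self.population}"
            )
        if self.recruited_cases < 0:
            raise RegistryDataError(
                f"recruited_cases must be nonnegative for county "
                f"{self.county_id!r} ({self.stratum})"
            )
        if self.mortality_cases is not None and self.mortality_cases < 0:
            raise RegistryDataError(
                f"mortality_cases must be nonnegative for county "
                f"{self.county_id!r} ({self.stratum})"
            )


@dataclass(frozen=True)
class IncidenceRate:
    """Recruited-case incidence rate, cases per ``rate_scale`` persons per period."""

    county_id: str
    stratum: str
    rate: float


@dataclass(frozen=True)
class AdjacencyList:
    """Symmetric contiguity structure: county id -> set of adjacent county ids."""

    neighbors: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for i, nbrs in self.neighbors.items():
            if i in nbrs:
                raise RegistryDataError(f"self-loop on region {i!r}")
            for j in nbrs:
                if j not in self.neighbors:
                    raise RegistryDataError(
                        f"neighbor {j!r} of region {i!r} is not a declared region"
                    )
                if i not in self.neighbors[j]:
                    raise RegistryDataError(
                        f"asymmetric adjacency: {i!r} -> {j!r} but not {j!r} -> {i!r}"
                    )

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(self.neighbors)

    def degree(self, county_id: str) -> int:
        return len(self.neighbors[county_id])

    def __len__(self) -> int:
        return len(self.neighbors)

    @classmethod
    def from_dict(
        cls, neighbors: Mapping[str, Iterable[str]], symmetrize: bool = False
    ) -> "AdjacencyList":
        """Build an adjacency list, optionally symmetrizing one-way links."""
        sets: dict[str, set[str]] = {i: set(nbrs) for i, nbrs in neighbors.items()}
        for i in sets:
            sets[i].discard(i)
        if symmetrize:
            for i, nbrs in list(sets.items()):
                for j in nbrs:
                    if j in sets and i not in sets[j]:
                        log.warning("symmetrizing one-way adjacency %s -> %s", i, j)
                        sets[j].add(i)
        return cls({i: frozenset(nbrs) for i, nbrs in sets.items()})

    def check_ids(self, county_ids: Iterable[str]) -> None:
        """Require the adjacency ids and the county-table ids to coincide."""
        table = set(county_ids)
        extra = set(self.neighbors) - table
        missing = table - set(self.neighbors)
        if extra or missing:
            raise RegistryDataError(
                "adjacency/county-table id mismatch: "
                f"only in adjacency {sorted(extra)}, only in table {sorted(missing)}"
            )


def read_county_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[CountyStratumRecord]:
    """Read a county x stratum table from CSV.

    ``dialect`` maps canonical column names (``county_id``, ``stratum``,
    ``population``, ``recruited_cases``, and optionally ``county_name`` and
    ``mortality_cases``) to the column names used in the file.
    """
    dialect = dict(dialect or {})
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {canon: dialect.get(canon, canon) for canon in CANONICAL_COLUMNS}
    missing = [colmap[c] for c in REQUIRED_COLUMNS if colmap[c] not in frame.columns]
    if missing:
        raise RegistryDataError(f"missing required column(s): {missing} in {path}")

    records: list[CountyStratumRecord] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in frame.iterrows():
        rowno = int(idx) + 2  # 1-based with header line
        county = row[colmap["county_id"]].strip()
        stratum = row[colmap["stratum"]].strip().lower()
        key = (county, stratum)
        if key in seen:
            raise RegistryDataError(
                f"duplicate (county, stratum) pair {key} at row {rowno}"
            )
        seen.add(key)

        def _int(canon: str, allow_blank: bool = False) -> int | None:
            raw = row[colmap[canon]].strip() if colmap[canon] in frame.columns else ""
            if raw == "":
                if allow_blank:
                    return None
                raise RegistryDataError(f"blank {canon} at row {rowno}")
            try:
                value = int(float(raw))
            except ValueError as exc:
                raise RegistryDataError(
                    f"nonnumeric {canon} {raw!r} at row {rowno}"
                ) from exc
            if value < 0:
                raise RegistryDataError(f"negative {canon} {value} at row {rowno}")
            return value

        name = (
            row[colmap["county_name"]].strip()
            if colmap["county_name"] in frame.columns
            else ""
        )
        try:
            records.append(
                CountyStratumRecord(
                    county_id=county,
                    county_name=name,
                    stratum=stratum,
                    population=_int("population"),
                    recruited_cases=_int("recruited_cases"),
                    mortality_cases=_int("mortality_cases", allow_blank=True),
                )
            )
        except RegistryDataError as exc:
            raise RegistryDataError(f"row {rowno}: {exc}") from exc
    return records


def write_county_table(
    records: Sequence[CountyStratumRecord], path: str | Path
) -> None:
    """Write records to CSV using the canonical column names."""
    frame = pd.DataFrame(
        {
            "county_id": [r.county_id for r in records],
            "county_name": [r.county_name for r in records],
            "stratum": [r.stratum for r in records],
            "population": [r.population for r in records],
            "recruited_cases": [r.recruited_cases for r in records],
            "mortality_cases": [
                "" if r.mortality_cases is None else r.mortality_cases
                for r in records
            ],
        }
    )
    frame.to_csv(path, index=False)


def read_gal(path: str | Path) -> AdjacencyList:
    """Read a GAL spatial-weights file.

    Layout: a header line whose last-but-one or only leading integer is the
    region count, then per region an ``id n_neighbors`` line followed (when
    ``n_neighbors > 0``) by a line of neighbor ids.  Asymmetric input is
    symmetrized with a logged warning; undeclared neighbor ids are an error.
    """
    lines = Path(path).read_text().splitlines()
    numbered = [(i + 1, ln.strip()) for i, ln in enumerate(lines) if ln.strip()]
    if not numbered:
        raise RegistryDataError(f"empty GAL file {path}")
    head_no, head = numbered[0]
    tokens = head.split()
    # Header is either "n" or the GeoDa-style "0 n shapefile key".
    try:
        n_regions = int(tokens[1] if len(tokens) > 1 else tokens[0])
    except ValueError as exc:
        raise RegistryDataError(
            f"malformed GAL header at line {head_no}: {head!r}"
        ) from exc

    neighbors: dict[str, list[str]] = {}
    cursor = 1
    for _ in range(n_regions):
        if cursor >= len(numbered):
            raise RegistryDataError(f"GAL file {path} truncated: expected {n_regions} regions")
        lineno, line = numbered[cursor]
        parts = line.split()
        if len(parts) != 2:
            raise RegistryDataError(
                f"malformed region header at line {lineno}: {line!r}"
            )
        region = parts[0]
        try:
            degree = int(parts[1])
        except ValueError as exc:
            raise RegistryDataError(
                f"malformed neighbor count at line {lineno}: {parts[1]!r}"
            ) from exc
        if degree < 0:
            raise RegistryDataError(f"negative neighbor count at line {lineno}")
        cursor += 1
        nbrs: list[str] = []
        if degree > 0:
            if cursor >= len(numbered):
                raise RegistryDataError(
                    f"GAL file {path} truncated after line {lineno}"
                )
            nb_lineno, nb_line = numbered[cursor]
            nbrs = nb_line.split()
            if len(nbrs) != degree:
                raise RegistryDataError(
                    f"line {nb_lineno}: expected {degree} neighbor ids, got {len(nbrs)}"
                )
            cursor += 1
        if region in neighbors:
            raise RegistryDataError(f"duplicate region {region!r} at line {lineno}")
        neighbors[region] = nbrs

    for region, nbrs in neighbors.items():
        for j in nbrs:
            if j not in neighbors:
                raise RegistryDataError(
                    f"neighbor {j!r} of region {region!r} is not a declared region"
                )
    return AdjacencyList.from_dict(neighbors, symmetrize=True)


def write_gal(adjacency: AdjacencyList, path: str | Path) -> None:
    """Write an adjacency list in GAL format (ids sorted for determinism)."""
    ids = sorted(adjacency.neighbors)
    out = [str(len(ids))]
    for i in ids:
        nbrs = sorted(adjacency.neighbors[i])
        out.append(f"{i} {len(nbrs)}")
        if nbrs:
            out.append(" ".join(nbrs))
    Path(path).write_text("\n".join(out) + "\n")


def compute_rates(
    records: Sequence[CountyStratumRecord], rate_scale: float = RATE_SCALE
) -> list[IncidenceRate]:
    """Recruited-case incidence rates: ``cases / population * rate_scale``."""
    if rate_scale <= 0:
        raise RegistryDataError(f"rate_scale must be positive, got {rate_scale}")
    return [
        IncidenceRate(
            county_id=r.county_id,
            stratum=r.stratum,
            rate=r.recruited_cases / r.population * rate_scale,
        )
        for r in records
    ]
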