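"""Mortality-based validation of the estimated case base.

Because the disease is rapidly fatal, county-level mortality counts should
track the complete case burden, including cases the registry missed.  The
validation grid therefore computes Pearson correlations between county case
counts — recruited only, after statistical estimation, and after spatial
adjustment — and mortality counts, over target counties, non-target
counties, and all counties, per stratum and for both strata combined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gap import CountyEstimate
from .spatial import AdjustmentOutcome

__all__ = [
    "ValidationError",
    "SUBSETS",
    "CASE_BASES",
    "pearson_r",
    "ValidationTable",
    "validation_table",
]

log = logging.getLogger(__name__)

SUBSETS = ("non_target", "all", "target")
CASE_BASES = ("recruited_only", "statistical", "spatial")


class ValidationError(ValueError):
    """Validation input unusable for a correlation."""


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation with explicit degenerate-input errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValidationError(f"need at least 3 observations, got {x.size}")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ValidationError(f"vector {name} is constant; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class ValidationTable:
    """Correlation grid: (stratum, subset, case_base) -> Pearson r.

    Cells that cannot be computed (too few counties, constant vectors, or
    missing mortality) are absent rather than zero.
    """

    cells: Mapping[tuple[str, str, str], float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stratum": s, "subset": sub, "case_base": base, "pearson_r": r}
            for (s, sub, base), r in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows, columns=["stratum", "subset", "case_base", "pearson_r"])


def validation_table(
    estimates: Sequence[CountyEstimate],
    adjustments: Sequence[AdjustmentOutcome] | None,
    mortality: Mapping[tuple[str, str], int],
    target_ids: Mapping[str, set[str]],
) -> ValidationTable:
    """Build the case-count vs mortality-count correlation grid.

    ``mortality`` maps (county_id, stratum) to death counts; counties without
    mortality are dropped from every cell.  For the combined stratum the two
    sex strata are summed per county and the target set is the union of the
    per-stratum target sets.
    """
    strata = sorted({e.stratum for e in estimates})
    final: dict[tuple[str, str], float] = {}
    if adjustments is not None:
        final = {(a.county_id, a.stratum): a.final_unrecruited for a in adjustments}

    # per (county, stratum): recruited / statistical / spatial case counts
    cases: dict[tuple[str, str], tuple[float, float, float]] = {}
    for e in estimates:
        key = (e.county_id, e.stratum)
        stat = e.recruited + e.unrecruited
        spat = e.recruited + final.get(key, e.unrecruited)
        cases[key] = (float(e.recruited), stat, spat)

    counties = sorted({cid for cid, _ in cases})
    cells: dict[tuple[str, str, str], float] = {}
    for stratum in strata + ["total"]:
        if stratum == "total":
            targets = set().union(*(target_ids.get(s, set()) for s in strata))
        else:
            targets = set(target_ids.get(stratum, set()))
        for subset in SUBSETS:
            if subset == "all":
                members = counties
            elif subset == "target":
                members = [c for c in counties if c in targets]
            else:
                members = [c for c in counties if c not in targets]
            for bi, base in enumerate(CASE_BASES):
                xs, ys = [], []
                for cid in members:
                    if stratum == "total":
                        keys = [(cid, s) for s in strata]
                    else:
                        keys = [(cid, stratum)]
                    if any(k not in cases or k not in mortality for k in keys):
                        continue
                    xs.append(sum(cases[k][bi] for k in keys))
                    ys.append(sum(mortality[k] for k in keys))
                try:
                    cells[(stratum, subset, base)] = pearson_r(xs, ys)
                except ValidationError as exc:
                    log.warning(
                        "validation cell (%s, %s, %s) skipped: %s",
                        stratum,
                        subset,
                        base,
                        exc,
                    )
    return ValidationTable(cells=cells)
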