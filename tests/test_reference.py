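"""Reference-county selection: ranking, z-band, straight section, Jenks, consensus."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import registrygap as rg
from registrygap.reference import ReferenceSelectionError
from conftest import make_rates


class TestRanking:
    def test_descending_order_and_diffs(self):
        series = rg.rank_by_rate(make_rates({"A": 2, "B": 5, "C": 0}))
        assert [cid for cid, _ in series.entries] == ["B", "A", "C"]
        assert series.diffs == (3.0, 2.0)

    def test_constant_series(self):
        series = rg.rank_by_rate(make_rates({"A": 3, "B": 3, "C": 3}))
        assert series.diffs == (0.0, 0.0)
        assert series.ratios == (1.0, 1.0)

    def test_ratios(self):
        series = rg.rank_by_rate(make_rates({"A": 4, "B": 2, "C": 1}))
        assert series.ratios == (2.0, 2.0)

    def test_zero_denominator_ratio_is_nan(self):
        series = rg.rank_by_rate(make_rates({"A": 4, "B": 0}))
        assert np.isnan(series.ratios[0])

    def test_ties_broken_by_county_id(self):
        series = rg.rank_by_rate(make_rates({"B": 2, "A": 2, "C": 2}))
        assert [cid for cid, _ in series.entries] == ["A", "B", "C"]


class TestZScore:
    def test_wide_band_admits_everyone(self):
        rr = rg.zscore_reference_range(
            make_rates({"A": 0, "B": 2, "C": 3, "D": 4, "E": 10}), z_level=100
        )
        assert rr.members == {"A", "B", "C", "D", "E"}
        assert (rr.lower, rr.upper) == (0.0, 10.0)

    def test_narrow_band_observed_extremes(self):
        # mean 3, sample sd sqrt(2.5): the 0.25-band (2.6047, 3.3953)
        # admits only the rate-3 county; bounds are observed rates
        rr = rg.zscore_reference_range(
            make_rates({"A": 1, "B": 2, "C": 3, "D": 4, "E": 5}), z_level=0.25
        )
        assert rr.members == {"C"}
        assert (rr.lower, rr.upper) == (3.0, 3.0)

    def test_constant_rates_rejected(self):
        with pytest.raises(ReferenceSelectionError, match="standard deviation"):
            rg.zscore_reference_range(make_rates({"A": 2, "B": 2, "C": 2}), 0.5)

    @given(
        rates=st.lists(
            st.floats(min_value=0, max_value=50, allow_nan=False), min_size=3, max_size=30
        ),
        z_small=st.floats(min_value=0.1, max_value=1.0),
        z_extra=st.floats(min_value=0.01, max_value=2.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_z_level(self, rates, z_small, z_extra):
        rated = make_rates({f"C{i:02d}": r for i, r in enumerate(rates)})
        if np.std(rates, ddof=1) == 0:
            return
        try:
            small = rg.zscore_reference_range(rated, z_small)
        except ReferenceSelectionError:
            return  # nothing admitted at the small level
        large = rg.zscore_reference_range(rated, z_small + z_extra)
        assert small.members <= large.members


class TestStraightSection:
    def test_flat_middle_recovered(self):
        series = rg.rank_by_rate(
            make_rates(dict(zip("ABCDEFG", [10, 9, 5.1, 5.0, 4.9, 4.8, 1])))
        )
        rr = rg.straight_section(series, max_diff=0.2, max_ratio=1.1, min_length=3)
        assert rr.members == {"C", "D", "E", "F"}
        assert rr.lower == pytest.approx(4.8)
        assert rr.upper == pytest.approx(5.1)

    def test_constant_series_is_one_run(self):
        series = rg.rank_by_rate(make_rates({"A": 2, "B": 2, "C": 2, "D": 2}))
        rr = rg.straight_section(series, max_diff=0.5, max_ratio=1.1, min_length=4)
        assert rr.members == {"A", "B", "C", "D"}

    def test_steep_series_errors(self):
        series = rg.rank_by_rate(make_rates({"A": 16, "B": 8, "C": 4, "D": 2}))
        with pytest.raises(ReferenceSelectionError, match="loosen"):
            rg.straight_section(series, max_diff=0.5, max_ratio=1.1, min_length=2)

    def test_zero_rates_excluded(self):
        series = rg.rank_by_rate(make_rates({"A": 2, "B": 2, "C": 0, "D": 0}))
        rr = rg.straight_section(series, max_diff=0.5, max_ratio=1.1, min_length=2)
        assert rr.members == {"A", "B"}

    def test_three_block_series_recovers_mid_block(self):
        # hotspot block / flat mid block / low block
        rates = {
            "H1": 20.0, "H2": 18.0, "H3": 16.0,
            "M1": 5.05, "M2": 5.0, "M3": 4.95, "M4": 4.9,
            "M5": 4.85, "M6": 4.8, "M7": 4.75, "M8": 4.7,
            "L1": 2.0, "L2": 1.2, "L3": 0.5,
        }
        series = rg.rank_by_rate(make_rates(rates))
        rr = rg.straight_section(series, max_diff=0.1, max_ratio=1.05, min_length=8)
        assert rr.members == {f"M{i}" for i in range(1, 9)}


def brute_force_jenks(values, k):
    """Independent oracle: enumerate every contiguous partition."""
    vals = sorted(values)
    n = len(vals)

    def sse(seg):
        m = sum(seg) / len(seg)
        return sum((v - m) ** 2 for v in seg)

    best_cost, best_cuts = None, None
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        cost = sum(sse(vals[a:b]) for a, b in zip(bounds, bounds[1:]))
        key = (cost, cuts)
        if best_cost is None or cost < best_cost - 1e-12 or (
            abs(cost - best_cost) <= 1e-12 and cuts < best_cuts
        ):
            best_cost, best_cuts = cost, cuts
    bounds = [0, *best_cuts, n]
    return best_cost, tuple(tuple(vals[a:b]) for a, b in zip(bounds, bounds[1:]))


class TestJenks:
    def test_two_cluster_split(self):
        part = rg.jenks_breaks([1, 2, 3, 10, 11, 12], k=2)
        assert part.sections == ((1, 2, 3), (10, 11, 12))
        assert part.breaks == (10,)
        assert part.gvf == pytest.approx(4.0)

    def test_saturated_partition(self):
        part = rg.jenks_breaks([4, 1, 7], k=3)
        assert part.gvf == 0.0
        assert part.sections == ((1,), (4,), (7,))

    def test_tied_values(self):
        part = rg.jenks_breaks([1, 1, 1, 9], k=2)
        assert part.sections == ((1, 1, 1), (9,))
        assert part.gvf == 0.0

    def test_k_exceeding_distinct_values_rejected(self):
        with pytest.raises(ReferenceSelectionError, match="distinct"):
            rg.jenks_breaks([1, 1, 2], k=3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        k = int(rng.integers(2, 5))
        values = np.round(rng.uniform(0, 20, size=n), 3).tolist()
        if len(set(values)) < k:
            return
        part = rg.jenks_breaks(values, k)
        cost, sections = brute_force_jenks(values, k)
        assert part.gvf == pytest.approx(cost, abs=1e-9)
        assert part.sections == sections


class TestJenksRange:
    def test_mean_in_middle_section(self):
        rates = make_rates({f"C{v:02d}": v for v in range(1, 13)})
        part = rg.jenks_breaks([r.rate for r in rates], k=3)
        rr = rg.jenks_reference_range(part, rates)
        assert rr.members == {f"C{v:02d}" for v in range(5, 9)}

    def test_mean_in_gap_selects_higher_section(self):
        # sections {0,1}, {10,11}: mean 5.5 falls in the gap
        rates = make_rates({"A": 0, "B": 1, "C": 10, "D": 11})
        part = rg.jenks_breaks([r.rate for r in rates], k=2)
        rr = rg.jenks_reference_range(part, rates)
        assert rr.members == {"C", "D"}

    def test_mean_inside_lowest_section(self):
        # mean 10/3 sits inside the low section [0, 4]
        rates = make_rates({"A": 0, "B": 1, "C": 2, "D": 3, "E": 4, "F": 10})
        part = rg.jenks_breaks([r.rate for r in rates], k=2)
        rr = rg.jenks_reference_range(part, rates)
        assert rr.members == {"A", "B", "C", "D", "E"}


class TestConsensus:
    def _ranges(self, bounds, rates):
        return [
            rg.ReferenceRange(
                method=m,
                lower=lo,
                upper=hi,
                members=frozenset(
                    r.county_id for r in rates if lo <= r.rate <= hi
                ),
            )
            for m, (lo, hi) in zip(("zscore", "straight_section", "jenks"), bounds)
        ]

    def test_interval_intersection(self):
        rates = make_rates({"A": 2.2, "B": 3.5, "C": 4.5, "D": 6.5})
        ranges = self._ranges([(2, 6), (3, 7), (2.5, 5)], rates)
        consensus = rg.consensus_reference(ranges, rates)
        assert (consensus.lower, consensus.upper) == (3, 5)
        assert consensus.members == {"B", "C"}

    def test_idempotent_on_identical_ranges(self):
        rates = make_rates({"A": 2, "B": 4, "C": 9})
        ranges = self._ranges([(1, 5)] * 3, rates)
        consensus = rg.consensus_reference(ranges, rates)
        assert (consensus.lower, consensus.upper) == (1, 5)
        assert consensus.members == {"A", "B"}

    def test_disjoint_ranges_error_suggests_majority(self):
        rates = make_rates({"A": 1.5, "B": 5.5})
        ranges = self._ranges([(1, 2), (5, 6), (1, 6)], rates)
        with pytest.raises(ReferenceSelectionError, match="majority"):
            rg.consensus_reference(ranges, rates)

    def test_majority_rule_two_of_three(self):
        rates = make_rates({"A": 1.5, "B": 3.0, "C": 5.5})
        ranges = self._ranges([(1, 4), (2, 6), (5, 6)], rates)
        consensus = rg.consensus_reference(ranges, rates, rule="majority")
        assert consensus.members == {"B", "C"}

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_intersection_members_subset_of_inputs(self, seed):
        rng = np.random.default_rng(seed)
        rates = make_rates(
            {f"C{i:02d}": v for i, v in enumerate(rng.uniform(0, 10, 20))}
        )
        ranges = self._ranges(
            [tuple(sorted(rng.uniform(0, 10, 2))) for _ in range(3)], rates
        )
        try:
            consensus = rg.consensus_reference(ranges, rates)
        except ReferenceSelectionError:
            return
        for r in ranges:
            assert consensus.members <= set(
                x.county_id for x in rates if r.lower <= x.rate <= r.upper
            )
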