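"""EB standardization, local Moran's I, and smoothing adjustment."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import registrygap as rg
from registrygap.spatial import SpatialAdjustmentError


def eb_from_values(values):
    """Wrap raw deviation values for direct Moran testing."""
    ids = tuple(sorted(values))
    return rg.EBStandardization(
        county_ids=ids, beta=0.0, alpha=0.0, z=tuple(values[i] for i in ids)
    )


def lattice_rook(n):
    adj = {}
    for r in range(n):
        for c in range(n):
            nbrs = set()
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n and 0 <= cc < n:
                    nbrs.add(f"N{rr}{cc}")
            adj[f"N{r}{c}"] = nbrs
    return rg.AdjacencyList.from_dict(adj)


class TestEBStandardize:
    def test_uniform_rates_have_zero_deviation(self):
        eb = rg.eb_standardize(
            {"A": 2, "B": 4, "C": 8}, {"A": 100, "B": 200, "C": 400}
        )
        assert eb.beta == pytest.approx(0.02)
        assert eb.z == pytest.approx((0.0, 0.0, 0.0))

    def test_hand_computed_three_counties(self):
        # beta = 6/300, s2 = 0.0002, alpha = max(0, 0.0002 - 0.02/100) = 0
        eb = rg.eb_standardize(
            {"A": 1, "B": 1, "C": 4}, {"A": 100, "B": 100, "C": 100}
        )
        assert eb.beta == pytest.approx(0.02)
        assert eb.alpha == pytest.approx(0.0)
        assert eb.z == pytest.approx(
            (-1 / math.sqrt(2), -1 / math.sqrt(2), math.sqrt(2))
        )

    def test_dominant_county_at_overall_rate_centered(self):
        eb = rg.eb_standardize(
            {"A": 2000, "B": 0, "C": 10}, {"A": 100_000, "B": 50, "C": 100}
        )
        z = eb.as_mapping()
        assert abs(z["A"]) < abs(z["C"])
        assert z["A"] == pytest.approx(0.0, abs=0.05)


class TestLocalMoran:
    def test_constant_vector_all_ns(self, path_graph):
        eb = eb_from_values({"A": 1.0, "B": 1.0, "C": 1.0})
        results = rg.local_moran(eb, path_graph, n_perm=99, seed=0)
        assert all(m.quadrant == "NS" and m.local_i == 0.0 for m in results)

    def test_four_node_path_hand_values(self):
        # values (+1, +1, -1, -1) on a path: m2 = 1, lags (1, 0, 0, -1),
        # hence local I = (1, 0, 0, 1)
        adj = rg.AdjacencyList.from_dict(
            {"A": {"B"}, "B": {"A", "C"}, "C": {"B", "D"}, "D": {"C"}}
        )
        eb = eb_from_values({"A": 1.0, "B": 1.0, "C": -1.0, "D": -1.0})
        results = {m.county_id: m for m in rg.local_moran(eb, adj, n_perm=999, seed=0)}
        assert results["A"].local_i == pytest.approx(1.0)
        assert results["B"].local_i == pytest.approx(0.0)
        assert results["C"].local_i == pytest.approx(0.0)
        assert results["D"].local_i == pytest.approx(1.0)

    def test_checkerboard_negative_autocorrelation(self):
        adj = lattice_rook(4)
        values = {f"N{r}{c}": 1.0 if (r + c) % 2 == 0 else -1.0 for r in range(4) for c in range(4)}
        results = rg.local_moran(eb_from_values(values), adj, n_perm=999, seed=0)
        assert all(m.local_i == pytest.approx(-1.0) for m in results)
        assert all(m.quadrant in ("HL", "LH", "NS") for m in results)

    @pytest.mark.parametrize("seed", range(5))
    def test_mean_local_equals_global_moran(self, seed):
        """Anselin decomposition: mean(I_i) equals the global Moran's I
        computed by direct double summation with row-standardized weights."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 26))
        ids = [f"C{i:02d}" for i in range(n)]
        # random connected-ish graph: a ring plus random chords
        adj = {i: set() for i in ids}
        for k in range(n):
            adj[ids[k]].add(ids[(k + 1) % n])
            adj[ids[(k + 1) % n]].add(ids[k])
        for _ in range(n):
            a, b = rng.choice(n, 2, replace=False)
            adj[ids[a]].add(ids[b])
            adj[ids[b]].add(ids[a])
        adjacency = rg.AdjacencyList.from_dict(adj)
        values = dict(zip(ids, rng.normal(size=n)))
        results = rg.local_moran(eb_from_values(values), adjacency, n_perm=99, seed=seed)

        y = np.array([values[i] for i in sorted(ids)]) - np.mean(list(values.values()))
        W = np.zeros((n, n))
        sorted_ids = sorted(ids)
        for i, ci in enumerate(sorted_ids):
            nbrs = adjacency.neighbors[ci]
            for j, cj in enumerate(sorted_ids):
                if cj in nbrs:
                    W[i, j] = 1.0 / len(nbrs)
        global_i = (n / W.sum()) * (y @ W @ y) / (y @ y)
        assert np.mean([m.local_i for m in results]) == pytest.approx(global_i)

    def test_exact_permutation_matches_enumeration(self):
        """Pseudo-p from exhaustive assignment enumeration on a 5-node graph
        equals an independent itertools-based enumeration."""
        ids = ["A", "B", "C", "D", "E"]
        adj = rg.AdjacencyList.from_dict(
            {"A": {"B", "C"}, "B": {"A", "D"}, "C": {"A", "E"}, "D": {"B"}, "E": {"C"}}
        )
        values = {"A": 2.0, "B": -1.0, "C": 0.5, "D": -0.5, "E": 1.5}
        results = {
            m.county_id: m
            for m in rg.local_moran(eb_from_values(values), adj, seed=0, exact=True)
        }
        y = {k: v - np.mean(list(values.values())) for k, v in values.items()}
        for cid in ids:
            others = [y[j] for j in ids if j != cid]
            d = len(adj.neighbors[cid])
            obs = np.mean([y[j] for j in adj.neighbors[cid]])
            lags = [np.mean(p) for p in itertools.permutations(others, d)]
            if obs >= 0:
                extreme = sum(l >= obs for l in lags)
            else:
                extreme = sum(l <= obs for l in lags)
            expected_p = (extreme + 1) / (len(lags) + 1)
            assert results[cid].pseudo_p == pytest.approx(expected_p)

    def test_low_n_perm_rejected(self, path_graph):
        eb = eb_from_values({"A": 1.0, "B": 0.0, "C": -1.0})
        with pytest.raises(SpatialAdjustmentError, match="n_perm"):
            rg.local_moran(eb, path_graph, n_perm=10)

    def test_island_reported_ns(self, caplog):
        adj = rg.AdjacencyList.from_dict({"A": {"B"}, "B": {"A"}, "Z": set()})
        eb = eb_from_values({"A": 1.0, "B": -1.0, "Z": 5.0})
        with caplog.at_level("WARNING"):
            results = {m.county_id: m for m in rg.local_moran(eb, adj, n_perm=99, seed=0)}
        assert results["Z"].quadrant == "NS"
        assert "no neighbors" in caplog.text


class TestSmoothing:
    def test_constant_neighborhood(self, path_graph):
        rates = {"A": 5.0, "B": 9.0, "C": 5.0}
        pops = {"A": 10.0, "B": 20.0, "C": 30.0}
        assert rg.smooth_outlier("B", rates, pops, path_graph) == pytest.approx(5.0)

    def test_population_weighted_average(self, path_graph):
        rates = {"A": 2.0, "B": 0.0, "C": 4.0}
        pops = {"A": 100.0, "B": 1.0, "C": 300.0}
        assert rg.smooth_outlier("B", rates, pops, path_graph) == pytest.approx(3.5)

    def test_single_neighbor(self, path_graph):
        rates = {"A": 7.7, "B": 1.0, "C": 2.0}
        pops = {"A": 10.0, "B": 10.0, "C": 10.0}
        assert rg.smooth_outlier("C", rates, pops, path_graph) == pytest.approx(1.0)

    def test_include_self_option(self, path_graph):
        rates = {"A": 2.0, "B": 6.0, "C": 4.0}
        pops = {"A": 100.0, "B": 100.0, "C": 100.0}
        assert rg.smooth_outlier("B", rates, pops, path_graph, include_self=True) == pytest.approx(4.0)

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_bounded_by_neighbor_extremes(self, seed):
        graph = rg.AdjacencyList.from_dict({"A": {"B"}, "B": {"A", "C"}, "C": {"B"}})
        rng = np.random.default_rng(seed)
        rates = {k: float(r) for k, r in zip("ABC", rng.uniform(0, 10, 3))}
        pops = {k: float(p) for k, p in zip("ABC", rng.uniform(1, 1e5, 3))}
        smoothed = rg.smooth_outlier("B", rates, pops, graph)
        assert min(rates["A"], rates["C"]) <= smoothed <= max(rates["A"], rates["C"])


def _estimate(cid, stratum, recruited, mu, is_target=True):
    return rg.CountyEstimate(
        county_id=cid, stratum=stratum, is_target=is_target, recruited=recruited,
        ln_pop=10.0, eta=math.log(mu), link_se=0.1, mu=mu,
        unrecruited=max(mu - recruited, 0.0) if is_target else 0.0,
    )


def _moran(cid, quadrant):
    return rg.LocalMoranResult(
        county_id=cid, z=0.0, lag=0.0, local_i=0.0, pseudo_p=0.01, quadrant=quadrant
    )


class TestApplyAdjustment:
    def setup_method(self):
        self.adj = rg.AdjacencyList.from_dict(
            {"A": {"B"}, "B": {"A", "C"}, "C": {"B"}}
        )
        self.pops = {"A": 100_000.0, "B": 100_000.0, "C": 100_000.0}

    def test_no_outliers_pass_through(self):
        ests = [_estimate("A", "female", 2, 3.0), _estimate("B", "female", 1, 2.0)]
        ests.append(_estimate("C", "female", 5, 4.0, is_target=False))
        rates = {"A": 3.0, "B": 2.0, "C": 5.0}
        moran = [_moran(c, "NS") for c in "ABC"]
        out = rg.apply_adjustment(ests, moran, rates, self.pops, self.adj)
        assert all(o.delta_unrecruited == 0.0 for o in out)
        assert [o.final_unrecruited for o in out] == [e.unrecruited for e in ests]

    def test_lh_county_gains_cases(self):
        # B is a low outlier: expected 3.0, neighbors at rate 5 -> smoothed
        # count 5.0, so 2.0 unrecruited cases are added
        ests = [
            _estimate("A", "female", 5, 5.0, is_target=False),
            _estimate("B", "female", 1, 3.0),
            _estimate("C", "female", 5, 5.0, is_target=False),
        ]
        rates = {"A": 5.0, "B": 3.0, "C": 5.0}
        moran = [_moran("A", "NS"), _moran("B", "LH"), _moran("C", "NS")]
        out = {o.county_id: o for o in rg.apply_adjustment(ests, moran, rates, self.pops, self.adj)}
        assert out["B"].adjusted_count == pytest.approx(5.0)
        assert out["B"].delta_unrecruited == pytest.approx(2.0)
        assert out["B"].final_unrecruited == pytest.approx(4.0)

    def test_hl_clamped_at_recruited(self):
        # B high outlier: expected 6, smoothed count 2 < recruited 4 ->
        # expected clamps at recruited, unrecruited drops to 0
        ests = [
            _estimate("A", "female", 2, 2.0, is_target=False),
            _estimate("B", "female", 4, 6.0),
            _estimate("C", "female", 2, 2.0, is_target=False),
        ]
        rates = {"A": 2.0, "B": 6.0, "C": 2.0}
        moran = [_moran("A", "NS"), _moran("B", "HL"), _moran("C", "NS")]
        out = {o.county_id: o for o in rg.apply_adjustment(ests, moran, rates, self.pops, self.adj)}
        assert out["B"].adjusted_count == pytest.approx(4.0)
        assert out["B"].final_unrecruited == 0.0

    def test_non_target_outlier_untouched(self):
        ests = [
            _estimate("A", "female", 5, 5.0, is_target=False),
            _estimate("B", "female", 1, 3.0, is_target=False),
            _estimate("C", "female", 5, 5.0, is_target=False),
        ]
        rates = {"A": 5.0, "B": 3.0, "C": 5.0}
        moran = [_moran("A", "NS"), _moran("B", "LH"), _moran("C", "NS")]
        out = {o.county_id: o for o in rg.apply_adjustment(ests, moran, rates, self.pops, self.adj)}
        assert out["B"].delta_unrecruited == 0.0
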