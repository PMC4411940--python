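"""Centrality and resampling-enrichment statistics."""

import math

import numpy as np
import pytest

from mdset.core_network import GeneSet, ProteinNetwork
from mdset.enrichment import (
    betweenness,
    bottleneck_set,
    degree_enrichment_curve,
    fisher_overlap,
    log_degree_bin_fractions,
    set_overlap_enrichment,
)

from conftest import (
    brute_force_betweenness,
    enumerate_fisher_upper_tail,
    path_network,
    random_network,
    star_network,
)


class TestBetweenness:
    def test_path_center(self):
        scores = betweenness(path_network(3)).scores
        assert scores == {"v0": 0.0, "v1": 1.0, "v2": 0.0}

    def test_star_center_is_leaf_pairs(self):
        scores = betweenness(star_network(5)).scores
        assert scores["hub"] == pytest.approx(math.comb(5, 2))
        assert all(scores[f"leaf{i}"] == 0 for i in range(5))

    def test_matches_geodesic_enumeration(self, rng):
        for _ in range(4):
            net = random_network(25, 0.12, rng)
            got = betweenness(net).scores
            want = brute_force_betweenness(net)
            for v in net.nodes:
                assert got[v] == pytest.approx(want[v], abs=1e-9)


class TestBottleneckSet:
    def test_ceil_rule(self, rng):
        net = random_network(10, 0.3, rng)
        assert len(bottleneck_set(betweenness(net), 0.2)) == 2

    def test_all_equal_scores_break_ties_by_node_order(self):
        net = ProteinNetwork(nodes=[f"x{i}" for i in range(10)])
        top = bottleneck_set(betweenness(net), 0.2)
        assert top == {"x0", "x1"}

    def test_matches_sort_then_slice(self, rng):
        net = random_network(100, 0.05, rng)
        scores = betweenness(net)
        got = bottleneck_set(scores, 0.2)
        ranked = sorted(scores.scores.items(), key=lambda kv: (-kv[1], kv[0]))
        assert got == {v for v, _ in ranked[: math.ceil(0.2 * 100)]}

    def test_quantile_bounds(self, rng):
        with pytest.raises(ValueError):
            bottleneck_set(betweenness(star_network(3)), 1.0)


class TestDegreeEnrichmentCurve:
    def test_marked_everything_gives_unit_enrichment(self, rng):
        net = random_network(60, 0.1, rng)
        curve = degree_enrichment_curve(
            net, GeneSet(frozenset(net.nodes)), R=50, seed=0
        )
        assert all(e == pytest.approx(1.0) for e in curve.enrichment)

    def test_counts_are_monotone_and_nested(self, rng):
        net = random_network(150, 0.04, rng)
        marked = GeneSet(frozenset(rng.choice(net.node_order, 40, replace=False)))
        curve = degree_enrichment_curve(net, marked, R=100, seed=1)
        assert list(curve.n_geq_k) == sorted(curve.n_geq_k, reverse=True)
        assert all(m <= n for m, n in zip(curve.n_marked_geq_k, curve.n_geq_k))

    def test_fixed_seed_is_bit_identical(self, rng):
        net = random_network(80, 0.06, rng)
        marked = GeneSet(frozenset(rng.choice(net.node_order, 20, replace=False)))
        a = degree_enrichment_curve(net, marked, R=200, seed=7)
        b = degree_enrichment_curve(net, marked, R=200, seed=7)
        assert a == b

    def test_disjoint_marked_set_raises(self, rng):
        net = random_network(20, 0.2, rng)
        with pytest.raises(ValueError):
            degree_enrichment_curve(net, GeneSet(frozenset({"offnet"})), R=10)

    def test_mean_of_ratios_estimator_close_to_default(self, rng):
        net = random_network(100, 0.08, rng)
        marked = GeneSet(frozenset(rng.choice(net.node_order, 50, replace=False)))
        a = degree_enrichment_curve(net, marked, R=400, seed=3)
        b = degree_enrichment_curve(
            net, marked, R=400, seed=3, estimator="mean-of-ratios"
        )
        # with large bins the two estimators agree to first order
        assert a.enrichment[0] == pytest.approx(b.enrichment[0], rel=0.1)


class TestLogDegreeBins:
    def test_trivial_fractions(self, rng):
        net = random_network(50, 0.1, rng)
        connected = {v for v in net.nodes if net.degree(v) > 0}
        full = log_degree_bin_fractions(net, connected, connected)
        populated = full[full["n_denominator"] > 0]
        assert (populated["fraction"] == 1.0).all()
        empty = log_degree_bin_fractions(net, set(), connected)
        assert (empty[empty["n_denominator"] > 0]["fraction"] == 0.0).all()

    def test_matches_direct_recount(self, rng):
        net = random_network(120, 0.05, rng)
        den = {v for v in net.nodes if net.degree(v) > 0}
        num = set(sorted(den)[::3])
        frame = log_degree_bin_fractions(net, num, den)
        for _, row in frame.iterrows():
            in_bin = {
                v for v in den if row["bin_lo"] <= net.degree(v) < row["bin_hi"]
            }
            if in_bin:
                assert row["fraction"] == pytest.approx(
                    len(in_bin & num) / len(in_bin)
                )

    def test_subset_violation_raises(self, rng):
        net = random_network(10, 0.3, rng)
        with pytest.raises(ValueError):
            log_degree_bin_fractions(net, {"offnet"}, net.nodes)


class TestSetOverlap:
    def test_marked_everything(self, rng):
        net = random_network(30, 0.2, rng)
        target = set(net.node_order[:7])
        res = set_overlap_enrichment(net, target, GeneSet(frozenset(net.nodes)), R=50, seed=0)
        assert res.observed == 7
        assert res.ratio == pytest.approx(1.0)
        assert res.p_ge == 1.0

    def test_null_mean_matches_hypergeometric(self, rng):
        net = random_network(20, 0.3, rng)
        target = set(net.node_order[:5])
        marked = GeneSet(frozenset(net.node_order[:8]))  # any 8 labels
        res = set_overlap_enrichment(net, target, marked, R=4000, seed=2)
        expected = 5 * 8 / 20  # hypergeometric mean
        assert res.null_mean == pytest.approx(expected, abs=3 * res.null_sd / math.sqrt(4000) + 0.05)

    def test_empty_target_raises(self, rng):
        net = random_network(10, 0.3, rng)
        with pytest.raises(ValueError):
            set_overlap_enrichment(net, set(), GeneSet(frozenset(net.nodes)), R=10)

    def test_plus_one_rule_bounds(self, rng):
        net = random_network(40, 0.1, rng)
        res = set_overlap_enrichment(
            net,
            set(net.node_order[:10]),
            GeneSet(frozenset(net.node_order[20:30])),
            R=99,
            seed=5,
        )
        for p in (res.p_ge, res.p_le):
            assert 1 / 100 <= p <= 1.0


class TestFisherOverlap:
    def test_full_mdset_forces_overlap(self):
        assert fisher_overlap(20, 20, 5, 5) == pytest.approx(1.0)

    def test_degenerate_tail_is_single_table(self):
        # overlap at its maximum with tiny expectation
        p = fisher_overlap(100, 5, 5, 5)
        single = enumerate_fisher_upper_tail(100, 5, 5, 5)
        assert p == pytest.approx(single, rel=1e-12)

    def test_matches_enumeration_on_grid(self):
        for n, k, m in [(20, 8, 5), (15, 6, 6), (30, 10, 12), (12, 3, 9)]:
            for x in range(0, min(k, m) + 1):
                assert fisher_overlap(n, k, m, x) == pytest.approx(
                    enumerate_fisher_upper_tail(n, k, m, x), abs=1e-12
                )

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            fisher_overlap(10, 4, 3, 4)
        with pytest.raises(ValueError):
            fisher_overlap(10, 11, 3, 2)
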