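"""Enumeration oracles: pmf, snapshot probability, reduced score, f-cases."""

import math

import numpy as np
import pytest

from icsource import (
    EdgeMask,
    EnumerationCapError,
    NoSourceError,
    WeightedDigraph,
    exact_basic_scores,
    exact_reduced_score,
    exact_snapshot_prob,
    f_value,
    mask_pmf,
    partition_edges,
    sample_live_edge,
    bounded_distances,
)
from icsource.exact import (
    exact_constrained_mass,
    iter_positive_masks,
    nodes_reaching_all,
)
from icsource.netcore import _iter_all_masks
from conftest import random_snapshot_instance, random_weighted_digraph


class TestMaskPmf:
    def test_single_edge_present(self):
        g = WeightedDigraph([("a", "b", 0.3)])
        assert mask_pmf(g, g.full_mask()) == pytest.approx(0.3)
        assert mask_pmf(g, EdgeMask(g, [])) == pytest.approx(0.7)

    def test_half_weights_uniform(self, path3):
        for mask in _iter_all_masks(path3):
            assert mask_pmf(path3, mask) == pytest.approx(0.25)

    def test_pmf_sums_to_one(self, path3):
        assert sum(mask_pmf(path3, m) for m in _iter_all_masks(path3)) == pytest.approx(1.0)

    def test_positive_masks_pin_certain_edges(self):
        g = WeightedDigraph([("a", "b", 1.0), ("b", "c", 0.5)])
        masks = list(iter_positive_masks(g))
        assert len(masks) == 2
        assert all(("a", "b") in m.present for m, _ in masks)
        assert sum(p for _, p in masks) == pytest.approx(1.0)


class TestSnapshotProb:
    def test_full_activation_needs_full_mask(self, path3):
        assert exact_snapshot_prob(path3, "a", {"a", "b", "c"}, 2) == pytest.approx(0.25)

    def test_sink_cannot_explain_spread(self, path3):
        assert exact_snapshot_prob(path3, "c", {"a", "b", "c"}, 2) == 0

    def test_zero_time_singleton(self, path3):
        assert exact_snapshot_prob(path3, "a", {"a"}, 0) == pytest.approx(1.0)

    def test_cap_refusal(self):
        rng = np.random.default_rng(0)
        g = random_weighted_digraph(rng, 8, 12)
        with pytest.raises(EnumerationCapError):
            exact_snapshot_prob(g, g.nodes[0], set(g.nodes), 3, cap=5)

    def test_matches_naive_live_edge_sampling(self, path3):
        """The subgraph sum equals the plain Monte Carlo indicator mean."""
        n = 20_000
        rng = np.random.default_rng(13)
        active = frozenset({"a", "b", "c"})
        hits = sum(
            1
            for _ in range(n)
            if frozenset(bounded_distances(sample_live_edge(path3, rng), "a", 2))
            == active
        )
        exact = float(exact_snapshot_prob(path3, "a", active, 2))
        assert abs(hits / n - exact) <= 3 * math.sqrt(exact * (1 - exact) / n)

    def test_constant_beyond_active_size(self):
        """Once tau reaches |A| the cascade must have terminated."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            g, active, _ = random_snapshot_instance(rng, max_edges=7)
            base = {
                s: exact_snapshot_prob(g, s, active, len(active)) for s in active
            }
            for extra in (1, 3):
                for s in active:
                    assert exact_snapshot_prob(
                        g, s, active, len(active) + extra
                    ) == pytest.approx(base[s])

    def test_factorizes_over_partition(self):
        """Full-graph pmf equals the product of the three partition pmfs."""
        rng = np.random.default_rng(8)
        for _ in range(5):
            g, active, _ = random_snapshot_instance(rng, max_edges=7)
            part = partition_edges(g, active)
            pieces = [
                WeightedDigraph([(u, v, g.weight(u, v)) for u, v in es], nodes=g.nodes)
                for es in (part.e1, part.e2, part.e3)
            ]
            for mask in _iter_all_masks(g):
                prod = 1.0
                for piece in pieces:
                    sub = EdgeMask(piece, [e for e in piece.edges if e in mask.present])
                    prod *= mask_pmf(piece, sub)
                assert prod == pytest.approx(mask_pmf(g, mask))


class TestFValue:
    @pytest.fixture
    def two_active(self, path3):
        """Active = {a, b}; E2 = {(b, c)} with weight 1/2; full G1 mask."""
        active = frozenset({"a", "b"})
        part = partition_edges(path3, active)
        g1 = path3.induced_subgraph(active)
        return path3, g1.full_mask(), part, active

    def test_below_eccentricity_is_zero(self, two_active):
        g, mask1, part, active = two_active
        assert f_value(mask1, "a", 0, part, active, g=g) == 0

    def test_at_eccentricity_excludes_frontier_boundary(self, two_active):
        # eps(a) = 1 and the only boundary edge leaves b at distance 1: empty product
        g, mask1, part, active = two_active
        assert f_value(mask1, "a", 1, part, active, g=g) == pytest.approx(1.0)

    def test_above_eccentricity_uses_all_boundary(self, two_active):
        g, mask1, part, active = two_active
        assert f_value(mask1, "a", 2, part, active, g=g) == pytest.approx(0.5)

    def test_non_explaining_source_is_zero(self, two_active):
        g, mask1, part, active = two_active
        assert f_value(mask1, "b", 2, part, active, g=g) == 0


class TestReducedScore:
    def test_worked_example(self, path3):
        score = exact_reduced_score(path3, {"a", "b", "c"}, 2)
        assert float(score.scores["a"]) > 0
        assert score.scores["b"] == 0
        assert score.scores["c"] == 0

    def test_singleton_snapshot(self, path3):
        score = exact_reduced_score(path3, {"a"}, 0)
        assert score.scores["a"] == pytest.approx(1.0)

    def test_no_single_source_explanation(self):
        g = WeightedDigraph([("a", "b", 0.5), ("c", "b", 0.5)])
        with pytest.raises(NoSourceError):
            exact_reduced_score(g, {"a", "c"}, 1)

    def test_proportional_to_snapshot_prob(self):
        """Reduced expectation and full snapshot probability share one ratio."""
        rng = np.random.default_rng(31)
        for _ in range(10):
            g, active, tau = random_snapshot_instance(rng, max_edges=8)
            reduced = exact_reduced_score(g, active, tau)
            ratios = []
            for s in active:
                full = float(exact_snapshot_prob(g, s, active, tau))
                red = float(reduced.scores[s])
                assert (full > 0) == (red > 0)
                if full > 0:
                    ratios.append(full / red)
            if len(ratios) > 1:
                assert max(ratios) - min(ratios) <= 1e-9 * max(ratios)


class TestSnapshotConditionSplit:
    def test_condition_equivalence_exhaustive(self):
        """A = R(G', s, tau) iff A = R(G1', s, tau) and no early boundary edge fired."""
        rng = np.random.default_rng(12)
        for _ in range(5):
            g, active, tau = random_snapshot_instance(rng, max_edges=8)
            part = partition_edges(g, active)
            g1 = g.induced_subgraph(active)
            g1_edges = set(g1.edges)
            for mask in _iter_all_masks(g):
                m1 = EdgeMask(g1, [e for e in mask.present if e in g1_edges])
                for s in active:
                    lhs = frozenset(bounded_distances(mask, s, bound=tau)) == active
                    d1 = bounded_distances(m1, s)
                    within = frozenset(n for n, d in d1.items() if d <= tau) == active
                    no_early_fire = all(
                        d1.get(i) == tau
                        or not (set(part.e2_by_source[i]) & mask.present)
                        for i in active
                    )
                    assert lhs == (within and no_early_fire)


class TestBasicScores:
    def test_normalization_and_support(self, path3):
        score = exact_basic_scores(path3, {"a", "b", "c"}, 2)
        assert score.scores["a"] == pytest.approx(1.0)  # only the full mask explains
        assert score.scores["c"] == 0
        assert float(score.z) == pytest.approx(
            float(exact_constrained_mass(path3, {"a", "b", "c"}))
        )

    def test_reachers_bruteforce(self, path3):
        mask = path3.full_mask()
        assert nodes_reaching_all(mask, {"a", "b", "c"}) == {"a"}
        assert nodes_reaching_all(mask, {"b", "c"}) == {"a", "b"}
        assert nodes_reaching_all(EdgeMask(path3, []), {"a", "b"}) == frozenset()
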