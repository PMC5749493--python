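"""Metropolis chain: moves, stationarity ingredients, samplers, rankings."""

import math

import numpy as np
import pytest

from icsource import (
    GraphInputError,
    NoSourceError,
    WeightedDigraph,
    candidate_sources,
    exact_basic_scores,
    exact_reduced_score,
    infer_source_basic,
    infer_source_reduced,
    local_move,
    new_chain,
    rank_candidates,
)
from icsource.mcmc import SourceScores, sample_masks


class TestLocalMove:
    def test_state_stays_in_constrained_space(self, make_instance):
        rng = np.random.default_rng(2)
        g, active, _ = make_instance(rng)
        state = new_chain(g, active, seed=5, universe="g1")
        g1 = g.induced_subgraph(active)
        for _ in range(300):
            local_move(state)
            mask = state.edge_mask()
            assert candidate_sources(mask, active) != frozenset()
            # cached candidate set agrees with a from-scratch recomputation
            assert state.candidates == candidate_sources(mask, active)
        assert state.moves == 300

    def test_active_set_mismatch_rejected(self, path3):
        state = new_chain(path3, {"a", "b", "c"}, seed=0, universe="g1")
        with pytest.raises(GraphInputError):
            local_move(state, active={"a", "b"})

    def test_even_odds_toggle_always_accepted_when_in_space(self):
        """With w = 1/2 the pmf ratio is 1, so any in-space proposal passes."""
        g = WeightedDigraph([("a", "b", 0.5), ("b", "a", 0.5)])
        state = new_chain(g, {"a", "b"}, seed=3, universe="g1")
        for _ in range(500):
            local_move(state)
        # the 2-cycle space contains 3 of the 4 masks (only the empty one is
        # out), so a fair share of proposals land in-space and must all pass
        assert state.acceptance_rate() > 0.4

    def test_out_of_space_proposal_rejected(self, path3):
        # S'_1 of the full path snapshot contains only the full G1 mask,
        # so every proposal (an edge removal) must be rejected
        state = new_chain(path3, {"a", "b", "c"}, seed=1, universe="g1")
        full = state.mask
        for _ in range(200):
            local_move(state)
            assert state.mask == full
        assert state.accepted == 0

    def test_detailed_balance_on_single_edge_flips(self, make_instance):
        """pi(x) P(x->y) == pi(y) P(y->x) for every in-space neighbour pair."""
        rng = np.random.default_rng(4)
        g, active, _ = make_instance(rng, max_edges=6)
        state = new_chain(g, active, seed=0, universe="g1")
        uni = state.universe
        free = uni.free
        m = len(free)

        def pi(mask):  # unnormalised restricted pmf
            p = 1.0
            for ei, w in enumerate(uni.weights):
                p *= w if mask >> ei & 1 else 1.0 - w
            return p

        in_space = [
            mask | uni.pinned_mask
            for mask in range(1 << len(uni.edges))
            if (mask | uni.pinned_mask) == mask and uni.member(mask)
        ]
        for x in in_space:
            for ei in free:
                y = x ^ (1 << ei)
                if y not in in_space:
                    continue
                w = uni.weights[ei]
                r_xy = (w / (1 - w)) if (y >> ei & 1) else ((1 - w) / w)
                r_yx = 1.0 / r_xy
                p_xy = min(1.0, r_xy) / m
                p_yx = min(1.0, r_yx) / m
                assert pi(x) * p_xy == pytest.approx(pi(y) * p_yx)


class TestInferBasic:
    def test_worked_example(self, path3):
        scores = infer_source_basic(path3, {"a", "b", "c"}, 2, k=2_000, seed=0)
        assert scores.scores["a"] == pytest.approx(1.0)
        assert scores.scores["b"] == 0
        assert scores.scores["c"] == 0

    def test_singleton_snapshot(self, path3):
        scores = infer_source_basic(path3, {"a"}, 0, k=500, seed=0)
        assert scores.scores["a"] == pytest.approx(1.0)

    def test_unexplainable_snapshot_raises(self):
        g = WeightedDigraph([("a", "b", 0.5), ("c", "b", 0.5)])
        with pytest.raises(NoSourceError):
            infer_source_basic(g, {"a", "c"}, 2, k=100, seed=0)

    def test_matches_enumeration_oracle(self, make_instance):
        """Chain scores track the exact constrained expectations."""
        rng = np.random.default_rng(44)
        for trial in range(5):
            g, active, tau = make_instance(rng, max_edges=6)
            exact = exact_basic_scores(g, active, tau)
            mc = infer_source_basic(g, active, tau, k=40_000, seed=trial)
            for s in active:
                q = float(exact.scores[s])
                if q in (0.0, 1.0):
                    assert mc.scores[s] == q
                else:
                    assert abs(mc.scores[s] - q) <= 0.03


class TestInferReduced:
    def test_worked_example(self, path3):
        scores = infer_source_reduced(path3, {"a", "b", "c"}, 2, 2, k=1_000, seed=0)
        assert scores.scores["a"] > 0
        assert scores.scores["b"] == 0
        assert scores.scores["c"] == 0

    def test_requires_two_active_nodes(self, path3):
        with pytest.raises(GraphInputError):
            infer_source_reduced(path3, {"a"}, 1, 1, k=100, seed=0)

    def test_tau_upper_below_one_rejected(self, path3):
        with pytest.raises(GraphInputError):
            infer_source_reduced(path3, {"a", "b"}, 0, 0, k=100, seed=0)

    def test_tau_range_clipping_identity(self, make_instance):
        """tau_u beyond |A| gives bitwise the same scores as tau_u = |A|."""
        rng = np.random.default_rng(6)
        for trial in range(3):
            g, active, _ = make_instance(rng, max_edges=7)
            n = len(active)
            a = infer_source_reduced(g, active, 1, n, k=4_000, seed=trial)
            b = infer_source_reduced(g, active, 1, 5 * n, k=4_000, seed=trial)
            assert a.scores == b.scores

    def test_zero_tau_lower_accepted(self, path3):
        # the natural encoding of "nothing known before the observation"
        scores = infer_source_reduced(path3, {"a", "b", "c"}, 0, 16, k=500, seed=0)
        assert scores.scores["a"] > 0

    def test_matches_reduced_oracle_known_tau(self, make_instance):
        rng = np.random.default_rng(77)
        for trial in range(5):
            g, active, tau = make_instance(rng, max_edges=7)
            exact = exact_reduced_score(g, active, tau)
            mc = infer_source_reduced(g, active, tau, tau, k=40_000, seed=trial)
            tot_ex = sum(float(v) for v in exact.scores.values())
            tot_mc = sum(mc.scores.values())
            assert tot_mc > 0
            for s in active:
                assert abs(
                    mc.scores[s] / tot_mc - float(exact.scores[s]) / tot_ex
                ) <= 0.03

    def test_agrees_with_basic_on_clear_instances(self, make_instance):
        """Both samplers rank identically when the oracle separates the top."""
        rng = np.random.default_rng(10)
        done = 0
        while done < 3:
            g, active, tau = make_instance(rng, max_edges=7)
            exact = exact_basic_scores(g, active, tau)
            vals = sorted((float(v) for v in exact.scores.values()), reverse=True)
            k = 30_000
            sep = 6 * math.sqrt(0.25 / k)
            if len(vals) < 2 or vals[0] - vals[1] < sep:
                continue
            basic = infer_source_basic(g, active, tau, k=k, seed=done)
            reduced = infer_source_reduced(g, active, tau, tau, k=k, seed=done)
            assert rank_candidates(basic).order[0] == rank_candidates(reduced).order[0]
            done += 1

    def test_counting_consistency(self, make_instance):
        """Scores are bounded by the number of summed tau terms (est <= 1)."""
        rng = np.random.default_rng(15)
        g, active, _ = make_instance(rng, max_edges=7)
        n = len(active)
        scores = infer_source_reduced(g, active, 1, n, k=5_000, seed=0)
        for v in scores.scores.values():
            assert 0.0 <= v <= n


class TestRanking:
    def test_rank_of_truth(self):
        s = SourceScores({"a": 0.4, "b": 0.1}, k=1, tau_range=(1, 1), algorithm="x")
        assert rank_candidates(s, truth="a").rank == 1

    def test_tie_broken_lexicographically(self):
        s = SourceScores({"a": 0.2, "b": 0.2}, k=1, tau_range=(1, 1), algorithm="x")
        r = rank_candidates(s, truth="b")
        assert r.order == ["a", "b"]
        assert r.rank == 2

    def test_absent_truth_flagged_past_the_end(self):
        s = SourceScores({"a": 0.2, "b": 0.1}, k=1, tau_range=(1, 1), algorithm="x")
        r = rank_candidates(s, truth="z")
        assert r.rank == 3
        assert not r.truth_in_candidates

    def test_empty_scores_rejected(self):
        s = SourceScores({}, k=1, tau_range=(1, 1), algorithm="x")
        with pytest.raises(GraphInputError):
            rank_candidates(s)


class TestVisitFrequencies:
    def test_degenerate_space_visits_single_state(self, path3):
        counts = sample_masks(path3, {"a", "b", "c"}, k=500, seed=0, universe="g1")
        assert len(counts) == 1
        ((mask, k),) = counts.items()
        assert k == 500
        assert mask == {("a", "b"), ("b", "c")}
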