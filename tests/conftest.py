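"""Shared fixtures: the worked 3-node path and random-instance factories."""

from __future__ import annotations

import numpy as np
import pytest

from icsource import WeightedDigraph, simulate_ic


@pytest.fixture
def path3() -> WeightedDigraph:
    """The worked example: a -> b -> c with weight 1/2 on both edges."""
    return WeightedDigraph([("a", "b", 0.5), ("b", "c", 0.5)])


@pytest.fixture
def path3_certain() -> WeightedDigraph:
    """Same topology with deterministic edges."""
    return WeightedDigraph([("a", "b", 1.0), ("b", "c", 1.0)])


def random_weighted_digraph(
    rng: np.random.Generator,
    n_nodes: int = 6,
    n_edges: int = 8,
    w_lo: float = 0.2,
    w_hi: float = 0.9,
) -> WeightedDigraph:
    """A random simple digraph with weights uniform in [w_lo, w_hi]."""
    edges: set[tuple[str, str]] = set()
    tries = 0
    while len(edges) < n_edges and tries < 60 * n_edges:
        u, v = rng.integers(n_nodes, size=2)
        tries += 1
        if u != v:
            edges.add((f"v{u}", f"v{v}"))
    return WeightedDigraph(
        [(u, v, float(rng.uniform(w_lo, w_hi))) for u, v in sorted(edges)]
    )


def random_snapshot_instance(
    rng: np.random.Generator,
    max_edges: int = 8,
    min_active: int = 2,
    n_nodes_range: tuple[int, int] = (3, 7),
    min_edges: int = 3,
):
    """A random graph plus a genuine cascade snapshot (post-termination tau).

    Snapshots come from actual simulated cascades so they are always
    explainable; returns (graph, active frozenset, tau) with tau = |active|.
    """
    while True:
        n_nodes = int(rng.integers(*n_nodes_range))
        n_edges = int(rng.integers(min_edges, max_edges + 1))
        g = random_weighted_digraph(rng, n_nodes, n_edges)
        if g.n_edges() < min_edges:
            continue
        for _ in range(50):
            s = g.nodes[int(rng.integers(len(g.nodes)))]
            trace = simulate_ic(g, s, rng_seed=int(rng.integers(2**31)))
            if len(trace.active) >= min_active:
                return g, trace.active, len(trace.active)


@pytest.fixture
def make_instance():
    return random_snapshot_instance


@pytest.fixture
def make_graph():
    return random_weighted_digraph
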