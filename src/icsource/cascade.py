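"""Independent Cascade simulation, sequentially and via live-edge sampling.

The Independent Cascade (IC) process starts with a single active source at
time 0.  At every subsequent time step, each node activated at the previous
step gets exactly one chance to activate each of its still-inactive
successors, succeeding independently with the edge weight as probability.
The process stops when a step activates nobody, or at an optional horizon.

Because each edge fires at most once with a fixed probability, the coin
flips can all be made up front: retain each edge independently with its
weight ("live edges"), then every node reachable from the source in the
retained subgraph is active, with activation time equal to its hop distance
from the source.  Both formulations are implemented here and are
distributionally identical; the equivalence is property-tested.

Seeding: every public entry point takes either an integer seed or a
``numpy.random.Generator``.  Batches derive per-run child streams from one
master ``SeedSequence`` by spawning, so run ``k`` of a batch is reproducible
and independent of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

from .netcore import EdgeMask, GraphInputError, Snapshot, WeightedDigraph, bounded_distances

__all__ = [
    "CascadeTrace",
    "simulate_ic",
    "sample_live_edge",
    "trace_from_mask",
    "simulate_many",
]


@dataclass(frozen=True)
class CascadeTrace:
    """One realised cascade: who was activated, and when.

    ``activation_time`` contains only activated nodes; the source is always
    present with time 0.  ``horizon`` records the time at which the trace
    was truncated, or ``math.inf`` if the process ran to termination.
    """

    source: str
    activation_time: Mapping[str, int]
    horizon: float

    @property
    def active(self) -> frozenset[str]:
        return frozenset(self.activation_time)

    def snapshot(self, tau_lower: int | None = None, tau_upper: int | None = None) -> Snapshot:
        return Snapshot(self.active, tau_lower=tau_lower, tau_upper=tau_upper)

    def duration(self) -> int:
        """Last activation time; 0 for a cascade that never left the source."""
        return max(self.activation_time.values())

    def write(self, path: str | Path) -> None:
        lines = [f"{n}\t{t}" for n, t in sorted(self.activation_time.items())]
        Path(path).write_text("\n".join(lines) + "\n")


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_ic(
    g: WeightedDigraph,
    source: str,
    horizon: float = math.inf,
    rng_seed: int | np.random.Generator = 0,
) -> CascadeTrace:
    """Run the sequential IC process from ``source``.

    At each step the frontier nodes attempt their outgoing edges in
    canonical (sorted) order; the order is immaterial for the distribution
    because every edge fires at most once, but fixing it makes runs
    reproducible under a seed.
    """
    g.require_node(source)
    if horizon < 0:
        raise GraphInputError("horizon must be nonnegative")
    rng = _as_rng(rng_seed)
    times: dict[str, int] = {source: 0}
    frontier = [source]
    t = 0
    while frontier and t < horizon:
        t += 1
        next_frontier: list[str] = []
        for u in frontier:
            for v, w in g.successors(u):
                if v in times:
                    continue
                if w >= 1 or rng.random() < w:
                    times[v] = t
                    next_frontier.append(v)
        frontier = next_frontier
    return CascadeTrace(source=source, activation_time=times,
                        horizon=horizon if frontier else math.inf)


def sample_live_edge(
    g: WeightedDigraph, rng_seed: int | np.random.Generator = 0
) -> EdgeMask:
    """Draw a live-edge subgraph: keep each edge independently with its weight."""
    rng = _as_rng(rng_seed)
    edges = g.edges
    if not edges:
        return EdgeMask(g, ())
    u = rng.random(len(edges))
    # draws are in [0, 1) so weight-1 edges are always retained
    present = [e for e, x in zip(edges, u) if x < float(g.weight(*e))]
    return EdgeMask(g, present)


def trace_from_mask(
    mask: EdgeMask, source: str, horizon: float = math.inf
) -> CascadeTrace:
    """Cascade implied by a live-edge subgraph: activation time = hop distance."""
    mask.parent.require_node(source)
    dist = bounded_distances(mask, source, bound=horizon)
    # the trace is truncated only if the mask still had strictly farther
    # reachable nodes beyond the horizon
    full = bounded_distances(mask, source)
    truncated = len(full) > len(dist)
    return CascadeTrace(
        source=source,
        activation_time=dist,
        horizon=horizon if truncated else math.inf,
    )


def simulate_many(
    g: WeightedDigraph,
    source: str,
    n_runs: int,
    horizon: float = math.inf,
    rng_seed: int = 0,
) -> Iterator[CascadeTrace]:
    """Yield ``n_runs`` independent cascades from per-run spawned streams."""
    master = np.random.SeedSequence(rng_seed)
    for child in master.spawn(n_runs):
        yield simulate_ic(g, source, horizon=horizon,
                          rng_seed=np.random.default_rng(child))


def read_trace(path: str | Path) -> CascadeTrace:
    times: dict[str, int] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        node, t = line.split("\t")
        times[node] = int(t)
    sources = [n for n, t in times.items() if t == 0]
    if len(sources) != 1:
        raise GraphInputError("trace file must contain exactly one node at time 0")
    return CascadeTrace(source=sources[0], activation_time=times, horizon=math.inf)
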