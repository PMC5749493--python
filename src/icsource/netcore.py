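"""Weighted directed networks, live-edge subgraphs and snapshot bookkeeping.

This module holds the graph-side primitives that everything else builds on:

* :class:`WeightedDigraph` -- the contact network ``G(V, E)`` with a
  transmission probability ``w_uv`` in ``(0, 1]`` on every directed edge;
* :class:`EdgeMask` -- a live-edge subgraph ``G'`` of the network, i.e. the
  subset of edges that "fired" in one realisation of the cascade process
  (all vertices are always kept);
* :class:`Snapshot` -- the observed active set ``A_tau`` together with what
  is known about the elapsed time ``tau``;
* :class:`EdgePartition` -- the split of ``E`` into edges inside the active
  set (E1), edges leaving it (E2, further grouped by their active source
  node) and edges whose source is inactive (E3);
* bounded BFS distances, reachable sets, eccentricities and the
  candidate-source set computed via strongly-connected-component
  condensation.

Node ids are opaque strings.  All orderings -- node and edge iteration,
tie-breaks in rankings -- are lexicographic on the id so that every run is
reproducible under a fixed seed.  Unreachable nodes never get a "large
number" distance: they are simply absent from distance maps, and
infinite eccentricities are reported as ``math.inf``.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "WeightedDigraph",
    "EdgeMask",
    "Snapshot",
    "EdgePartition",
    "bounded_distances",
    "reachable_within",
    "eccentricity",
    "candidate_sources",
    "partition_edges",
    "read_edgelist",
    "write_edgelist",
    "read_snapshot",
    "write_snapshot",
]

Edge = tuple[str, str]


class GraphInputError(ValueError):
    """Raised for malformed graphs, unknown node ids or bad snapshots."""


class WeightedDigraph:
    """A weighted directed graph with edge weights in ``(0, 1]``.

    Weights are transmission probabilities: ``w_uv`` is the probability that
    an activation of ``u`` propagates along the edge ``(u, v)``.  Self-loops
    and duplicate directed edges are rejected at construction time: a
    self-loop can never change reachability and the cascade model gives each
    directed edge exactly one chance to fire, so parallel edges have no
    meaning here.

    Weights may be ``float`` or any exact numeric type supporting
    comparison and arithmetic (``fractions.Fraction`` is used by the
    hardness-reduction machinery, which needs exact dyadic probabilities).
    """

    __slots__ = ("_nodes", "_edges", "_weights", "_succ", "_index")

    def __init__(
        self,
        edges: Iterable[tuple[str, str, object]],
        nodes: Iterable[str] = (),
    ) -> None:
        weights: dict[Edge, object] = {}
        node_set: set[str] = {str(n) for n in nodes}
        for u, v, w in edges:
            u, v = str(u), str(v)
            if u == v:
                raise GraphInputError(f"self-loop on node {u!r} is not allowed")
            if (u, v) in weights:
                raise GraphInputError(f"duplicate edge ({u!r}, {v!r})")
            if not 0 < w <= 1:
                raise GraphInputError(
                    f"edge ({u!r}, {v!r}) has weight {w!r}, expected 0 < w <= 1"
                )
            weights[u, v] = w
            node_set.add(u)
            node_set.add(v)
        self._nodes: tuple[str, ...] = tuple(sorted(node_set))
        self._edges: tuple[Edge, ...] = tuple(sorted(weights))
        self._weights: dict[Edge, object] = {e: weights[e] for e in self._edges}
        succ: dict[str, list[tuple[str, object]]] = {n: [] for n in self._nodes}
        for (u, v), w in self._weights.items():
            succ[u].append((v, w))
        self._succ = {u: tuple(vs) for u, vs in succ.items()}
        self._index = {n: i for i, n in enumerate(self._nodes)}

    # -- basic accessors ---------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def edges(self) -> tuple[Edge, ...]:
        return self._edges

    @property
    def weights(self) -> Mapping[Edge, object]:
        return self._weights

    def weight(self, u: str, v: str) -> object:
        return self._weights[u, v]

    def successors(self, u: str) -> tuple[tuple[str, object], ...]:
        return self._succ[u]

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def __len__(self) -> int:
        return len(self._nodes)

    def n_edges(self) -> int:
        return len(self._edges)

    def require_node(self, node: str) -> None:
        if node not in self._index:
            raise GraphInputError(f"unknown node id {node!r}")

    # -- derived graphs ----------------------------------------------------
    def induced_subgraph(self, nodes: Iterable[str]) -> "WeightedDigraph":
        """Subgraph induced by ``nodes`` (keeps isolated members)."""
        keep = set(nodes)
        for n in keep:
            self.require_node(n)
        edges = [
            (u, v, w) for (u, v), w in self._weights.items() if u in keep and v in keep
        ]
        return WeightedDigraph(edges, nodes=keep)

    def full_mask(self) -> "EdgeMask":
        return EdgeMask(self, self._edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        for (u, v), w in self._weights.items():
            g.add_edge(u, v, weight=w)
        return g

    def undirected_networkx(self) -> nx.Graph:
        return self.to_networkx().to_undirected()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"WeightedDigraph(|V|={len(self._nodes)}, |E|={len(self._edges)})"


class EdgeMask:
    """A live-edge subgraph: a subset of the parent's edges, all vertices kept."""

    __slots__ = ("parent", "present", "_succ")

    def __init__(self, parent: WeightedDigraph, present: Iterable[Edge]) -> None:
        pres = frozenset((str(u), str(v)) for u, v in present)
        extra = pres - set(parent.edges)
        if extra:
            raise GraphInputError(f"mask contains edges not in parent: {sorted(extra)}")
        self.parent = parent
        self.present = pres
        self._succ: dict[str, tuple[str, ...]] | None = None

    def successors(self, u: str) -> tuple[str, ...]:
        if self._succ is None:
            succ: dict[str, list[str]] = {n: [] for n in self.parent.nodes}
            for a, b in sorted(self.present):
                succ[a].append(b)
            self._succ = {n: tuple(vs) for n, vs in succ.items()}
        return self._succ[u]

    def with_edge(self, edge: Edge) -> "EdgeMask":
        return EdgeMask(self.parent, self.present | {edge})

    def without_edge(self, edge: Edge) -> "EdgeMask":
        return EdgeMask(self.parent, self.present - {edge})

    def __contains__(self, edge: Edge) -> bool:
        return edge in self.present

    def __len__(self) -> int:
        return len(self.present)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EdgeMask):
            return NotImplemented
        return self.parent is other.parent and self.present == other.present

    def __hash__(self) -> int:
        return hash((id(self.parent), self.present))

    def __repr__(self) -> str:  # pragma: no cover
        return f"EdgeMask({len(self.present)}/{self.parent.n_edges()} edges)"


@dataclass(frozen=True)
class Snapshot:
    """The observed active set plus what is known about the elapsed time.

    ``tau_lower``/``tau_upper`` bound the number of time steps between the
    source's activation and the observation.  If the time is known exactly,
    set both to the same value; if nothing is known, leave both unset and
    let the inference routines fall back to their widest admissible range.
    """

    active: frozenset[str]
    tau_lower: int | None = None
    tau_upper: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "active", frozenset(str(n) for n in self.active))
        if not self.active:
            raise GraphInputError("snapshot active set must be nonempty")
        if self.tau_lower is not None and self.tau_lower < 0:
            raise GraphInputError("tau_lower must be nonnegative")
        if self.tau_upper is not None and self.tau_upper < 1:
            raise GraphInputError("tau_upper must be positive")
        if (
            self.tau_lower is not None
            and self.tau_upper is not None
            and self.tau_lower > self.tau_upper
        ):
            raise GraphInputError("tau_lower must not exceed tau_upper")

    @property
    def tau_known(self) -> int | None:
        if self.tau_lower is not None and self.tau_lower == self.tau_upper:
            return self.tau_lower
        return None


@dataclass(frozen=True)
class EdgePartition:
    """Split of the edge set by position relative to the active set.

    ``e1``: both endpoints active; ``e2``: active source, inactive
    destination; ``e3``: inactive source.  ``e2_by_source`` groups the E2
    edges by their (active) source node and has an entry -- possibly an
    empty tuple -- for every active node.
    """

    e1: tuple[Edge, ...]
    e2: tuple[Edge, ...]
    e3: tuple[Edge, ...]
    e2_by_source: Mapping[str, tuple[Edge, ...]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# reachability primitives
# ---------------------------------------------------------------------------

def bounded_distances(
    mask: EdgeMask, s: str, bound: float = math.inf
) -> dict[str, int]:
    """BFS distances from ``s`` over the mask's present edges.

    Nodes farther than ``bound`` (or unreachable) are absent from the
    returned map; ``d(s, s) = 0`` always.
    """
    mask.parent.require_node(s)
    dist = {s: 0}
    frontier = deque([s])
    while frontier:
        u = frontier.popleft()
        du = dist[u]
        if du >= bound:
            continue
        for v in mask.successors(u):
            if v not in dist:
                dist[v] = du + 1
                frontier.append(v)
    return dist


def reachable_within(mask: EdgeMask, s: str, tau: float) -> frozenset[str]:
    """The set ``{i : d(s, i) <= tau}`` of nodes reachable within ``tau`` hops."""
    return frozenset(bounded_distances(mask, s, bound=tau))


def eccentricity(mask: EdgeMask, s: str, over: Iterable[str]) -> float:
    """``max_{i in over} d(s, i)`` in the mask, ``inf`` if any is unreachable."""
    targets = set(over)
    if not targets:
        raise GraphInputError("eccentricity over an empty node set is undefined")
    for n in targets:
        mask.parent.require_node(n)
    dist = bounded_distances(mask, s)
    if not targets <= dist.keys():
        return math.inf
    return max(dist[n] for n in targets)


def candidate_sources(mask: EdgeMask, active: Iterable[str]) -> frozenset[str]:
    """Nodes from which every active node is reachable in the mask.

    Intended for the active-induced subgraph (the mask's parent node set
    equals the active set).  Uses the condensation of the mask: the
    condensation is a DAG, so it has at least one strongly connected
    component with no predecessor.  If there is exactly one such component
    it is the candidate set; if there are several, no single node can reach
    everything and the candidate set is empty.
    """
    active = frozenset(str(n) for n in active)
    if active != frozenset(mask.parent.nodes):
        raise GraphInputError(
            "candidate_sources expects a mask over the active-induced subgraph"
        )
    g = nx.DiGraph()
    g.add_nodes_from(mask.parent.nodes)
    g.add_edges_from(mask.present)
    cond = nx.condensation(g)
    roots = [c for c in cond.nodes if cond.in_degree(c) == 0]
    if len(roots) != 1:
        return frozenset()
    return frozenset(cond.nodes[roots[0]]["members"])


def partition_edges(g: WeightedDigraph, active: Iterable[str]) -> EdgePartition:
    """Classify every edge by the activity of its endpoints."""
    active = frozenset(str(n) for n in active)
    for n in active:
        g.require_node(n)
    e1: list[Edge] = []
    e2: list[Edge] = []
    e3: list[Edge] = []
    by_source: dict[str, list[Edge]] = {n: [] for n in sorted(active)}
    for u, v in g.edges:
        if u not in active:
            e3.append((u, v))
        elif v in active:
            e1.append((u, v))
        else:
            e2.append((u, v))
            by_source[u].append((u, v))
    return EdgePartition(
        e1=tuple(e1),
        e2=tuple(e2),
        e3=tuple(e3),
        e2_by_source={u: tuple(es) for u, es in by_source.items()},
    )


# ---------------------------------------------------------------------------
# text formats
# ---------------------------------------------------------------------------

def read_edgelist(path: str | Path) -> WeightedDigraph:
    """Read a graph from tab-separated ``src<TAB>dst<TAB>weight`` lines.

    Blank lines and lines starting with ``#`` are skipped.
    """
    edges = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise GraphInputError(
                f"{path}:{lineno}: expected 'src<TAB>dst<TAB>weight', got {raw!r}"
            )
        u, v, w = parts
        try:
            weight = float(w)
        except ValueError as exc:
            raise GraphInputError(f"{path}:{lineno}: bad weight {w!r}") from exc
        edges.append((u, v, weight))
    return WeightedDigraph(edges)


def write_edgelist(g: WeightedDigraph, path: str | Path) -> None:
    lines = [f"{u}\t{v}\t{g.weight(u, v)!r}" for u, v in g.edges]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_snapshot(
    path: str | Path,
    tau_lower: int | None = None,
    tau_upper: int | None = None,
) -> Snapshot:
    """Read an active set, one node id per line (``#`` comments skipped)."""
    nodes = [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.strip().startswith("#")
    ]
    return Snapshot(frozenset(nodes), tau_lower=tau_lower, tau_upper=tau_upper)


def write_snapshot(snapshot: Snapshot, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(snapshot.active)) + "\n")


def _iter_all_masks(g: WeightedDigraph) -> Iterator[EdgeMask]:
    """All ``2^|E|`` live-edge subgraphs (for tiny graphs / oracles only)."""
    edges = g.edges
    for bits in range(1 << len(edges)):
        yield EdgeMask(g, (e for i, e in enumerate(edges) if bits >> i & 1))
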