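"""Metropolis sampling over constrained live-edge subgraph spaces.

Estimating the snapshot likelihood by naive live-edge sampling fails
because almost no random subgraph explains the observation: the fraction of
subgraphs in which some node reaches the whole active set can be
exponentially small.  The samplers here therefore walk a Markov chain whose
states are exactly the *explaining* subgraphs and whose stationary law is
the live-edge distribution restricted (and renormalised) to that space.

One local move toggles a single uniformly chosen edge of the sampling
universe and accepts with the Metropolis probability ``min(1, r)`` where
``r`` is ``w/(1-w)`` for an addition and ``(1-w)/w`` for a removal; a
proposal whose result leaves the constrained space is always rejected, and
every rejection repeats the current state as a sample (required for the
stationary law to come out right).  Weight-1 edges are pinned present --
their absence has probability zero -- and are never proposed.

Two samplers are provided:

* :func:`infer_source_basic` walks subgraphs of the whole network and
  counts, per candidate, how often the candidate's ``tau``-bounded
  reachable set equals the active set exactly.
* :func:`infer_source_reduced` walks subgraphs of the active-induced
  subgraph ``G1`` only -- the chain scales with the cascade, not the
  network -- and aggregates, per candidate ``s`` and per observed
  eccentricity, the boundary deflation terms that reconstruct the
  likelihood for *every* elapsed time ``tau`` at once.  Scores for a time
  range ``[tau_l, tau_u]`` sum the per-``tau`` estimates uniformly.

Internally a subgraph is an integer bitmask over the universe's edge list,
and the per-subgraph quantities (candidate set, eccentricities, deflation
products) are memoised per visited mask, which makes revisits -- the common
case for a local-move chain -- nearly free.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .netcore import EdgeMask, GraphInputError, WeightedDigraph, partition_edges
from .exact import NoSourceError

__all__ = [
    "ChainState",
    "SourceScores",
    "RankResult",
    "local_move",
    "new_chain",
    "infer_source_basic",
    "infer_source_reduced",
    "sample_masks",
    "rank_candidates",
]

_RNG_CHUNK = 8192
_DEFAULT_CACHE_LIMIT = 1 << 19


# ---------------------------------------------------------------------------
# integer-indexed edge universe
# ---------------------------------------------------------------------------

class _Universe:
    """Shared integer-indexed view of the sampling universe.

    ``mode`` is ``"full"`` (whole network, known ``tau``) or ``"g1"``
    (active-induced subgraph, tau-free accumulators).  Nodes and edges are
    re-indexed to dense integers; a chain state is then just a bitmask over
    the free (weight < 1) edges, with pinned weight-1 edges always set.
    """

    def __init__(
        self,
        g: WeightedDigraph,
        active: frozenset[str],
        mode: str,
        tau: int | None = None,
        cache_limit: int = _DEFAULT_CACHE_LIMIT,
    ) -> None:
        self.graph = g
        self.active_ids = active
        self.mode = mode
        self.tau = tau
        base = g.induced_subgraph(active) if mode == "g1" else g
        self.base = base
        self.nodes: tuple[str, ...] = base.nodes
        self._nidx = {n: i for i, n in enumerate(self.nodes)}
        self.edges: tuple[tuple[str, str], ...] = base.edges
        self.weights = [float(base.weight(*e)) for e in self.edges]
        self.active = frozenset(self._nidx[n] for n in active if n in self._nidx)
        n = len(self.nodes)
        self.succ: list[list[tuple[int, int]]] = [[] for _ in range(n)]
        self.pred: list[list[tuple[int, int]]] = [[] for _ in range(n)]
        for ei, (u, v) in enumerate(self.edges):
            ui, vi = self._nidx[u], self._nidx[v]
            self.succ[ui].append((ei, vi))
            self.pred[vi].append((ei, ui))
        self.free = [ei for ei, w in enumerate(self.weights) if w < 1.0]
        self.pinned_mask = 0
        for ei, w in enumerate(self.weights):
            if w >= 1.0:
                self.pinned_mask |= 1 << ei
        self.full_bitmask = (1 << len(self.edges)) - 1
        # boundary (E2) deflation factors, used by the g1 accumulators
        partition = partition_edges(g, active)
        self.partition = partition
        self.boundary_factor = np.ones(n)
        for u, es in partition.e2_by_source.items():
            if u in self._nidx:
                q = 1.0
                for e in es:
                    q *= 1.0 - float(g.weight(*e))
                self.boundary_factor[self._nidx[u]] = q
        self.w_all = float(np.prod([self.boundary_factor[i] for i in self.active])) \
            if self.active else 1.0
        self._cache: dict[int, tuple | None] = {}
        self._cache_limit = cache_limit

    # -- reachability helpers on bitmasks ----------------------------------
    def _bfs(self, mask: int, s: int, bound: float) -> dict[int, int]:
        dist = {s: 0}
        frontier = [s]
        d = 0
        while frontier and d < bound:
            d += 1
            nxt = []
            for u in frontier:
                for ei, v in self.succ[u]:
                    if mask >> ei & 1 and v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        return dist

    def _ancestors_of_all_active(self, mask: int) -> list[int]:
        """Nodes from which every active node is reachable (reverse BFS)."""
        result: set[int] | None = None
        for a in self.active:
            seen = {a}
            stack = [a]
            while stack:
                u = stack.pop()
                for ei, p in self.pred[u]:
                    if mask >> ei & 1 and p not in seen:
                        seen.add(p)
                        stack.append(p)
            result = seen if result is None else result & seen
            if not result:
                return []
        return sorted(result) if result is not None else []

    def _g1_candidates(self, mask: int) -> list[int]:
        """Unique predecessor-free SCC of the condensation, or empty.

        Tarjan-style two-pass SCC on the masked adjacency.  Because every
        node of the g1 universe is active, a node explains the snapshot iff
        its component is the single root of the condensation DAG.
        """
        n = len(self.nodes)
        order: list[int] = []
        seen = [False] * n
        for r in range(n):
            if seen[r]:
                continue
            seen[r] = True
            stack: list[tuple[int, int]] = [(r, 0)]
            while stack:
                u, i = stack[-1]
                advanced = False
                while i < len(self.succ[u]):
                    ei, v = self.succ[u][i]
                    i += 1
                    if mask >> ei & 1 and not seen[v]:
                        stack[-1] = (u, i)
                        seen[v] = True
                        stack.append((v, 0))
                        advanced = True
                        break
                if not advanced:
                    if i >= len(self.succ[u]):
                        order.append(u)
                        stack.pop()
                    else:
                        stack[-1] = (u, i)
        comp = [-1] * n
        ncomp = 0
        for u in reversed(order):
            if comp[u] != -1:
                continue
            comp[u] = ncomp
            stack2 = [u]
            while stack2:
                x = stack2.pop()
                for ei, p in self.pred[x]:
                    if mask >> ei & 1 and comp[p] == -1:
                        comp[p] = ncomp
                        stack2.append(p)
            ncomp += 1
        has_pred = [False] * ncomp
        for ei, (u, v) in enumerate(self.edges):
            if mask >> ei & 1:
                cu, cv = comp[self._nidx[u]], comp[self._nidx[v]]
                if cu != cv:
                    has_pred[cv] = True
        roots = [c for c in range(ncomp) if not has_pred[c]]
        if len(roots) != 1:
            return []
        return [i for i in range(n) if comp[i] == roots[0]]

    # -- per-mask payloads --------------------------------------------------
    def payload(self, mask: int):
        """Memoised per-subgraph quantities; ``None`` iff mask leaves the space."""
        try:
            return self._cache[mask]
        except KeyError:
            pass
        value = self._compute_payload(mask)
        if len(self._cache) < self._cache_limit:
            self._cache[mask] = value
        return value

    def _compute_payload(self, mask: int):
        if self.mode == "g1":
            cands = self._g1_candidates(mask)
            if not cands:
                return None
            out = []
            for s in cands:
                dist = self._bfs(mask, s, math.inf)
                eps = max(dist[i] for i in self.active)
                term = 1.0
                for i in self.active:
                    if dist[i] < eps:
                        term *= self.boundary_factor[i]
                out.append((s, eps, term))
            return tuple(out)
        # full universe: membership witnesses + tau-exact explainers
        reachers = self._ancestors_of_all_active(mask)
        if not reachers:
            return None
        qualifying = []
        for s in self.active:
            if s not in reachers:
                continue
            dist = self._bfs(mask, s, self.tau)
            if len(dist) == len(self.active) and set(dist) == self.active:
                qualifying.append(s)
        return tuple(reachers), tuple(qualifying)

    def member(self, mask: int) -> bool:
        return self.payload(mask) is not None

    def to_edge_mask(self, mask: int) -> EdgeMask:
        return EdgeMask(self.base, (e for i, e in enumerate(self.edges) if mask >> i & 1))

    def node_id(self, i: int) -> str:
        return self.nodes[i]


# ---------------------------------------------------------------------------
# chain state and the local move
# ---------------------------------------------------------------------------

@dataclass
class ChainState:
    """Current position of the Metropolis walk.

    The mask is held as an integer bitmask; :meth:`edge_mask` materialises
    it as an :class:`~icsource.netcore.EdgeMask`.  ``moves`` counts all
    attempted moves (accepted and rejected alike), ``accepted`` only the
    accepted ones.
    """

    universe: _Universe
    mask: int
    rng: np.random.Generator
    moves: int = 0
    accepted: int = 0
    _buf_idx: np.ndarray = field(default=None, repr=False)
    _buf_u: np.ndarray = field(default=None, repr=False)
    _buf_pos: int = field(default=0, repr=False)

    def edge_mask(self) -> EdgeMask:
        return self.universe.to_edge_mask(self.mask)

    @property
    def candidates(self) -> frozenset[str]:
        """Nodes that currently explain the snapshot in this subgraph."""
        payload = self.universe.payload(self.mask)
        if payload is None:  # pragma: no cover - states are kept in-space
            return frozenset()
        if self.universe.mode == "g1":
            return frozenset(self.universe.node_id(s) for s, _, _ in payload)
        return frozenset(self.universe.node_id(s) for s in payload[0])

    def acceptance_rate(self) -> float:
        return self.accepted / self.moves if self.moves else 0.0

    def _draw(self) -> tuple[int, float]:
        if self._buf_idx is None or self._buf_pos >= len(self._buf_idx):
            self._buf_idx = self.rng.integers(
                0, len(self.universe.free), size=_RNG_CHUNK
            )
            self._buf_u = self.rng.random(_RNG_CHUNK)
            self._buf_pos = 0
        i = self._buf_pos
        self._buf_pos += 1
        return int(self._buf_idx[i]), float(self._buf_u[i])


def new_chain(
    g: WeightedDigraph,
    active: Iterable[str],
    seed: int | np.random.Generator,
    universe: str = "g1",
    tau: int | None = None,
    cache_limit: int = _DEFAULT_CACHE_LIMIT,
) -> ChainState:
    """Start a chain at the full universe subgraph (always in the space).

    Raises :class:`~icsource.exact.NoSourceError` when even the full
    subgraph admits no explaining node.
    """
    active = frozenset(str(n) for n in active)
    if not active:
        raise GraphInputError("active set must be nonempty")
    for n in active:
        g.require_node(n)
    if universe not in ("g1", "full"):
        raise GraphInputError(f"unknown sampling universe {universe!r}")
    uni = _Universe(g, active, universe, tau=tau, cache_limit=cache_limit)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = ChainState(universe=uni, mask=uni.full_bitmask, rng=rng)
    if not uni.member(state.mask):
        raise NoSourceError("no single-source explanation for the active set")
    return state


def local_move(state: ChainState, active: Iterable[str] | None = None) -> ChainState:
    """One Metropolis step; mutates and returns ``state``.

    A rejected proposal leaves the mask unchanged but still advances the
    move counter -- the repeated state is a sample.
    """
    if active is not None and frozenset(map(str, active)) != state.universe.active_ids:
        raise GraphInputError("active set does not match the chain's universe")
    uni = state.universe
    state.moves += 1
    if not uni.free:
        return state
    j, u = state._draw()
    ei = uni.free[j]
    w = uni.weights[ei]
    bit = 1 << ei
    if state.mask & bit:
        r = (1.0 - w) / w
        proposal = state.mask & ~bit
    else:
        r = w / (1.0 - w)
        proposal = state.mask | bit
    if (r >= 1.0 or u < r) and uni.member(proposal):
        state.mask = proposal
        state.accepted += 1
    return state


# ---------------------------------------------------------------------------
# scores, rankings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SourceScores:
    """Per-candidate (unnormalised) likelihood scores from one sampler run."""

    scores: Mapping[str, float]
    k: int
    tau_range: tuple[int, int]
    algorithm: str
    acceptance_rate: float = float("nan")

    def ranking(self) -> list[str]:
        return sorted(self.scores, key=lambda n: (-self.scores[n], n))

    def top(self) -> str:
        return self.ranking()[0]

    def to_tsv(self) -> str:
        lines = ["node\tscore\trank"]
        for rank, node in enumerate(self.ranking(), start=1):
            lines.append(f"{node}\t{self.scores[node]:.10g}\t{rank}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class RankResult:
    order: Sequence[str]
    rank: int
    truth_in_candidates: bool


def rank_candidates(scores: SourceScores, truth: str | None = None) -> RankResult:
    """Deterministic ranking: descending score, ties lexicographic by id.

    If ``truth`` is given but absent from the candidate set, the rank is
    reported one past the end with ``truth_in_candidates=False``.
    """
    if not scores.scores:
        raise GraphInputError("cannot rank an empty score table")
    order = scores.ranking()
    if truth is None:
        return RankResult(order=order, rank=0, truth_in_candidates=True)
    truth = str(truth)
    if truth in scores.scores:
        return RankResult(order=order, rank=order.index(truth) + 1,
                          truth_in_candidates=True)
    return RankResult(order=order, rank=len(order) + 1, truth_in_candidates=False)


def _default_burn_in(uni: _Universe) -> int:
    return 10 * max(1, len(uni.edges))


# ---------------------------------------------------------------------------
# whole-graph sampler (known tau)
# ---------------------------------------------------------------------------

def infer_source_basic(
    g: WeightedDigraph,
    active: Iterable[str],
    tau: int,
    k: int,
    seed: int | np.random.Generator = 0,
    burn_in: int | None = None,
) -> SourceScores:
    """Estimate constrained snapshot-probability scores on the whole network.

    Runs ``k`` post-burn-in local moves over all edges of ``G``; after each
    move every node whose ``tau``-bounded reachable set equals the active
    set is credited.  ``score[i] = count[i] / k`` estimates the restricted
    indicator expectation, proportional to ``Pr(A | G, i, tau)``.
    """
    if k <= 0:
        raise GraphInputError("sample count k must be positive")
    if tau < 0:
        raise GraphInputError("tau must be nonnegative")
    active = frozenset(str(n) for n in active)
    state = new_chain(g, active, seed, universe="full", tau=tau)
    uni = state.universe
    n_burn = _default_burn_in(uni) if burn_in is None else burn_in
    for _ in range(n_burn):
        local_move(state)
    counts = Counter()
    for _ in range(k):
        local_move(state)
        payload = uni.payload(state.mask)
        for s in payload[1]:
            counts[s] += 1
    scores = {n: counts.get(uni._nidx[n], 0) / k for n in sorted(active)}
    return SourceScores(scores=scores, k=k, tau_range=(tau, tau),
                        algorithm="basic", acceptance_rate=state.acceptance_rate())


# ---------------------------------------------------------------------------
# reduced sampler on G1 (known or unknown tau)
# ---------------------------------------------------------------------------

def infer_source_reduced(
    g: WeightedDigraph,
    active: Iterable[str],
    tau_lower: int,
    tau_upper: int,
    k: int,
    seed: int | np.random.Generator = 0,
    burn_in: int | None = None,
) -> SourceScores:
    """Estimate source scores from the active-induced subgraph alone.

    The chain walks explaining subgraphs of ``G1``.  For each sample and
    each candidate ``s`` therein, the accumulators record the candidate's
    eccentricity ``eps`` and the deflation product over boundary edges
    leaving nodes strictly closer than ``eps``.  From these, the score for
    any elapsed time ``tau`` is reconstructed as

        est(s, tau) = (A(s, tau) + W * sum_{tau' < tau} C(s, tau')) / k

    with ``W`` the deflation product over *all* boundary edges, and the
    reported score sums ``est`` uniformly over the integer times in
    ``[tau_lower, tau_upper]`` clipped to ``[1, |A|]`` (beyond ``|A|`` the
    cascade must have terminated, so the likelihood is constant).
    """
    if k <= 0:
        raise GraphInputError("sample count k must be positive")
    active = frozenset(str(n) for n in active)
    if len(active) < 2:
        raise GraphInputError(
            "the reduced sampler needs at least two active nodes; "
            "a single-node snapshot carries no time information"
        )
    if tau_upper < 1:
        raise GraphInputError("tau_upper must be at least 1")
    if tau_lower > tau_upper:
        raise GraphInputError("tau_lower must not exceed tau_upper")
    state = new_chain(g, active, seed, universe="g1")
    uni = state.universe
    n_burn = _default_burn_in(uni) if burn_in is None else burn_in
    for _ in range(n_burn):
        local_move(state)
    n_active = len(active)
    cand_full = uni.payload(uni.full_bitmask)
    cand_nodes = sorted(s for s, _, _ in cand_full)
    a_acc = {s: np.zeros(n_active + 1) for s in cand_nodes}
    c_acc = {s: np.zeros(n_active + 1) for s in cand_nodes}
    for _ in range(k):
        local_move(state)
        for s, eps, term in uni.payload(state.mask):
            a_acc[s][eps] += term
            c_acc[s][eps] += 1
    w_all = uni.w_all
    lo = min(max(tau_lower, 1), n_active)
    hi = min(tau_upper, n_active)
    # active nodes outside the candidate set can never explain the snapshot
    scores: dict[str, float] = {n: 0.0 for n in sorted(active)}
    for s in cand_nodes:
        cum_c = np.concatenate(([0.0], np.cumsum(c_acc[s])))  # cum_c[t] = sum_{t'<t}
        total = 0.0
        for tau in range(lo, hi + 1):
            total += (a_acc[s][tau] + w_all * cum_c[tau]) / k
        scores[uni.node_id(s)] = total
    return SourceScores(scores=scores, k=k, tau_range=(tau_lower, tau_upper),
                        algorithm="reduced", acceptance_rate=state.acceptance_rate())


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def sample_masks(
    g: WeightedDigraph,
    active: Iterable[str],
    k: int,
    seed: int | np.random.Generator = 0,
    universe: str = "g1",
    tau: int | None = None,
    burn_in: int | None = None,
) -> Counter:
    """Visit counts of the chain over subgraphs (keyed by present-edge set).

    Used to check that the empirical visit frequencies match the restricted
    live-edge law; the counts sum to ``k``.
    """
    active = frozenset(str(n) for n in active)
    state = new_chain(g, active, seed, universe=universe, tau=tau)
    n_burn = _default_burn_in(state.universe) if burn_in is None else burn_in
    for _ in range(n_burn):
        local_move(state)
    counts: Counter = Counter()
    edges = state.universe.edges
    for _ in range(k):
        local_move(state)
        key = frozenset(e for i, e in enumerate(edges) if state.mask >> i & 1)
        counts[key] += 1
    return counts
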