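"""Brute-force enumeration oracles for snapshot likelihoods.

These routines enumerate live-edge subgraphs exhaustively and are the
ground truth against which the Metropolis sampler is validated.  They are
exponential in the number of enumerated edges by necessity (the inference
problem is #P-complete), so every entry point refuses graphs above a
configurable edge cap instead of silently running forever.

Three quantities are computed:

* ``exact_snapshot_prob`` -- the probability that a cascade from ``s``
  observed after ``tau`` steps shows exactly the active set ``A``:
  the sum over all live-edge subgraphs ``G'`` of ``Pr(G') * I(A = R(G', s, tau))``
  where ``R`` is the bounded reachable set.
* ``exact_basic_scores`` -- the same indicator expectation but under the
  distribution restricted to subgraphs in which *some* node reaches all of
  ``A`` (the constrained space the whole-graph sampler walks on), i.e.
  ``exact_snapshot_prob / Z`` with ``Z`` the restricted mass.
* ``exact_reduced_score`` -- the reduced score: the expectation, over
  subgraphs of the active-induced subgraph ``G1`` that admit a single
  source, of the deflation factor ``f`` which multiplies the indicator by
  the probability that no boundary edge out of an early-activated node
  fired.  This expectation is proportional to the full snapshot
  probability, with a proportionality constant independent of the
  candidate, so it ranks candidates identically at a fraction of the cost.

Weight-1 edges are present in every subgraph of positive probability, so
they are pinned present and excluded from enumeration; this is exact and is
what makes the hardness-reduction instances (many weight-1 gadget edges)
enumerable.  All arithmetic preserves the weight type: with
``fractions.Fraction`` weights the results are exact rationals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

from .netcore import (
    EdgeMask,
    EdgePartition,
    GraphInputError,
    WeightedDigraph,
    bounded_distances,
    candidate_sources,
    partition_edges,
)

__all__ = [
    "ExactScore",
    "EnumerationCapError",
    "mask_pmf",
    "iter_positive_masks",
    "exact_snapshot_prob",
    "exact_basic_scores",
    "exact_constrained_mass",
    "nodes_reaching_all",
    "f_value",
    "exact_reduced_score",
]

DEFAULT_ENUM_CAP = 20


class EnumerationCapError(ValueError):
    """The graph has too many free edges for exhaustive enumeration."""


class NoSourceError(ValueError):
    """No node can reach the whole active set: no single-source explanation."""


@dataclass(frozen=True)
class ExactScore:
    """Per-candidate exact scores with their normalisation constant.

    ``kind`` is ``"basic"`` for the constrained indicator expectation over
    full-graph subgraphs and ``"reduced"`` for the deflated expectation over
    subgraphs of the active-induced subgraph.  ``z`` is the probability mass
    of the constrained subgraph space (positive whenever it is nonempty).
    """

    scores: Mapping[str, object]
    z: object
    kind: str

    def ranking(self) -> list[str]:
        return sorted(self.scores, key=lambda n: (-float(self.scores[n]), n))

    def argmax_set(self) -> frozenset[str]:
        """All maximisers, compared with the native (possibly exact) arithmetic."""
        best = max(self.scores.values())
        return frozenset(n for n, v in self.scores.items() if v == best)

    def to_tsv(self) -> str:
        lines = ["node\tscore\trank"]
        for rank, node in enumerate(self.ranking(), start=1):
            lines.append(f"{node}\t{self.scores[node]}\t{rank}")
        return "\n".join(lines) + "\n"


def mask_pmf(g: WeightedDigraph, mask: EdgeMask) -> object:
    """Probability of one live-edge subgraph: prod of w if present else 1-w."""
    if mask.parent is not g:
        raise GraphInputError("mask does not belong to the given graph")
    p = 1
    for e in g.edges:
        w = g.weight(*e)
        p *= w if e in mask.present else 1 - w
    return p


def _split_pinned(g: WeightedDigraph) -> tuple[list, list]:
    """Edges with weight exactly 1 (always live) vs. free edges."""
    pinned = [e for e in g.edges if g.weight(*e) == 1]
    free = [e for e in g.edges if g.weight(*e) != 1]
    return pinned, free


def iter_positive_masks(
    g: WeightedDigraph, cap: int = DEFAULT_ENUM_CAP
) -> Iterator[tuple[EdgeMask, object]]:
    """All live-edge subgraphs of positive probability, with their pmf.

    Enumerates only edges of weight < 1 (``2^n_free`` subgraphs); weight-1
    edges are pinned present.  The pmfs sum to one.
    """
    pinned, free = _split_pinned(g)
    if len(free) > cap:
        raise EnumerationCapError(
            f"{len(free)} free edges exceed the enumeration cap of {cap}; "
            "use the Monte Carlo sampler instead"
        )
    weights = [g.weight(*e) for e in free]
    for bits in range(1 << len(free)):
        present = list(pinned)
        p = 1
        for i, (e, w) in enumerate(zip(free, weights)):
            if bits >> i & 1:
                present.append(e)
                p *= w
            else:
                p *= 1 - w
        yield EdgeMask(g, present), p


def nodes_reaching_all(mask: EdgeMask, active: Iterable[str]) -> frozenset[str]:
    """All parent-graph nodes from which every active node is reachable.

    Computed as the intersection over active nodes of their ancestor sets
    (reverse BFS), which is cheap on the small graphs the oracles accept.
    """
    active = [str(n) for n in active]
    for n in active:
        mask.parent.require_node(n)
    pred: dict[str, list[str]] = {n: [] for n in mask.parent.nodes}
    for u, v in mask.present:
        pred[v].append(u)
    result: set[str] | None = None
    for a in active:
        seen = {a}
        stack = [a]
        while stack:
            u = stack.pop()
            for p in pred[u]:
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        result = seen if result is None else result & seen
        if not result:
            return frozenset()
    return frozenset(result if result is not None else ())


def exact_snapshot_prob(
    g: WeightedDigraph,
    s: str,
    active: Iterable[str],
    tau: int,
    cap: int = DEFAULT_ENUM_CAP,
) -> object:
    """Exact probability that the snapshot after ``tau`` steps equals ``active``."""
    g.require_node(s)
    active = frozenset(str(n) for n in active)
    total = 0
    for mask, p in iter_positive_masks(g, cap=cap):
        if frozenset(bounded_distances(mask, s, bound=tau)) == active:
            total += p
    return total


def exact_constrained_mass(
    g: WeightedDigraph, active: Iterable[str], cap: int = DEFAULT_ENUM_CAP
) -> object:
    """Mass ``Z`` of subgraphs in which some node reaches the whole active set."""
    active = frozenset(str(n) for n in active)
    z = 0
    for mask, p in iter_positive_masks(g, cap=cap):
        if nodes_reaching_all(mask, active):
            z += p
    return z


def exact_basic_scores(
    g: WeightedDigraph,
    active: Iterable[str],
    tau: int,
    cap: int = DEFAULT_ENUM_CAP,
) -> ExactScore:
    """Constrained indicator expectation for every node, by full enumeration.

    This is the quantity the whole-graph Metropolis sampler estimates:
    ``Pr(A | G, s, tau) / Z`` with ``Z`` the mass of the constrained space.
    """
    active = frozenset(str(n) for n in active)
    for n in active:
        g.require_node(n)
    z = 0
    num: dict[str, object] = {n: 0 for n in g.nodes}
    for mask, p in iter_positive_masks(g, cap=cap):
        if not nodes_reaching_all(mask, active):
            continue
        z += p
        # only active nodes can satisfy R(mask, s, tau) == active (s is in R)
        for s in active:
            if frozenset(bounded_distances(mask, s, bound=tau)) == active:
                num[s] += p
    if z == 0:
        raise NoSourceError("no single-source explanation for the active set")
    return ExactScore(scores={n: v / z for n, v in num.items()}, z=z, kind="basic")


def _boundary_factors(
    g: WeightedDigraph, partition: EdgePartition
) -> dict[str, object]:
    """Per active node, prod of (1-w) over its outgoing boundary (E2) edges."""
    factors: dict[str, object] = {}
    for u, es in partition.e2_by_source.items():
        q = 1
        for e in es:
            q *= 1 - g.weight(*e)
        factors[u] = q
    return factors


def f_value(
    mask1: EdgeMask,
    s: str,
    tau: int,
    partition: EdgePartition,
    active: Iterable[str],
    g: WeightedDigraph | None = None,
) -> object:
    """Deflated indicator ``f(G1', s, tau)`` for one subgraph of ``G1``.

    Value is 0 unless ``s`` reaches the whole active set within ``tau``
    hops in ``mask1``.  Otherwise it is the probability that no boundary
    edge fired out of any node activated strictly before ``tau``: at
    ``tau`` equal to the eccentricity of ``s`` only nodes strictly closer
    than the eccentricity contribute, and for any larger ``tau`` every
    boundary edge contributes (the value ``W``), independent of ``tau``.
    """
    active = frozenset(str(n) for n in active)
    weights = g if g is not None else mask1.parent
    dist = bounded_distances(mask1, s)
    if not active <= dist.keys():
        return 0
    eps = max(dist[n] for n in active)
    if tau < eps:
        return 0
    factors = _boundary_factors(weights, partition)
    value = 1
    if tau == eps:
        for n in active:
            if dist[n] < eps:
                value *= factors.get(n, 1)
    else:
        for n in active:
            value *= factors.get(n, 1)
    return value


def exact_reduced_score(
    g: WeightedDigraph,
    active: Iterable[str],
    tau: int,
    cap: int = DEFAULT_ENUM_CAP,
) -> ExactScore:
    """Exact reduced score by enumerating subgraphs of the active-induced graph.

    Proportional to ``exact_snapshot_prob`` for every candidate (the
    constant is the restricted mass of the constrained ``G1`` subgraph
    space), which is what makes ranking on ``G1`` alone sufficient.
    """
    active = frozenset(str(n) for n in active)
    for n in active:
        g.require_node(n)
    g1 = g.induced_subgraph(active)
    partition = partition_edges(g, active)
    z1 = 0
    num: dict[str, object] = {n: 0 for n in sorted(active)}
    for mask1, p1 in iter_positive_masks(g1, cap=cap):
        if not candidate_sources(mask1, active):
            continue
        z1 += p1
        for s in active:
            fv = f_value(mask1, s, tau, partition, active, g=g)
            if fv:
                num[s] += p1 * fv
    if z1 == 0:
        raise NoSourceError("no single-source explanation for the active set")
    return ExactScore(scores={n: v / z1 for n, v in num.items()}, z=z1, kind="reduced")
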