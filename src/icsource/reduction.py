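"""Executable #P-hardness reduction: s-t connectedness to source inference.

The s-t connectedness problem asks, for a directed graph ``Ghat`` and two
of its nodes ``s`` and ``t``, how many of the ``2^|Ehat|`` edge subsets
contain a path from ``s`` to ``t``.  It is a canonical #P-complete counting
problem, and source inference inherits that hardness through the gadget
built here:

* every original edge gets weight 1/2;
* two fresh nodes ``v`` and ``u`` are added, with ``t -> v`` (weight 1),
  ``v -> u`` (weight ``p``), ``u -> s`` (weight 1) and ``v -> i``
  (weight 1) for every original node ``i``;
* the observed snapshot is *all* nodes, with elapsed time ``|V|`` (so only
  reachability matters, never distances).

On this instance the snapshot likelihood of ``v`` and of ``t`` is exactly
``p``; every other original node scores strictly below ``p``; and the
likelihood of ``u`` equals ``Connectedness(Ghat, s, t) * (1/2)^|Ehat|``.
Hence asking an exact source-inference oracle whether ``u`` attains the
maximum, for a binary-searched sequence of dyadic values of ``p``, recovers
the exact connectedness count in about ``|Ehat|`` oracle calls -- a
polynomial-time Turing reduction, demonstrated end to end below.

All probabilities here are dyadic rationals; the oracle queries compare
``fractions.Fraction`` values, so argmax ties are decided exactly, never by
floating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .netcore import GraphInputError, WeightedDigraph
from .exact import DEFAULT_ENUM_CAP, ExactScore, iter_positive_masks
from .netcore import bounded_distances

__all__ = [
    "ReductionInstance",
    "build_instance",
    "count_connectedness_bruteforce",
    "solve_connectedness_via_oracle",
    "instance_scores",
]

AUX_V = "__v__"
AUX_U = "__u__"


@dataclass(frozen=True)
class ReductionInstance:
    """A source-inference instance encoding an s-t connectedness question."""

    graph: WeightedDigraph
    active: frozenset[str]
    tau: int
    s: str
    t: str
    v: str
    u: str
    p: Fraction
    n_original_edges: int


def build_instance(
    ghat: WeightedDigraph, s: str, t: str, p: Fraction | float
) -> ReductionInstance:
    """Build the gadget instance from an s-t connectedness input.

    ``ghat``'s weights are ignored: the gadget fixes every original edge at
    weight 1/2.  ``p`` must lie strictly between 0 and 1.
    """
    ghat.require_node(s)
    ghat.require_node(t)
    if s == t:
        raise GraphInputError(
            "s and t must differ: with s = t every edge subset connects them"
        )
    p = Fraction(p)
    if not 0 < p < 1:
        raise GraphInputError("parameter p must satisfy 0 < p < 1")
    half = Fraction(1, 2)
    one = Fraction(1)
    edges: list[tuple[str, str, Fraction]] = [(a, b, half) for a, b in ghat.edges]
    edges.append((t, AUX_V, one))
    edges.append((AUX_V, AUX_U, p))
    edges.append((AUX_U, s, one))
    for i in ghat.nodes:
        edges.append((AUX_V, i, one))
    g = WeightedDigraph(edges)
    return ReductionInstance(
        graph=g,
        active=frozenset(g.nodes),
        tau=len(g.nodes),
        s=s,
        t=t,
        v=AUX_V,
        u=AUX_U,
        p=p,
        n_original_edges=ghat.n_edges(),
    )


def count_connectedness_bruteforce(
    ghat: WeightedDigraph, s: str, t: str, cap: int = DEFAULT_ENUM_CAP
) -> int:
    """Count edge subsets of ``ghat`` containing a path from ``s`` to ``t``."""
    ghat.require_node(s)
    ghat.require_node(t)
    if ghat.n_edges() > cap:
        raise GraphInputError(
            f"{ghat.n_edges()} edges exceed the enumeration cap of {cap}"
        )
    edges = ghat.edges
    count = 0
    for bits in range(1 << len(edges)):
        succ: dict[str, list[str]] = {}
        for i, (a, b) in enumerate(edges):
            if bits >> i & 1:
                succ.setdefault(a, []).append(b)
        seen = {s}
        stack = [s]
        while stack:
            x = stack.pop()
            if x == t:
                break
            for y in succ.get(x, ()):
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if t in seen:
            count += 1
    return count


def instance_scores(inst: ReductionInstance, cap: int = DEFAULT_ENUM_CAP) -> ExactScore:
    """Exact snapshot likelihood of every node of a gadget instance.

    Weight-1 gadget edges are pinned by the enumerator, so only the
    ``|Ehat| + 1`` coin-flip edges are enumerated; the scores are exact
    ``Fraction`` values.
    """
    g = inst.graph
    scores: dict[str, Fraction] = {}
    masks = list(iter_positive_masks(g, cap=cap))
    active = inst.active
    for node in g.nodes:
        total = Fraction(0)
        for mask, pmass in masks:
            if frozenset(bounded_distances(mask, node, bound=inst.tau)) == active:
                total += pmass
        scores[node] = total
    z = sum(scores.values())
    return ExactScore(scores=scores, z=z if z else Fraction(1), kind="basic")


def solve_connectedness_via_oracle(
    ghat: WeightedDigraph,
    s: str,
    t: str,
    cap: int = DEFAULT_ENUM_CAP,
    return_queries: bool = False,
) -> int | tuple[int, int]:
    """Recover the connectedness count via binary search over oracle calls.

    Maintains an integer interval known to contain the count.  Each step
    sets ``p = mid * (1/2)^|Ehat|``, builds the gadget, asks the exact
    oracle for the full argmax set, and keeps the half of the interval
    consistent with whether ``u`` attains the maximum (``u`` is maximal
    iff the count is at least ``mid``).  The number of oracle queries is at
    most ``|Ehat| + 1``.
    """
    ghat.require_node(s)
    ghat.require_node(t)
    if s == t:
        raise GraphInputError("s and t must differ")
    m = ghat.n_edges()
    if m == 0:
        return (0, 0) if return_queries else 0
    scale = Fraction(1, 2) ** m
    lo, hi = 0, (1 << m) - 1  # the empty subset never connects s != t
    queries = 0
    while lo < hi:
        mid = (lo + hi + 1) // 2
        inst = build_instance(ghat, s, t, mid * scale)
        queries += 1
        score = instance_scores(inst, cap=cap)
        if inst.u in score.argmax_set():
            lo = mid
        else:
            hi = mid - 1
    return (lo, queries) if return_queries else lo
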