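"""Synthetic networks, cascade trials and the evaluation protocol.

No external dataset ships with the package: benchmark networks are drawn
from standard random-graph models and weighted either uniformly, uniformly
at random in an interval, or by the reciprocal of the destination's
in-degree -- the convention for turning an unweighted social graph into an
influence network (a node voted for, followed or linked by many peers is
proportionally harder for any single one of them to influence).

A *trial* draws a uniformly random source, simulates one cascade, snapshots
it, and retains it only if the snapshot has at least two active nodes and
at least ``min_candidates`` candidate sources (nodes that reach the whole
active set inside the active-induced subgraph).  The candidate-set filter
keeps the trials from being trivial: a cascade with one candidate is solved
by the filter itself.  Retained trials are scored by

* **error distance** -- shortest-path distance between the inferred and the
  true source with edge directions ignored;
* **rank** -- 1-based position of the true source in the deterministic
  ranking (descending score, ties lexicographic);
* **relative rank** -- rank divided by the candidate-set size.

A uniform draw from the active set serves as the random-guess baseline.
"""

from __future__ import annotations

import math
import time
from dataclasses import asdict, dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .cascade import CascadeTrace, simulate_ic
from .exact import exact_reduced_score
from .mcmc import infer_source_basic, infer_source_reduced, rank_candidates
from .netcore import (
    GraphInputError,
    Snapshot,
    WeightedDigraph,
    candidate_sources,
)

__all__ = [
    "TrialRecord",
    "TrialBudgetError",
    "generate_network",
    "generate_trial",
    "candidate_set",
    "error_distance",
    "run_trials",
    "summarize",
]


class TrialBudgetError(RuntimeError):
    """Raised when no acceptable cascade was generated within the budget."""


def _node_name(i: int, width: int) -> str:
    return f"n{i:0{width}d}"


def _weight_edges(
    edges: list[tuple[str, str]],
    weighting,
    rng: np.random.Generator,
) -> list[tuple[str, str, float]]:
    if weighting == "reciprocal_in_degree":
        indeg: dict[str, int] = {}
        for _, v in edges:
            indeg[v] = indeg.get(v, 0) + 1
        return [(u, v, 1.0 / indeg[v]) for u, v in edges]
    if isinstance(weighting, tuple) and weighting and weighting[0] == "uniform":
        w = float(weighting[1])
        if not 0 < w <= 1:
            raise GraphInputError("uniform weight must be in (0, 1]")
        return [(u, v, w) for u, v in edges]
    if isinstance(weighting, tuple) and weighting and weighting[0] == "random":
        a, b = float(weighting[1]), float(weighting[2])
        if not 0 < a <= b <= 1:
            raise GraphInputError("random weight bounds must satisfy 0 < a <= b <= 1")
        ws = rng.uniform(a, b, size=len(edges))
        return [(u, v, float(w)) for (u, v), w in zip(edges, ws)]
    raise GraphInputError(f"unknown weighting rule {weighting!r}")


def generate_network(
    model: str,
    n: int,
    params: Mapping | None = None,
    weighting="reciprocal_in_degree",
    seed: int = 0,
) -> WeightedDigraph:
    """Draw a directed network and attach edge weights.

    Models: ``erdos_renyi`` (directed G(n, p), param ``p``),
    ``barabasi_albert`` (preferential attachment, param ``m``; each
    undirected edge is kept in both directions so that in-degree weighting
    is meaningful), ``linear`` (the path v1 -> v2 -> ... -> vn), and
    ``custom`` (param ``edges``: explicit (src, dst) pairs).
    """
    if n < 2:
        raise GraphInputError("need at least two nodes")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    width = len(str(n - 1))
    names = [_node_name(i, width) for i in range(n)]
    if model == "linear":
        edges = [(names[i], names[i + 1]) for i in range(n - 1)]
    elif model == "erdos_renyi":
        p = float(params.get("p", 0.1))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)), directed=True)
        edges = [(names[u], names[v]) for u, v in g.edges]
    elif model == "barabasi_albert":
        m = int(params.get("m", 2))
        g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
        edges = []
        for u, v in g.edges:
            edges.append((names[u], names[v]))
            edges.append((names[v], names[u]))
    elif model == "custom":
        edges = [(str(u), str(v)) for u, v in params["edges"]]
    else:
        raise GraphInputError(f"unknown network model {model!r}")
    if not edges:
        raise GraphInputError("generated network has no edges; raise p or m")
    return WeightedDigraph(_weight_edges(edges, weighting, rng))


def candidate_set(g: WeightedDigraph, active: Iterable[str]) -> frozenset[str]:
    """Candidate sources: nodes reaching the whole active set within G1."""
    active = frozenset(str(a) for a in active)
    g1 = g.induced_subgraph(active)
    return candidate_sources(g1.full_mask(), active)


def generate_trial(
    g: WeightedDigraph,
    min_candidates: int = 20,
    horizon: float = math.inf,
    seed: int = 0,
    max_attempts: int = 1000,
) -> tuple[str, Snapshot, CascadeTrace]:
    """Draw one retained cascade trial: (true source, snapshot, trace).

    Sources are uniform over nodes; a cascade is rejected and redrawn if it
    activates fewer than two nodes or yields fewer than ``min_candidates``
    candidate sources.
    """
    if min_candidates < 1:
        raise GraphInputError("min_candidates must be at least 1")
    master = np.random.SeedSequence(seed)
    for attempt, child in enumerate(master.spawn(max_attempts), start=1):
        rng = np.random.default_rng(child)
        source = g.nodes[int(rng.integers(len(g.nodes)))]
        trace = simulate_ic(g, source, horizon=horizon, rng_seed=rng)
        if len(trace.active) < 2:
            continue
        cands = candidate_set(g, trace.active)
        if len(cands) < min_candidates:
            continue
        return source, trace.snapshot(), trace
    raise TrialBudgetError(
        f"no cascade with >= {min_candidates} candidates and >= 2 active nodes "
        f"in {max_attempts} attempts on a {len(g.nodes)}-node network; "
        "relax min_candidates or use a denser network"
    )


def error_distance(g: WeightedDigraph, inferred: str, truth: str) -> float:
    """Shortest-path hops between nodes, ignoring edge direction; inf if apart."""
    g.require_node(inferred)
    g.require_node(truth)
    try:
        return float(
            nx.shortest_path_length(g.undirected_networkx(), inferred, truth)
        )
    except nx.NetworkXNoPath:
        return math.inf


@dataclass(frozen=True)
class TrialRecord:
    """Outcome of one retained trial."""

    trial: int
    seed: int
    true_source: str
    n_active: int
    n_candidates: int
    inferred: str
    error_distance: float
    rank: int
    relative_rank: float
    random_guess_distance: float
    tau_observed: int
    tau_lower: int
    tau_upper: int
    runtime_s: float


def _observed_tau(trace: CascadeTrace, horizon: float) -> int:
    # post-termination snapshots use the conservative elapsed time |A|;
    # a finite horizon is itself the elapsed time
    return int(horizon) if math.isfinite(horizon) else len(trace.active)


def run_trials(config: Mapping) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run a reproducible batch of trials; returns (records, summary).

    ``config`` keys (defaults in parentheses):

    - ``graph``: dict passed to :func:`generate_network` --
      ``model`` ("erdos_renyi"), ``n`` (100), ``params``, ``weighting``;
    - ``trials`` (20): number of retained trials;
    - ``min_candidates`` (1), ``horizon`` (inf), ``max_attempts`` (1000);
    - ``tau_mode``: "known" (default) or "range"; in range mode the input
      range is ``[0, range_factor * tau_observed]`` with ``range_factor`` (2);
    - ``algorithm``: "reduced" (default), "basic", or "exact";
    - ``k`` (10000): Monte Carlo samples per trial; ``burn_in`` (None);
    - ``seed`` (0): master seed; trial t uses an independent spawned stream.
    """
    graph_cfg = dict(config.get("graph", {}))
    model = graph_cfg.pop("model", "erdos_renyi")
    n = int(graph_cfg.pop("n", 100))
    n_trials = int(config.get("trials", 20))
    min_candidates = int(config.get("min_candidates", 1))
    horizon = config.get("horizon", math.inf)
    horizon = math.inf if horizon in (None, "inf") else float(horizon)
    tau_mode = config.get("tau_mode", "known")
    range_factor = float(config.get("range_factor", 2))
    algorithm = config.get("algorithm", "reduced")
    k = int(config.get("k", 10_000))
    burn_in = config.get("burn_in")
    master_seed = int(config.get("seed", 0))
    max_attempts = int(config.get("max_attempts", 1000))

    g = generate_network(
        model,
        n,
        params=graph_cfg.pop("params", None),
        weighting=graph_cfg.pop("weighting", "reciprocal_in_degree"),
        seed=master_seed,
    )
    seeds = np.random.SeedSequence(master_seed).spawn(n_trials)
    records: list[TrialRecord] = []
    for t, child in enumerate(seeds):
        t0 = time.perf_counter()
        trial_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            source, snapshot, trace = generate_trial(
                g,
                min_candidates=min_candidates,
                horizon=horizon,
                seed=trial_seed,
                max_attempts=max_attempts,
            )
        except TrialBudgetError as exc:
            raise TrialBudgetError(f"trial {t}: {exc}") from exc
        tau_obs = _observed_tau(trace, horizon)
        if tau_mode == "known":
            tau_lo = tau_hi = tau_obs
        elif tau_mode == "range":
            tau_lo, tau_hi = 0, max(1, int(range_factor * tau_obs))
        else:
            raise GraphInputError(f"unknown tau_mode {tau_mode!r}")
        if algorithm == "reduced":
            scores = infer_source_reduced(
                g, snapshot.active, tau_lo, tau_hi, k=k,
                seed=np.random.default_rng(child.spawn(1)[0]), burn_in=burn_in,
            )
        elif algorithm == "basic":
            scores = infer_source_basic(
                g, snapshot.active, tau_obs, k=k,
                seed=np.random.default_rng(child.spawn(1)[0]), burn_in=burn_in,
            )
        elif algorithm == "exact":
            scores = exact_reduced_score(g, snapshot.active, tau_obs)
        else:
            raise GraphInputError(f"unknown algorithm {algorithm!r}")
        cands = candidate_set(g, snapshot.active)
        ranked = rank_candidates(scores, truth=source)
        inferred = ranked.order[0]
        guess_rng = np.random.default_rng(child.spawn(1)[0])
        guess = sorted(snapshot.active)[int(guess_rng.integers(len(snapshot.active)))]
        records.append(
            TrialRecord(
                trial=t,
                seed=trial_seed,
                true_source=source,
                n_active=len(snapshot.active),
                n_candidates=len(cands),
                inferred=inferred,
                error_distance=error_distance(g, inferred, source),
                rank=ranked.rank,
                relative_rank=ranked.rank / max(1, len(cands)),
                random_guess_distance=error_distance(g, guess, source),
                tau_observed=tau_obs,
                tau_lower=tau_lo,
                tau_upper=tau_hi,
                runtime_s=time.perf_counter() - t0,
            )
        )
    df = pd.DataFrame([asdict(r) for r in records]).sort_values("trial")
    return df.reset_index(drop=True), summarize(df)


def summarize(records: pd.DataFrame, top_ks: Iterable[int] = (1, 2, 4, 10)) -> pd.DataFrame:
    """Summary table: distance/rank histograms and top-k hit fractions."""
    rows = []
    for d, c in records["error_distance"].value_counts().sort_index().items():
        rows.append(("error_distance", str(d), int(c) / len(records)))
    for r, c in records["rank"].value_counts().sort_index().items():
        rows.append(("rank", str(r), int(c) / len(records)))
    for k in top_ks:
        rows.append(("rank_le", str(k), float((records["rank"] <= k).mean())))
    rows.append(("relative_rank", "mean", float(records["relative_rank"].mean())))
    rows.append(("relative_rank", "median", float(records["relative_rank"].median())))
    rows.append(
        ("random_guess_distance", "mean",
         float(records["random_guess_distance"].replace(math.inf, np.nan).mean()))
    )
    return pd.DataFrame(rows, columns=["metric", "bin", "value"])
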