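# Methods

## Model

A network is a simple directed graph `G(V, E)` with weights
`w_ij ∈ (0, 1]`: the probability that an activation of `i` propagates along
`(i, j)`.  The Independent Cascade process starts with one active source at
time 0; at each step, every node activated at the previous step gets one
chance per outgoing edge to activate the target, independently with
probability `w`.  The process stops when a step activates nobody.  Because
each edge fires at most once with a fixed probability, the process is
distributionally identical to *live-edge sampling*: keep each edge
independently with probability `w`, then node `i` activates at time
`d_{G'}(source, i)`, its hop distance in the retained subgraph `G'`.  Both
forms are implemented (`cascade.simulate_ic`, `cascade.sample_live_edge` +
`cascade.trace_from_mask`) and the equivalence is verified by a
total-variation test against exhaustive enumeration.

Self-loops and parallel edges are rejected at load time: a self-loop never
changes reachability, and the model gives each directed edge exactly one
chance, so parallel edges are meaningless.  Node ids are opaque strings and
every ordering in the package (iteration, rank tie-breaks) is lexicographic
on the id, so all runs are reproducible under a fixed seed.

## The inference problem and the constrained chain

Given a snapshot `A_τ` (active nodes only, no times), the
maximum-likelihood source maximises
`Pr(A_τ | G, s, τ) = E_{G'}[I(A_τ = R(G', s, τ))]`.  Exact evaluation is
#P-complete — the `reduction` module is an executable proof, see below — and
naive live-edge sampling is useless because the indicator is zero for
almost every subgraph.  The `mcmc` module therefore samples the live-edge
law *restricted* to explaining subgraphs (those where some node reaches all
of `A_τ`), using Metropolis toggles of single edges:

* proposal: uniform over the universe's weight-<1 edges, toggle semantics;
* acceptance: `min(1, w/(1−w))` for an addition, `min(1, (1−w)/w)` for a
  removal, 0 if the result leaves the constrained space;
* a rejected proposal repeats the current state as a sample (required for
  the restricted law to be the stationary distribution — detailed balance
  is unit-tested on all in-space neighbour pairs of small instances);
* weight-1 edges are pinned present: their absence has probability zero, so
  proposing them would waste moves.  This pinning is also applied in the
  enumeration oracles, which makes the reduction gadget (whose auxiliary
  edges all have weight 1) enumerable over only its coin-flip edges.

The whole-graph sampler (`infer_source_basic`) counts, per candidate, how
often the candidate's `τ`-bounded reachable set equals `A_τ` exactly;
`count/K` estimates the restricted indicator expectation, proportional to
the likelihood with a candidate-independent constant.

## Reduction to the active-induced subgraph and unknown τ

Edges split into `E1` (inside `A_τ`), `E2` (leaving `A_τ`), `E3` (from
inactive nodes).  The snapshot condition factorises: it holds in `G'` iff
it holds in `G'_1 = G' ∩ G1` and no node activated strictly before `τ` has
a live `E2` edge (verified exhaustively in the test suite).  Consequently
the likelihood is proportional to an expectation over subgraphs of `G1`
only, of the indicator times the *deflation factor*: the probability
`∏(1−w)` over `E2` edges leaving nodes closer than `τ` to the candidate.
The proportionality constant is again candidate-independent; the test suite
checks it is constant to relative 1e-9 across candidates on random
instances (in practice it agrees to machine precision).

For a candidate `s` explaining a sampled `G'_1`, the deflation factor as a
function of `τ` takes only three values: 0 below the eccentricity `ε(s)`
(the farthest active node's distance), a partial boundary product at
`ε(s)`, and the full boundary product `W = ∏_{E2}(1−w)` for every larger
`τ`.  The reduced sampler (`infer_source_reduced`) therefore accumulates,
per candidate and per observed eccentricity, the partial products `A(s, ε)`
and visit counts `C(s, ε)`, and reconstructs

    est(s, τ) = (A(s, τ) + W · Σ_{τ' < τ} C(s, τ')) / K

for every `τ` at once.  A time range `[τ_l, τ_u]` is scored by summing
`est(s, τ)` uniformly over the integer times in the range clipped to
`[1, |A_τ|]` — a flat prior over admissible times, the least-informative
combination rule, which reduces exactly to the known-τ case when
`τ_l = τ_u`.  Clipping is sound because eccentricities cannot exceed
`|A_τ| − 1` and the likelihood is constant for `τ ≥ |A_τ|` (the cascade
must have terminated); both facts are property-tested.  `τ_l = 0` is
accepted and treated as `τ_l = 1` (a cascade observed at time 0 would be a
single node, which carries no ranking information); the reduced sampler
requires `|A_τ| ≥ 2` for the same reason.

Candidate sets are computed by strongly-connected-component condensation:
on `G1` the candidates are exactly the members of the condensation's unique
predecessor-free component (empty if there are several).  The public
`netcore.candidate_sources` uses networkx's condensation; the sampler's hot
loop uses a hand-written two-pass SCC over bitmask-filtered adjacency for
speed, and a property test keeps the two routes in agreement.

### Numerical and performance choices

* Chain state is an integer bitmask over the universe's edge list.
  Per-subgraph quantities (candidate set, eccentricities, deflation
  products) are memoised per visited mask (bounded cache, 2^19 entries,
  recompute-on-overflow); local-move revisits are the common case, so this
  changes no value while making a move cost ~1 µs on small universes.
* Burn-in defaults to 10× the universe's edge count; no thinning (every
  post-burn-in state is a sample).  Both are configurable; acceptance rates
  are reported for diagnostics.  No convergence diagnostic is built in —
  the stationarity test in the suite compares visit frequencies against the
  exact restricted law on enumerable instances (TV < 0.02 at K = 1e6).
* Randomness: one integer master seed; batch runs derive per-run streams by
  `numpy.random.SeedSequence` spawning, so run k of a batch is reproducible
  independently of the others.
* Probabilities are plain float products (exact `Fraction` products where
  the inputs are Fractions).  At the enumeration cap — 20 free edges,
  ~10^6 subgraphs, the default refusal threshold for all oracles — products
  of ≤ 20 validated-positive weights cannot underflow.
* Empty products are 1.0 (e.g. a candidate with no sub-eccentric boundary
  edges, or `E2 = ∅`, giving `W = 1`).

## Enumeration oracles

`exact` computes the same three quantities by brute force on small
instances: the snapshot probability (sum over all positive-probability
subgraphs), the restricted indicator expectation the whole-graph chain
estimates, and the reduced expectation over `G1` subgraphs.  These are the
ground truth for the sampler tests.  They refuse instances above the edge
cap rather than run forever; the hardness of the general problem is the
reason the Monte Carlo path exists at all.

## The hardness reduction as running code

`reduction` converts an s-t connectedness instance `Ĝ` (count the edge
subsets in which `t` is reachable from `s`; #P-complete) into a
source-inference instance: all original edges get weight 1/2; fresh nodes
`v, u` are wired as `t→v` (1), `v→u` (p), `u→s` (1) and `v→i` (1) for
every original node; the snapshot is all nodes at `τ = |V|`, so only
reachability matters.  On this gadget `Pr(A|G,v,τ) = Pr(A|G,t,τ) = p`,
every other original node scores strictly below `p`, and
`Pr(A|G,u,τ) = Connectedness · (1/2)^{|Ê|}`.  Binary search on dyadic `p`
with an exact-oracle argmax query per step recovers the count in at most
`|Ê| + 1` queries.  All gadget arithmetic uses `fractions.Fraction`, so
argmax ties are decided exactly.  The gadget construction is pinned down by
the three likelihood identities above, which the test suite verifies on
random instances — any wiring violating them fails the tests.

## Synthetic benchmark

`bench` emulates a snapshot-inference study on synthetic data, since the
package ships no external network.  Defaults and their reasons:

* **Networks**: directed Erdős–Rényi, bidirected Barabási–Albert, paths, or
  custom edge lists.  BA graphs keep each undirected edge in both
  directions so in-degree is well defined for weighting.
* **Weights**: `reciprocal_in_degree` (`w_ij = 1/indeg(j)`) by default —
  the standard convention for deriving influence probabilities from an
  unweighted directed social graph; uniform and uniform-random weightings
  are available for controlled experiments.
* **Trials**: uniform random source, one IC cascade, snapshot either
  post-termination (elapsed time recorded as `|A_τ|`, the conservative
  value once activity has stopped) or at a finite horizon.  Cascades with
  fewer than 2 active nodes or fewer than `min_candidates` candidate
  sources are redrawn; the filter default is 20 candidates, which discards
  trials the candidate filter alone would solve.  Retained trials always
  contain the true source in the candidate set (property-tested): every
  activation edge lies inside `G1`.
* **Metrics**: undirected shortest-path error distance, rank of the true
  source under the deterministic tie rule (descending score, then
  lexicographic id — ranks among tied scores are therefore reproducible but
  arbitrary), relative rank (rank / candidate-set size), and a
  uniform-over-`A_τ` random-guess baseline.

The acceptance script's benchmark uses a 150-node Erdős–Rényi network
(`p = 0.04`, reciprocal in-degree weights), 30 retained trials with the
≥ 20-candidate filter, and the reduced sampler at K = 2·10^5 samples per
trial — sizes chosen so the full script completes in minutes on one CPU
while keeping the chain long enough to rank ~35-candidate sets stably.
Oracle-anchored validation runs at K up to 10^6 on enumerable instances.

## What the synthetic generator does and does not show

The generator reproduces the *mechanics* of the study conditions — IC
cascades from uniformly drawn sources on directed weighted networks,
candidate filtering, snapshot-only observation with known or bounded
elapsed time.  It does not reproduce the degree distribution, clustering,
or community structure of a real 7000-node social network, and at
150 nodes the candidate sets are small relative to such a network's.
Passing tests therefore demonstrate correctness of the estimator and
sampler (they agree with exact enumeration wherever enumeration is
feasible) and plausible ranking behaviour at desk scale; they do not
certify accuracy rates on any particular real network.

## Known limitations

* Single source only; multiple simultaneous sources are out of scope.
* The basic whole-graph sampler scales with the full network and exists
  mainly as an oracle-checkable reference; use the reduced sampler for
  anything large.
* Mixing is not diagnosed automatically; for large `G1` spaces, sample
  counts must grow (the acceptance-rate log is the first thing to check).
* Observed snapshots are assumed exact — no missing or spurious actives.
* The enumeration oracles are exponential by design and refuse beyond the
  edge cap.
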