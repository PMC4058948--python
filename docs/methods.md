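# Methods

## Model

A probabilistic network is a directed graph `G = (V, E, P)` in which each
edge `e` exists independently with probability `P(e)`. Loaded networks
require `P(e) ∈ (0, 1]`; internally constructed networks (perturbation
replicates, certain-edge limits) may carry `P(e) ∈ [0, 1]`, with `P(e) = 0`
meaning the edge is certainly absent. Self-loops and parallel duplicate
edges are rejected at load time (duplicates can optionally be merged into
one edge with `p = 1 − Π(1 − p_k)`); an undirected input edge becomes two
independent directed events. Node identifiers are opaque, case-sensitive
strings. The independence assumption is the standard one for
confidence-weighted interaction networks; correlated edge events are out of
scope.

The core quantity is `p(s, t)`: the probability that at least one directed
path of existing edges leads from `s` to `t`. Only simple paths matter, so
edges entering `s` or leaving `t` can never contribute. `p(s, s)` is left
undefined (the library refuses `s == t`; profiles record such pairs as
missing) — a caller who needs a convention may treat it as 1.

## Separators and stages

An *s-t node separator* is a node set `K` whose removal leaves no directed
`s → t` path (by convention, any set containing `s` or `t` separates).
`K` splits the nodes into left nodes (reachable from `s` without entering
`K`), the separator, and right nodes (the rest), and the edges into left
edges `L(K)` (within left ∪ K), right edges, and backward edges (from a
right node into K or the left side). Since the left side is closed under
successors outside `K`, a left→right edge cannot exist and the three edge
classes are exhaustive. A separator with no backward edges is *good*: then
every route from `s` to a node of `K` lies entirely inside `L(K)`, which is
what permits stage-local computation.

A valid sequence `K_0 = {s}, …, K_{c+1} = {t}` of good separators (each
`K_j ∖ K_i` on the right of `K_i` for `i < j`) induces edge stages
`E_j = L(K_j) ∖ L(K_{j−1})` that partition the edge set. The pair-specific
pruning performed first — drop edges into `s` and out of `t`, then keep the
nodes reachable from `s` and co-reachable to `t` — guarantees that
`L(K_{c+1})` covers every remaining edge and that `{s}` and `{t}` are good.

## The collapsed polynomial

Each edge contributes `F_i = p_i x_i + q_i y_i` (present/absent,
`q_i = 1 − p_i`). Products of edge polynomials enumerate deterministic
configurations; the collapsing operator keeps that product tractable. At
separator `K_i` the state is `Σ_S β_S z_S` with
`β_S = p({s}, S, K_i)`: the probability that exactly the subset `S` of
`K_i` is reachable from the source (`z_∅` is the absorbing failure label).
Advancing one stage aggregates the stage's edges one at a time — each open
term splits into a present branch (coefficient × p) and an absent branch
(coefficient × q) — and after every aggregation applies the collapse rule:
a term collapses to `γ z_T` as soon as its decided edges determine the
reachable subset `T ⊆ K_{i+1}`, i.e. when the `K_{i+1}`-nodes reachable
from `S` through the decided-present edges coincide with those reachable
when every still-undecided edge is assumed present. Coefficients of equal
`z_T` merge, and collapsed terms absorb later edge polynomials unchanged
(`p + q = 1`). Determination is evaluated with two indicator functions on
the stage subgraph: χ (a path from `S` using only decided-present edges)
and ω (some minimal cut lies entirely inside the decided-absent set,
computed by the equivalent unreachability check). Both the coefficient sum
(≡ 1) and the worst-case term count `2^(|K_i| + |Θ|)` are invariants
checked in the tests.

Floating-point is plain double precision; the acceptance battery holds the
method to 1e-12 against the oracles on small instances. Exact rational
arithmetic (`exact=True`, CLI `--exact-rational`) is available for
verification.

### Stage evaluators

Two equivalent evaluators compute a stage. The *per-term* evaluator is the
literal polynomial algebra above. The *state-merging* evaluator, used
automatically for acyclic stages whose worst-case work exponent
(stage edges + log2 of carried terms) reaches 12, walks the stage's edges
grouped by tail in topological order — so a node's reached-status is final
before its outgoing edges are considered — and keeps terms merged whenever
their decided edges induce the same set of reached nodes; an edge whose
tail is unreached is absorbed outright. This is the same
coefficient-summing the collapsing operator performs at separator
boundaries, applied continuously, and produces identical stage outputs
(asserted by a dual-route test on random stages). Pruned edges are
re-indexed in topological order (SCC-condensation order for cyclic inputs)
so that the fixed ascending-index aggregation order resolves node statuses
as early as possible.

## Choosing separators

Any valid sequence gives the same probability (a tested invariance), but
sizes differ. The greedy search starts at `{s}` and repeatedly takes as
candidate the nodes one edge beyond the territory already passed. A
candidate with backward edges is repaired: a backward edge whose head lies
in the candidate pushes that node one hop forward; one that bypasses the
candidate (head already passed) pulls its tail into the candidate. If this
push-forward loop revisits a candidate set, a second repair absorbs
backward-edge tails monotonically, which always terminates with a good —
possibly large — separator; a lexicographic trimming pass then drops nodes
whose removal keeps the set a good separator. Intermediate separators are
therefore not guaranteed minimal; correctness never depends on it. When the
frontier reaches `t`, or no further progress is possible, the sequence
closes with `{t}` and all remaining edges form the final stage. Optimal
sequence search is a non-goal.

Ties are broken lexicographically throughout, so sequences are
deterministic and reproducible.

## Oracles

Two independent exponential references certify the method: exhaustive
enumeration of all `2^n` edge configurations (default cap 20 edges) and
inclusion–exclusion over all simple s-t paths (default cap 18 paths).
Exceeding a cap is an error, never a silent truncation. Both agree with
each other and with the collapsing method to 1e-12 across randomized
batteries of cyclic, randomly weighted networks.

## Downstream analyses

**Profiles.** `R[i, j] = p(s_i, t_j)` for source/target lists; self pairs
are missing (NaN), unreachable pairs are exactly 0. Entries are
independent single-pair computations, so evaluation order is irrelevant.

**Centrality.** `Σ_s Σ_t [p(s,t) − p_ḡ(s,t)]` with gene `g` and its
incident edges removed; the sum is the expected number of source–target
pairs for which `g` is indispensable, and is non-negative because node
removal only removes routes. When `g` is itself a source or target the
post-removal probability of its pairs is taken as 0 — the gene can no
longer send or receive — which keeps the centrality of hub sources
meaningful; `skip_self_pairs=True` excludes those pairs instead. All
values are emitted; any display threshold is left to the consumer.

**Stability.** For each of `replicates` (default 20) rounds, every edge
probability is redrawn uniformly from `[p − δ, p + δ] ∩ [0, 1]` (a point
interval returns its point), the profile recomputed, and
`|p^δ(s,t) − p(s,t)|` averaged over pairs; the replicate means are then
averaged. Per-replicate RNG streams derive from (seed, replicate index),
so results are reproducible and independent of evaluation order. `δ = 0`
yields exactly 0; the mean change trends upward in δ.

## Synthetic networks

The generator produces preferential-attachment (scale-free) networks —
the standard topology model for biological networks — with the edge count
pinned to exactly twice the node count: a 3-node seed star, m = 2
attachments per new node (the repeated-nodes scheme, attachment probability
proportional to degree), and uniformly random extra non-duplicate edges to
make up the remaining four. Each edge receives an independent probability
uniform on `(prob_low, prob_high]`, default `(0, 1]` — an uninformative
default, exposed as a knob.

Orientation is the one genuinely consequential choice. The default,
`orientation="age"`, directs every edge from the older to the newer node,
giving a layered acyclic network in the spirit of the hierarchical
decomposition of regulatory networks (top-layer regulators reaching
transcription-factor layers below). The alternative `"random"` orients
each edge by coin flip, but at a few hundred nodes this produces a giant
strongly connected component, inside which *no* good separator exists (any
split of a strongly connected set leaves a backward edge), so exact
computation — by this or any method — degenerates to configuration
enumeration. The layered default is what makes millisecond-scale
single-pair queries on 300-node networks possible and is the study
condition used by the scalability checks. Age-layered networks are sparse
in reachable pairs (a random pair is usually disconnected); analyses that
need rich profiles should take early (hub) nodes as sources.

What the generator does not emulate: confidence values estimated from
expression data, correlated edge probabilities, or the specific in/out
degree laws of any real TRN. Passing tests certify the algorithm's
exactness and scaling on layered scale-free topologies, not biological
conclusions about any particular organism's network.

## Problem sizes used in the checks

The randomized verification battery uses 200 networks of 4–8 nodes and
3–12 edges (small enough for the 2^n oracle while covering cycles,
disconnection and probability extremes). The scalability check samples 75
ordered pairs — a third from the best-connected hub, the rest uniform — on
a 300-node, 600-edge generated network, the largest size in the synthetic
design. The stability curve uses a 50-node network, 3 hub sources × 6
targets, 20 replicates per δ. These sizes are the package's own choice of
a representative, quickly reproducible battery; all are parameters, not
limits.

## Known limitations

- Exactness is up to double rounding unless `exact=True`.
- Worst-case cost remains exponential in stage width; dense strongly
  connected regions (e.g. randomly oriented networks) are intractable by
  nature of the #P-complete problem, not by implementation.
- Edge events are independent; undirected edges become two independent
  directed events, with no correlation modelled.
- The greedy sequence is heuristic: good, not optimal, separators.
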