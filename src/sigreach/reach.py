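"""Exact s-t reachability probability by polynomial collapsing.

Each edge e_i contributes a first-degree polynomial p_i·x_i + q_i·y_i
(present / absent, q_i = 1 − p_i).  The product of the edge polynomials of
an edge set enumerates its deterministic configurations, one term per
configuration, with the coefficient equal to the configuration probability.
Evaluated naively this is the 2^n enumeration that makes the problem
#P-hard.

The divide-and-conquer step works stage by stage along a sequence of good
node separators K_0 = {s}, K_1, …, K_{c+1} = {t}.  At separator K the state
of the computation is a *collapsed* polynomial Σ_S β_S·z_S where z_S stands
for the event "exactly the subset S ⊆ K is reachable from the source" and
β_S is its probability.  Advancing to the next separator aggregates the
stage's edge polynomials one edge at a time; as soon as a term's partial
edge assignment fully determines which subset T of the next separator is
reachable, the term collapses to β·z_T, and coefficients of identical z_T
merge.  Collapsed terms absorb later edge polynomials unchanged
(β·z_T·(p x + q y) → β·z_T since p + q = 1).  After the final stage the
polynomial is γ_{t}·z_{t} + γ_∅·z_∅ and γ_{t} is the s-t reachability
probability.

Whether a term is determined is decided by two indicator functions on the
stage subgraph: χ_{S,u}(I) = 1 iff u is reachable from S using only the
edges decided present (I); ω_{S,v}(A) = 1 iff some minimal S-v edge cut lies
entirely inside the decided-absent set A — equivalently, v is unreachable
from S even if every not-yet-decided edge turns out to be present.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .network import (
    DeterministicNetwork,
    NetworkValidationError,
    ProbabilisticNetwork,
    maximal_deterministic,
    prune_for_pair,
)
from .separators import SeparatorSequence, greedy_separator_sequence

__all__ = [
    "Stage",
    "StagePolynomial",
    "chi",
    "omega",
    "c_indicator",
    "aggregate_edge",
    "collapse",
    "advance_stage",
    "reachability_probability",
    "reachability_report",
]

_EMPTY: frozenset = frozenset()


@dataclass
class Stage:
    """Context for one stage: consecutive separators and the edges between.

    ``edge_order`` lists the stage's edge indices in ascending order; they
    are aggregated in that order.  ``adj`` is the stage subgraph's adjacency
    (node -> list of (head, edge index)) restricted to stage edges.
    """

    K_prev: frozenset[str]
    K_next: frozenset[str]
    edge_order: tuple[int, ...]
    adj: dict[str, list[tuple[str, int]]]
    p: Mapping[int, float | Fraction]

    @classmethod
    def from_network(
        cls,
        net: ProbabilisticNetwork,
        K_prev: Iterable[str],
        K_next: Iterable[str],
        stage_edges: Iterable[int],
        exact: bool = False,
    ) -> "Stage":
        idx = frozenset(stage_edges)
        adj: dict[str, list[tuple[str, int]]] = {}
        probs: dict[int, float | Fraction] = {}
        for e in net.edges:
            if e.index in idx:
                adj.setdefault(e.source, []).append((e.target, e.index))
                probs[e.index] = Fraction(e.p) if exact else e.p
        return cls(
            K_prev=frozenset(K_prev),
            K_next=frozenset(K_next),
            edge_order=tuple(sorted(idx)),
            adj=adj,
            p=probs,
        )

    def reach_closure(self, seeds: frozenset[str], allowed: frozenset[int]) -> frozenset[str]:
        """Nodes reachable from ``seeds`` using only stage edges in ``allowed``."""
        seen = set(seeds)
        queue = deque(seeds)
        while queue:
            u = queue.popleft()
            for v, i in self.adj.get(u, ()):
                if i in allowed and v not in seen:
                    seen.add(v)
                    queue.append(v)
        return frozenset(seen)


def chi(stage_or_net, S: Iterable[str], u: str, I: Iterable[int]) -> int:
    """Path indicator χ_{S,u}(I): 1 iff u is reachable from some node of S
    via edges whose indices all lie in I.  A node of S reaches itself by the
    empty path."""
    S = frozenset(S)
    I = frozenset(I)
    if isinstance(stage_or_net, Stage):
        return int(u in stage_or_net.reach_closure(S, I))
    adj = _det_adj(stage_or_net)
    return int(u in _closure(adj, S, I))


def omega(stage_or_net, S: Iterable[str], v: str, absent: Iterable[int]) -> int:
    """Cut indicator ω_{S,v}(absent): 1 iff for every s' ∈ S some minimal
    s'-v edge cut lies inside ``absent`` — operationally, v is unreachable
    from S once the edges in ``absent`` are removed."""
    S = frozenset(S)
    absent = frozenset(absent)
    if isinstance(stage_or_net, Stage):
        allowed = frozenset(stage_or_net.edge_order) - absent
        return int(v not in stage_or_net.reach_closure(S, allowed))
    adj = _det_adj(stage_or_net)
    allowed = frozenset(e.index for e in stage_or_net.edges) - absent
    return int(v not in _closure(adj, S, allowed))


def _det_adj(detnet: DeterministicNetwork) -> dict[str, list[tuple[str, int]]]:
    adj: dict[str, list[tuple[str, int]]] = {}
    for e in detnet.edges:
        adj.setdefault(e.source, []).append((e.target, e.index))
    return adj


def _closure(adj, seeds: frozenset[str], allowed: frozenset[int]) -> frozenset[str]:
    seen = set(seeds)
    queue = deque(seeds)
    while queue:
        u = queue.popleft()
        for v, i in adj.get(u, ()):
            if i in allowed and v not in seen:
                seen.add(v)
                queue.append(v)
    return frozenset(seen)


def c_indicator(
    stage: Stage,
    S: Iterable[str],
    T: Iterable[str],
    I: Iterable[int],
    theta: Iterable[int],
) -> int:
    """T-reachability indicator C_{S,T}(I) = Π_{u∈T} χ_{S,u}(I) ·
    Π_{v∈K_next∖T} ω_{S,v}(Θ∖I).  At most one T evaluates to 1 for a fixed
    (S, I)."""
    S = frozenset(S)
    T = frozenset(T)
    I = frozenset(I)
    theta = frozenset(theta)
    for u in T:
        if not chi(stage, S, u, I):
            return 0
    for v in stage.K_next - T:
        if not omega(stage, S, v, theta - I):
            return 0
    return 1


@dataclass
class StagePolynomial:
    """Sparse edge-aggregation polynomial during one stage.

    ``open_terms`` maps (S, I) -> coefficient for uncollapsed terms: S ⊆
    K_prev is the carried z_S label, I ⊆ theta the stage edges decided
    present (absent = theta − I, shared by all open terms).  ``collapsed``
    maps T ⊆ K_next (or ∅, the failure label) -> coefficient.  Coefficients
    are non-negative and sum to 1: every aggregation splits p + q = 1 and
    every collapse only moves mass between keys.
    """

    stage: Stage
    stage_index: int = 0
    theta: frozenset[int] = _EMPTY
    open_terms: dict[tuple[frozenset[str], frozenset[int]], float] = field(default_factory=dict)
    collapsed: dict[frozenset[str], float] = field(default_factory=dict)

    def coefficient_sum(self):
        return sum(self.open_terms.values()) + sum(self.collapsed.values())

    @property
    def n_terms(self) -> int:
        return len(self.open_terms) + len(self.collapsed)


def aggregate_edge(poly: StagePolynomial, edge_index: int, p=None) -> StagePolynomial:
    """Multiply the edge polynomial p·x + (1−p)·y of one stage edge in.

    Every open term splits into a present branch (coefficient × p, index
    joining I and Θ) and an absent branch (coefficient × (1−p)); collapsed
    z_T terms absorb the factor unchanged.  Zero-coefficient branches are
    dropped immediately.  Mutates and returns ``poly``.
    """
    if edge_index in poly.theta:
        raise ValueError(f"edge {edge_index} already aggregated in this stage")
    if edge_index not in poly.stage.p:
        raise ValueError(f"edge {edge_index} is not part of this stage")
    if p is None:
        p = poly.stage.p[edge_index]
    q = 1 - p
    new_terms: dict[tuple[frozenset[str], frozenset[int]], float] = {}
    for (S, I), coef in poly.open_terms.items():
        if p != 0:
            key = (S, I | {edge_index})
            new_terms[key] = new_terms.get(key, 0) + coef * p
        if q != 0:
            new_terms[(S, I)] = new_terms.get((S, I), 0) + coef * q
    poly.open_terms = new_terms
    poly.theta = poly.theta | {edge_index}
    return poly


def collapse(poly: StagePolynomial, stage: Stage | None = None) -> StagePolynomial:
    """Apply the collapsing operator ρ to every open term.

    A term γ·x_I·y_{Θ∖I}·z_S collapses to γ·z_T when the reachable subset
    T of the next separator is already determined, i.e. the nodes of K_next
    reachable from S through the present edges I coincide with those still
    reachable when every undecided edge is added.  Undetermined terms stay.
    Mutates and returns ``poly``.
    """
    stage = stage or poly.stage
    undecided = frozenset(stage.edge_order) - poly.theta
    keep: dict[tuple[frozenset[str], frozenset[int]], float] = {}
    for (S, I), coef in poly.open_terms.items():
        pessimistic = stage.reach_closure(S, I)
        optimistic = stage.reach_closure(S, I | undecided)
        T = frozenset(pessimistic & stage.K_next)
        if frozenset(optimistic & stage.K_next) == T:
            poly.collapsed[T] = poly.collapsed.get(T, 0) + coef
        else:
            keep[(S, I)] = coef
    poly.open_terms = keep
    return poly


#: acyclic stages whose worst-case per-term work exponent (stage edges plus
#: log2 of the carried term count) reaches this use the state-merging
#: evaluator instead of the per-term algebra
_FAST_STAGE_MIN_EXPONENT = 12


def _stage_topo_order(stage: Stage) -> list[str] | None:
    """Topological node order of the stage subgraph, or None if cyclic."""
    nodes = set(stage.K_prev) | set(stage.K_next)
    for u, outs in stage.adj.items():
        nodes.add(u)
        nodes.update(v for v, _ in outs)
    indeg = {v: 0 for v in nodes}
    for u, outs in stage.adj.items():
        for v, _ in outs:
            indeg[v] += 1
    import heapq

    ready = [v for v in nodes if indeg[v] == 0]
    heapq.heapify(ready)
    order: list[str] = []
    while ready:
        v = heapq.heappop(ready)
        order.append(v)
        for w, _ in stage.adj.get(v, ()):
            indeg[w] -= 1
            if indeg[w] == 0:
                heapq.heappush(ready, w)
    return order if len(order) == len(nodes) else None


def _advance_stage_frontier(
    prev: Mapping[frozenset[str], float],
    stage: Stage,
    order: list[str],
    stage_index: int = 0,
    trace: list | None = None,
    check_conservation: bool = False,
) -> dict[frozenset[str], float]:
    """State-merging evaluation of one acyclic stage.

    Produces exactly the same γ_T = p({s}, T, K_next) as the per-term
    algebra: it walks the stage's edges grouped by tail in topological
    order, so a node's reached-status is final before any of its outgoing
    edges is considered, and keeps terms merged whenever their decided
    edges induce the same set of reached nodes.  An edge whose tail is not
    reached is absorbed outright (p + q = 1), and a node's flag is
    projected away once all its outgoing edges are decided — the same
    coefficient-summing that the collapsing operator applies at separator
    boundaries, applied continuously.
    """
    zero_key: frozenset[str] = _EMPTY
    gamma: dict[frozenset[str], float] = {}
    if zero_key in prev and prev[zero_key] != 0:
        gamma[zero_key] = prev[zero_key]
    states: dict[frozenset[str], float] = {}
    for S, coef in prev.items():
        if coef == 0 or not S:
            continue
        states[S] = states.get(S, 0) + coef
    for v in order:
        outs = sorted(stage.adj.get(v, ()), key=lambda x: x[1])
        for w, j in outs:
            p = stage.p[j]
            q = 1 - p
            new: dict[frozenset[str], float] = {}
            for st, coef in states.items():
                if v in st and w not in st:
                    if p != 0:
                        key = st | {w}
                        new[key] = new.get(key, 0) + coef * p
                    if q != 0:
                        new[st] = new.get(st, 0) + coef * q
                else:
                    # tail unreached or head already reached: p + q absorbed
                    new[st] = new.get(st, 0) + coef
            states = new
            if check_conservation:
                total = sum(states.values()) + sum(gamma.values())
                _check_total(total)
            if trace is not None:
                trace.append((f"stage{stage_index}:e{j}", len(states), len(gamma)))
        if v not in stage.K_next:
            new = {}
            for st, coef in states.items():
                key = st - {v}
                new[key] = new.get(key, 0) + coef
            states = new
    for st, coef in states.items():
        T = frozenset(st & stage.K_next)
        gamma[T] = gamma.get(T, 0) + coef
    return gamma


def _check_total(total) -> None:
    if isinstance(total, Fraction):
        ok = total == 1
    else:
        ok = abs(total - 1.0) <= 1e-12
    if not ok:
        raise RuntimeError(f"coefficient sum {total} drifted from 1")


def advance_stage(
    prev: Mapping[frozenset[str], float],
    stage: Stage,
    stage_index: int = 0,
    trace: list | None = None,
    check_conservation: bool = False,
    method: str = "auto",
) -> dict[frozenset[str], float]:
    """Fold one stage: from β_S = p({s}, S, K_prev) to γ_T = p({s}, T, K_next).

    ``prev`` must be fully collapsed (keys are subsets of K_prev; the empty
    set z_∅ is the absorbing failure label and is carried through
    unchanged).  Edges are aggregated in ascending index order with a
    collapse pass after each.  ``trace`` collects per-step term counts as
    (step, n_open, n_collapsed) tuples.

    ``method`` selects the evaluator: ``"terms"`` is the per-term
    polynomial algebra, ``"frontier"`` the equivalent state-merging walk
    (acyclic stages only), and ``"auto"`` (default) picks ``"frontier"``
    for large acyclic stages and ``"terms"`` otherwise.
    """
    for S in prev:
        if not S <= stage.K_prev:
            raise ValueError(
                f"previous polynomial key {sorted(S)} is not a subset of K_prev"
            )
    if method not in ("auto", "terms", "frontier"):
        raise ValueError(f"unknown method {method!r}")
    work_exponent = len(stage.edge_order) + max(0, len(prev) - 1).bit_length()
    if method == "frontier" or (
        method == "auto" and work_exponent >= _FAST_STAGE_MIN_EXPONENT
    ):
        order = _stage_topo_order(stage)
        if order is not None:
            return _advance_stage_frontier(
                prev, stage, order, stage_index=stage_index, trace=trace,
                check_conservation=check_conservation,
            )
        if method == "frontier":
            raise ValueError("frontier evaluation requires an acyclic stage")
    poly = StagePolynomial(stage=stage, stage_index=stage_index)
    for S, coef in prev.items():
        if coef == 0:
            continue
        if S:
            poly.open_terms[(S, _EMPTY)] = coef
        else:
            poly.collapsed[_EMPTY] = poly.collapsed.get(_EMPTY, 0) + coef
    one = Fraction(1) if isinstance(next(iter(stage.p.values()), 1.0), Fraction) else 1.0
    collapse(poly)
    if trace is not None:
        trace.append((f"stage{stage_index}:init", len(poly.open_terms), len(poly.collapsed)))
    for step, j in enumerate(stage.edge_order, start=1):
        aggregate_edge(poly, j)
        if check_conservation:
            _assert_conserved(poly, one)
        collapse(poly)
        if check_conservation:
            _assert_conserved(poly, one)
        if trace is not None:
            trace.append((f"stage{stage_index}:e{j}", len(poly.open_terms), len(poly.collapsed)))
    if poly.open_terms:  # cannot happen once Θ covers the stage
        raise RuntimeError("stage finished with uncollapsed terms")
    return dict(poly.collapsed)


def _assert_conserved(poly: StagePolynomial, one) -> None:
    total = poly.coefficient_sum()
    if isinstance(one, Fraction):
        ok = total == 1
    else:
        ok = abs(total - 1.0) <= 1e-12
    if not ok:
        raise RuntimeError(f"coefficient sum {total} drifted from 1")


def _fold(
    net: ProbabilisticNetwork,
    s: str,
    t: str,
    seq: SeparatorSequence,
    exact: bool,
    trace: list | None,
    check_conservation: bool,
) -> dict[frozenset[str], float]:
    coeffs: dict[frozenset[str], float] = {
        frozenset({s}): Fraction(1) if exact else 1.0
    }
    for i, stage_edges in enumerate(seq.stages, start=1):
        stage = Stage.from_network(
            net, seq.separators[i - 1], seq.separators[i], stage_edges, exact=exact
        )
        coeffs = advance_stage(
            coeffs, stage, stage_index=i, trace=trace, check_conservation=check_conservation
        )
    return coeffs


def reachability_probability(
    net: ProbabilisticNetwork,
    s: str,
    t: str,
    sequence: SeparatorSequence | None = None,
    exact: bool = False,
    trace: list | None = None,
    check_conservation: bool = False,
):
    """Probability that a signal from ``s`` reaches ``t``.

    The network is pruned to the nodes that can lie on an s-t route, a
    greedy good-separator sequence is built, and the collapsed polynomial is
    folded across the stages; the coefficient of z_{t} in the final
    two-term polynomial is returned.  ``exact=True`` computes with rational
    arithmetic.  A caller may supply an explicit ``sequence`` (referring to
    ``net``'s own edge indices; pruning is then skipped) — any valid
    sequence yields the same probability.
    """
    if s == t:
        raise NetworkValidationError("source and target must differ")
    if s not in net.nodes or t not in net.nodes:
        missing = s if s not in net.nodes else t
        raise NetworkValidationError(f"node {missing!r} not in network")
    if sequence is not None:
        coeffs = _fold(net, s, t, sequence, exact, trace, check_conservation)
        result = coeffs.get(frozenset({t}), Fraction(0) if exact else 0.0)
        return result if exact else min(1.0, max(0.0, float(result)))
    pruned = prune_for_pair(net, s, t)
    if not any(e.source == s for e in pruned.edges):
        return Fraction(0) if exact else 0.0
    seq = greedy_separator_sequence(pruned, s, t)
    coeffs = _fold(pruned, s, t, seq, exact, trace, check_conservation)
    result = coeffs.get(frozenset({t}), Fraction(0) if exact else 0.0)
    if exact:
        return result
    return min(1.0, max(0.0, float(result)))


def reachability_report(
    net: ProbabilisticNetwork, s: str, t: str, exact: bool = False
) -> dict:
    """reachability_probability plus the separator sequence and size trace."""
    trace: list = []
    if s == t:
        raise NetworkValidationError("source and target must differ")
    pruned = prune_for_pair(net, s, t)
    if not any(e.source == s for e in pruned.edges):
        return {
            "probability": 0.0,
            "separators": [[s], [t]],
            "trace": [],
            "n_pruned_nodes": pruned.n_nodes,
            "n_pruned_edges": pruned.n_edges,
        }
    seq = greedy_separator_sequence(pruned, s, t)
    coeffs = _fold(pruned, s, t, seq, exact, trace, False)
    prob = float(coeffs.get(frozenset({t}), 0.0))
    return {
        "probability": prob,
        "separators": [sorted(K) for K in seq.separators],
        "trace": trace,
        "n_pruned_nodes": pruned.n_nodes,
        "n_pruned_edges": pruned.n_edges,
    }
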