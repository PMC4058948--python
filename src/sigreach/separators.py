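"""Node-separator machinery for s-t reachability.

An s-t node separator is a node set K whose removal leaves no directed path
from the source s to the target t.  A separator splits the nodes into *left*
nodes (reachable from s without entering K), the separator itself, and
*right* nodes (everything else), and correspondingly splits the edges into
left edges L(K) (both endpoints in left ∪ K), right edges (within the right
part, or separator -> right), and backward edges (right -> separator or
right -> left).  A separator with no backward edges is *good*; good
separators are what makes stage-by-stage computation of reachability sound,
because then every route from s to a separator node lives entirely inside
L(K).

The greedy sequence search advances a frontier of nodes one hop beyond the
current separator, repairing frontiers that have incident backward edges by
pushing the offending nodes one hop forward, until the target is reached.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Mapping, Sequence

from .network import DetEdge, DeterministicNetwork, ProbabilisticNetwork, maximal_deterministic

__all__ = [
    "SeparatorPartition",
    "SeparatorSequence",
    "SeparatorError",
    "classify",
    "is_separator",
    "is_good",
    "is_minimal",
    "theorem1_holds",
    "greedy_separator_sequence",
    "trivial_separator_sequence",
    "validate_sequence",
]


class SeparatorError(ValueError):
    """A node set fails a separator precondition."""


@dataclass(frozen=True)
class SeparatorPartition:
    """Node and edge classes induced by an s-t separator K."""

    separator: frozenset[str]
    left_nodes: frozenset[str]
    right_nodes: frozenset[str]
    left_edges: frozenset[int]
    right_edges: frozenset[int]
    backward_edges: frozenset[int]


@dataclass(frozen=True)
class SeparatorSequence:
    """Ordered good separators K_0..K_{c+1} with their induced edge stages.

    ``separators[0] == {s}`` and ``separators[-1] == {t}``.  Stage ``j``
    (1-based) is ``L(K_j) \\ L(K_{j-1})``: the edges that first become left
    edges at separator j.  Stages are pairwise disjoint and cover all edges.
    """

    separators: tuple[frozenset[str], ...]
    stages: tuple[frozenset[int], ...]

    @property
    def n_stages(self) -> int:
        return len(self.stages)


def _reachable_avoiding(
    adj: Mapping[str, list[DetEdge]], start: str, blocked: frozenset[str]
) -> set[str]:
    """Nodes reachable from ``start`` without entering ``blocked``.

    ``start`` itself is included only if it is not blocked.
    """
    if start in blocked:
        return set()
    seen = {start}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for e in adj[u]:
            v = e.target
            if v not in seen and v not in blocked:
                seen.add(v)
                queue.append(v)
    return seen


def is_separator(
    detnet: DeterministicNetwork, s: str, t: str, K: frozenset[str] | set[str]
) -> bool:
    """True iff deleting K leaves no directed s->t path.

    By convention K containing s or t separates (supports the boundary
    separators K_0 = {s} and K_{c+1} = {t}).
    """
    K = frozenset(K)
    if s in K or t in K:
        return True
    adj = detnet.successors()
    return t not in _reachable_avoiding(adj, s, K)


def classify(
    detnet: DeterministicNetwork, s: str, t: str, K: frozenset[str] | set[str]
) -> SeparatorPartition:
    """Partition nodes and edges of ``detnet`` by the separator ``K``.

    Left nodes are those reachable from s without entering K (empty when
    s ∈ K); right nodes are the rest.  No left -> right edge can exist, so
    every edge is left, right or backward.
    """
    K = frozenset(K)
    if not is_separator(detnet, s, t, K):
        raise SeparatorError(f"{sorted(K)} is not an {s}-{t} separator")
    adj = detnet.successors()
    left = frozenset(_reachable_avoiding(adj, s, K))
    right = frozenset(detnet.nodes - left - K)
    left_e, right_e, back_e = set(), set(), set()
    for e in detnet.edges:
        u, v = e.source, e.target
        if u in right:
            if v in right:
                right_e.add(e.index)
            else:  # right -> separator or right -> left
                back_e.add(e.index)
        elif u in K and v in right:
            right_e.add(e.index)
        else:
            # u in left ∪ K with v in left ∪ K; left -> right is impossible
            # because left is closed under successors outside K.
            left_e.add(e.index)
    return SeparatorPartition(
        separator=K,
        left_nodes=left,
        right_nodes=right,
        left_edges=frozenset(left_e),
        right_edges=frozenset(right_e),
        backward_edges=frozenset(back_e),
    )


def is_good(partition: SeparatorPartition) -> bool:
    """A separator is good when it induces no backward edges."""
    return not partition.backward_edges


def is_minimal(
    detnet: DeterministicNetwork, s: str, t: str, K: frozenset[str] | set[str]
) -> bool:
    """True iff no proper subset of K is an s-t separator.

    Any superset of a separator (avoiding s and t) is a separator, so it
    suffices to test the subsets obtained by dropping one node.
    """
    K = frozenset(K)
    if not is_separator(detnet, s, t, K):
        raise SeparatorError(f"{sorted(K)} is not an {s}-{t} separator")
    if not K:
        return True
    for v in K:
        if is_separator(detnet, s, t, K - {v}):
            return False
    return True


def theorem1_holds(
    detnet: DeterministicNetwork, s: str, t: str, K: frozenset[str] | set[str]
) -> bool:
    """Check that K also separates s from every right node of K.

    This must hold for every valid separator; it exists as a test utility.
    """
    part = classify(detnet, s, t, K)
    return all(is_separator(detnet, s, u, part.separator) for u in part.right_nodes)


def _left_edge_set(detnet: DeterministicNetwork, s: str, t: str, K: frozenset[str]) -> frozenset[int]:
    return classify(detnet, s, t, K).left_edges


def trivial_separator_sequence(
    net: ProbabilisticNetwork, s: str, t: str
) -> SeparatorSequence:
    """The single-stage sequence ({s}, {t}): always valid, possibly slow."""
    all_edges = frozenset(e.index for e in net.edges)
    return SeparatorSequence(
        separators=(frozenset({s}), frozenset({t})),
        stages=(all_edges,),
    )


def validate_sequence(
    net: ProbabilisticNetwork, s: str, t: str, seq: SeparatorSequence
) -> None:
    """Raise SeparatorError if ``seq`` violates any sequence invariant."""
    det = maximal_deterministic(net)
    seps = seq.separators
    if seps[0] != frozenset({s}):
        raise SeparatorError("sequence must start with {s}")
    if seps[-1] != frozenset({t}):
        raise SeparatorError("sequence must end with {t}")
    parts = []
    for K in seps:
        part = classify(det, s, t, K)
        if part.backward_edges:
            raise SeparatorError(f"separator {sorted(K)} is not good")
        parts.append(part)
    for i in range(len(seps)):
        for j in range(i + 1, len(seps)):
            extra = seps[j] - seps[i]
            if extra - parts[i].right_nodes:
                raise SeparatorError(
                    f"nodes {sorted(extra - parts[i].right_nodes)} of separator {j}"
                    f" are not right nodes of separator {i}"
                )
    prev = frozenset()
    covered: set[int] = set()
    for j, (part, stage) in enumerate(zip(parts[1:], seq.stages), start=1):
        if not prev <= part.left_edges:
            raise SeparatorError(f"left edge sets not nested at stage {j}")
        if stage != part.left_edges - prev:
            raise SeparatorError(f"stage {j} does not match L(K_j) \\ L(K_{j-1})")
        if covered & stage:
            raise SeparatorError(f"stage {j} overlaps an earlier stage")
        covered |= stage
        prev = part.left_edges
    if covered != {e.index for e in net.edges}:
        raise SeparatorError("stages do not cover the edge set")


def _repair_push_forward(
    det: DeterministicNetwork,
    adj: Mapping[str, list[DetEdge]],
    s: str,
    t: str,
    candidate: frozenset[str],
    interior: frozenset[str],
) -> frozenset[str] | None:
    """Repair a candidate separator by pushing nodes one hop forward.

    A backward edge whose head sits in the candidate marks that node for
    replacement by its one-hop successors; a backward edge that bypasses
    the candidate (head already in passed territory) pulls its tail, a
    right node, into the candidate.  Returns a good separator, or None if
    the iteration revisits a candidate, swallows t, or loses the separator
    property.
    """
    seen: set[frozenset[str]] = set()
    while True:
        if candidate in seen or not candidate or t in candidate:
            return None
        seen.add(candidate)
        if not is_separator(det, s, t, candidate):
            return None
        part = classify(det, s, t, candidate)
        if not part.backward_edges:
            return candidate
        heads_in_candidate: set[str] = set()
        orphan_tails: set[str] = set()
        for i in part.backward_edges:
            e = det.edges[i - 1]
            if e.target in candidate:
                heads_in_candidate.add(e.target)
            else:
                orphan_tails.add(e.source)
        grown = set(candidate) | orphan_tails
        for v in sorted(heads_in_candidate):
            grown.discard(v)
            for e in adj[v]:
                if e.target not in interior:
                    grown.add(e.target)
        candidate = frozenset(grown)


def _repair_absorb_tails(
    det: DeterministicNetwork, s: str, t: str, candidate: frozenset[str]
) -> frozenset[str] | None:
    """Repair by absorbing every backward-edge tail into the candidate.

    Tails are right nodes, so the candidate grows monotonically and stays a
    separator; in a pruned network t has no outgoing edges and is never a
    tail, so this always terminates with a good (possibly large) separator.
    The caller's trimming pass then shrinks it again.
    """
    while True:
        part = classify(det, s, t, candidate)
        if not part.backward_edges:
            return candidate
        tails = frozenset(det.edges[i - 1].source for i in part.backward_edges)
        if t in tails:
            return None
        grown = candidate | tails
        if grown == candidate:
            return None
        candidate = grown


def greedy_separator_sequence(
    net: ProbabilisticNetwork, s: str, t: str
) -> SeparatorSequence:
    """Greedy search for a sequence of good separators between s and t.

    ``net`` must already be pruned for the pair (every edge on some s-t
    route).  Starting from K_0 = {s}, the candidate next separator is the
    set of nodes one edge beyond the current separator and the territory
    already passed.  While a candidate node has an incident backward edge,
    it is replaced by its one-hop successors.  The first good candidate is
    trimmed towards minimality and accepted.  When the frontier reaches t,
    the sequence closes with K_{c+1} = {t}; if the repair loop revisits a
    candidate or a candidate stops being a separator, the sequence also
    closes with {t}, putting all remaining edges in one final stage (always
    correct, possibly slower).
    """
    if s == t:
        raise SeparatorError("source and target must differ")
    det = maximal_deterministic(net)
    adj = det.successors()
    all_edges = frozenset(e.index for e in det.edges)

    seps: list[frozenset[str]] = [frozenset({s})]
    left_edge_sets: list[frozenset[int]] = [_left_edge_set(det, s, t, seps[0])]
    passed: frozenset[str] = frozenset()  # left nodes of the current separator

    while True:
        K = seps[-1]
        interior = passed | K
        candidate = frozenset(
            e.target for u in interior for e in adj[u] if e.target not in interior
        )
        if not candidate or t in candidate:
            break
        accepted = _repair_push_forward(det, adj, s, t, candidate, interior)
        if accepted is None:
            accepted = _repair_absorb_tails(det, s, t, candidate)
        if accepted is None:
            break
        # trim towards minimality: drop nodes (lexicographic scan) while the
        # set stays a good separator advancing past the current one
        for v in sorted(accepted):
            smaller = accepted - {v}
            if not smaller or not is_separator(det, s, t, smaller):
                continue
            p2 = classify(det, s, t, smaller)
            if p2.backward_edges or (smaller & (passed | K)):
                continue
            accepted = smaller
        part = classify(det, s, t, accepted)
        new_left_edges = part.left_edges
        if not (left_edge_sets[-1] < new_left_edges) or (accepted & interior):
            break  # no progress or overlap with passed territory: close with {t}
        seps.append(accepted)
        left_edge_sets.append(new_left_edges)
        passed = part.left_nodes

    seps.append(frozenset({t}))
    left_edge_sets.append(all_edges)
    stages = tuple(
        left_edge_sets[i] - left_edge_sets[i - 1] for i in range(1, len(seps))
    )
    seq = SeparatorSequence(separators=tuple(seps), stages=stages)
    validate_sequence(net, s, t, seq)
    return seq
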