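"""Probabilistic network data model, validation, edge-list I/O and pruning.

A probabilistic network is a directed graph in which every edge exists
independently with a given probability.  A network with ``n`` probabilistic
edges therefore represents ``2**n`` deterministic topologies; the quantities
computed elsewhere in this package (reachability probabilities, profiles,
centralities) are expectations over that ensemble.

Edge lists are plain text: ``source target probability``, one edge per line,
``#`` comments and blank lines ignored.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Edge",
    "DetEdge",
    "ProbabilisticNetwork",
    "DeterministicNetwork",
    "NetworkValidationError",
    "EdgeListParseError",
    "load_network",
    "write_network",
    "maximal_deterministic",
    "prune_for_pair",
    "remove_node",
]


class NetworkValidationError(ValueError):
    """A network violates a structural or probability constraint."""


class EdgeListParseError(ValueError):
    """An edge-list line could not be parsed."""


@dataclass(frozen=True)
class Edge:
    """A directed probabilistic edge.

    ``index`` is 1-based and unique within a network.  ``p`` is the
    probability that the edge (interaction) actually exists.  Loaded
    networks require ``0 < p <= 1``; networks built internally (e.g. by the
    perturbation analysis) may carry ``p == 0``, which is treated as an
    edge that is certainly absent.
    """

    index: int
    source: str
    target: str
    p: float


@dataclass(frozen=True)
class DetEdge:
    """A directed edge of a deterministic network (no probability)."""

    index: int
    source: str
    target: str


def _check_structure(edges: Sequence, nodes: set[str]) -> None:
    seen_pairs: set[tuple[str, str]] = set()
    seen_idx: set[int] = set()
    for e in edges:
        if e.source == e.target:
            raise NetworkValidationError(f"self-loop on node {e.source!r}")
        pair = (e.source, e.target)
        if pair in seen_pairs:
            raise NetworkValidationError(f"duplicate edge {e.source!r} -> {e.target!r}")
        seen_pairs.add(pair)
        if e.index in seen_idx:
            raise NetworkValidationError(f"duplicate edge index {e.index}")
        seen_idx.add(e.index)
        if e.source not in nodes or e.target not in nodes:
            raise NetworkValidationError(
                f"edge {e.index} references a node missing from the node set"
            )
    if edges and sorted(seen_idx) != list(range(1, len(edges) + 1)):
        raise NetworkValidationError("edge indices must be contiguous starting at 1")


@dataclass(frozen=True)
class ProbabilisticNetwork:
    """Directed graph with an independent existence probability per edge."""

    nodes: frozenset[str]
    edges: tuple[Edge, ...]
    name: str | None = None
    #: maps this network's edge index -> edge index in the network it was
    #: derived from (identity for freshly loaded networks).
    original_index: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_structure(self.edges, set(self.nodes))
        for e in self.edges:
            if not (0.0 <= e.p <= 1.0):
                raise NetworkValidationError(
                    f"edge {e.index} has probability {e.p} outside [0, 1]"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def successors(self) -> dict[str, list[Edge]]:
        adj: dict[str, list[Edge]] = {v: [] for v in self.nodes}
        for e in self.edges:
            adj[e.source].append(e)
        return adj

    def edge_probability(self) -> dict[int, float]:
        return {e.index: e.p for e in self.edges}

    def with_probabilities(self, p: Mapping[int, float]) -> "ProbabilisticNetwork":
        """Return a copy whose edge ``i`` carries probability ``p[i]``."""
        new_edges = tuple(replace(e, p=float(p[e.index])) for e in self.edges)
        return replace(self, edges=new_edges)


@dataclass(frozen=True)
class DeterministicNetwork:
    """Structure-only view of a network (the maximal deterministic network)."""

    nodes: frozenset[str]
    edges: tuple[DetEdge, ...]

    def __post_init__(self) -> None:
        _check_structure(self.edges, set(self.nodes))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def successors(self) -> dict[str, list[DetEdge]]:
        adj: dict[str, list[DetEdge]] = {v: [] for v in self.nodes}
        for e in self.edges:
            adj[e.source].append(e)
        return adj

    def predecessors(self) -> dict[str, list[DetEdge]]:
        adj: dict[str, list[DetEdge]] = {v: [] for v in self.nodes}
        for e in self.edges:
            adj[e.target].append(e)
        return adj


def build_network(
    edge_spec: Iterable[tuple[str, str, float]],
    name: str | None = None,
    extra_nodes: Iterable[str] = (),
    merge_duplicates: bool = False,
) -> ProbabilisticNetwork:
    """Construct a validated network from ``(source, target, p)`` triples.

    With ``merge_duplicates`` parallel edges on the same ordered pair are
    merged into one edge with combined probability ``1 - prod(1 - p_k)``
    (probability that at least one of the parallel interactions exists).
    """
    merged: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    for src, dst, p in edge_spec:
        pair = (src, dst)
        if pair in merged:
            if not merge_duplicates:
                raise NetworkValidationError(f"duplicate edge {src!r} -> {dst!r}")
            merged[pair] = 1.0 - (1.0 - merged[pair]) * (1.0 - p)
        else:
            merged[pair] = p
            order.append(pair)
    edges = tuple(
        Edge(i + 1, src, dst, merged[(src, dst)])
        for i, (src, dst) in enumerate(order)
    )
    nodes = frozenset(extra_nodes) | {e.source for e in edges} | {e.target for e in edges}
    return ProbabilisticNetwork(
        nodes=nodes,
        edges=edges,
        name=name,
        original_index={e.index: e.index for e in edges},
    )


def load_network(
    path: str | Path,
    undirected: bool = False,
    merge_duplicates: bool = False,
    name: str | None = None,
) -> ProbabilisticNetwork:
    """Read a whitespace-separated edge list into a ProbabilisticNetwork.

    Each non-comment line is ``source target probability`` with
    ``0 < probability <= 1``.  With ``undirected=True`` every line yields two
    directed edges in opposite directions, each carrying the line's
    probability and treated as independent events.
    """
    path = Path(path)
    triples: list[tuple[str, str, float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 3 fields, got {len(fields)}"
                )
            src, dst, ptxt = fields
            try:
                p = float(ptxt)
            except ValueError as exc:
                raise EdgeListParseError(
                    f"{path}:{lineno}: cannot parse probability {ptxt!r}"
                ) from exc
            if not (0.0 < p <= 1.0):
                raise NetworkValidationError(
                    f"{path}:{lineno}: probability {p} outside (0, 1]"
                )
            if src == dst:
                raise NetworkValidationError(f"{path}:{lineno}: self-loop on {src!r}")
            triples.append((src, dst, p))
            if undirected:
                triples.append((dst, src, p))
    return build_network(
        triples, name=name or path.stem, merge_duplicates=merge_duplicates
    )


def write_network(net: ProbabilisticNetwork, path: str | Path, header: str | None = None) -> None:
    """Write a tab-separated edge list with 17 significant digits."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for e in net.edges:
            fh.write(f"{e.source}\t{e.target}\t{e.p:.17g}\n")


def load_node_list(path: str | Path) -> list[str]:
    """Read a node-list file: one identifier per line, '#' comments ignored."""
    out: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def maximal_deterministic(net: ProbabilisticNetwork) -> DeterministicNetwork:
    """Drop probabilities: the topology in which every edge is present."""
    return DeterministicNetwork(
        nodes=net.nodes,
        edges=tuple(DetEdge(e.index, e.source, e.target) for e in net.edges),
    )


def _reachable(adj: Mapping[str, list], start: str) -> set[str]:
    seen = {start}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for e in adj[u]:
            if e.target not in seen:
                seen.add(e.target)
                queue.append(e.target)
    return seen


def _coreachable(radj: Mapping[str, list], start: str) -> set[str]:
    seen = {start}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for e in radj[u]:
            if e.source not in seen:
                seen.add(e.source)
                queue.append(e.source)
    return seen


def _toposort_edges(edges: list, nodes: set[str]) -> list:
    """Order edges by a topological order of their tail nodes.

    Uses the topological order of strongly connected components (node order
    within a component, and the relative order of parallel candidates, falls
    back to the input order).  Downstream stage computations aggregate edges
    in ascending index order, so a topological numbering lets node statuses
    resolve — and polynomial terms collapse — as early as possible.
    """
    index = {v: i for i, v in enumerate(sorted(nodes))}
    n = len(index)
    succ: dict[int, set[int]] = {i: set() for i in range(n)}
    for e in edges:
        succ[index[e.source]].add(index[e.target])
    # Tarjan-free SCC via iterative Kosaraju
    order: list[int] = []
    seen = [False] * n
    for root in range(n):
        if seen[root]:
            continue
        stack = [(root, iter(succ[root]))]
        seen[root] = True
        while stack:
            v, it = stack[-1]
            advanced = False
            for w in it:
                if not seen[w]:
                    seen[w] = True
                    stack.append((w, iter(succ[w])))
                    advanced = True
                    break
            if not advanced:
                order.append(v)
                stack.pop()
    pred: dict[int, set[int]] = {i: set() for i in range(n)}
    for u, ws in succ.items():
        for w in ws:
            pred[w].add(u)
    comp = [-1] * n
    ncomp = 0
    for v in reversed(order):
        if comp[v] != -1:
            continue
        stack = [v]
        comp[v] = ncomp
        while stack:
            u = stack.pop()
            for w in pred[u]:
                if comp[w] == -1:
                    comp[w] = ncomp
                    stack.append(w)
        ncomp += 1
    # Kosaraju (reversed finish order on the transpose) numbers components
    # in topological order of the condensation.
    rank = {e.index: pos for pos, e in enumerate(edges)}
    return sorted(
        edges,
        key=lambda e: (comp[index[e.source]], comp[index[e.target]], rank[e.index]),
    )


def prune_for_pair(net: ProbabilisticNetwork, s: str, t: str) -> ProbabilisticNetwork:
    """Restrict ``net`` to the part that can carry an s-t signal.

    Keeps the nodes that are reachable from ``s`` and from which ``t`` is
    reachable in the maximal deterministic network (``s`` and ``t`` are always
    retained).  Edges entering ``s`` or leaving ``t`` are dropped first: no
    simple s-t route uses them, so the reachability probability is unchanged,
    and their removal guarantees that after pruning every remaining edge lies
    on some s-t route.  Edge indices are re-assigned contiguously; the
    mapping back to the input indices is kept in ``original_index``.
    """
    if s not in net.nodes:
        raise NetworkValidationError(f"source node {s!r} not in network")
    if t not in net.nodes:
        raise NetworkValidationError(f"target node {t!r} not in network")
    kept_edges = [e for e in net.edges if e.target != s and e.source != t]
    adj: dict[str, list[Edge]] = {v: [] for v in net.nodes}
    radj: dict[str, list[Edge]] = {v: [] for v in net.nodes}
    for e in kept_edges:
        adj[e.source].append(e)
        radj[e.target].append(e)
    keep = (_reachable(adj, s) & _coreachable(radj, t)) | {s, t}
    final = [e for e in kept_edges if e.source in keep and e.target in keep]
    final = _toposort_edges(final, keep)
    new_edges = tuple(
        Edge(i + 1, e.source, e.target, e.p) for i, e in enumerate(final)
    )
    orig = {
        i + 1: net.original_index.get(e.index, e.index)
        for i, e in enumerate(final)
    }
    return ProbabilisticNetwork(
        nodes=frozenset(keep),
        edges=new_edges,
        name=net.name,
        original_index=orig,
    )


def remove_node(net: ProbabilisticNetwork, g: str) -> ProbabilisticNetwork:
    """Delete node ``g`` together with all incident edges, re-indexing edges."""
    if g not in net.nodes:
        raise NetworkValidationError(f"node {g!r} not in network")
    final = [e for e in net.edges if g not in (e.source, e.target)]
    new_edges = tuple(
        Edge(i + 1, e.source, e.target, e.p) for i, e in enumerate(final)
    )
    orig = {
        i + 1: net.original_index.get(e.index, e.index)
        for i, e in enumerate(final)
    }
    return ProbabilisticNetwork(
        nodes=frozenset(net.nodes - {g}),
        edges=new_edges,
        name=net.name,
        original_index=orig,
    )
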