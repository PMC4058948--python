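"""Reference implementations for certifying the collapsing algorithm.

Both oracles are exponential and exist only for verification on small
instances: exhaustive enumeration of the 2^n edge configurations, and the
inclusion-exclusion sum over simple s-t paths.
"""

from __future__ import annotations

import networkx as nx

from .network import NetworkValidationError, ProbabilisticNetwork

__all__ = [
    "OracleCapError",
    "brute_force_reachability",
    "inclusion_exclusion_reachability",
]


class OracleCapError(ValueError):
    """Instance too large for an exponential oracle."""


def brute_force_reachability(
    net: ProbabilisticNetwork, s: str, t: str, max_edges: int = 20
) -> float:
    """Sum configuration probabilities over all 2^n edge subsets with an
    s->t path.

    A network with n probabilistic edges represents exactly 2^n
    deterministic configurations; each contributes
    prod(p_i, present) * prod(1-p_i, absent) if t is reachable from s in it.
    """
    if s not in net.nodes or t not in net.nodes:
        raise NetworkValidationError("source or target not in network")
    n = net.n_edges
    if n > max_edges:
        raise OracleCapError(
            f"{n} edges exceeds the {max_edges}-edge enumeration cap; "
            "use the collapsing algorithm (sigreach.reach) instead"
        )
    edges = net.edges
    total = 0.0
    for mask in range(1 << n):
        prob = 1.0
        adj: dict[str, list[str]] = {}
        for k, e in enumerate(edges):
            if mask >> k & 1:
                prob *= e.p
                adj.setdefault(e.source, []).append(e.target)
            else:
                prob *= 1.0 - e.p
        if prob == 0.0:
            continue
        # DFS for an s->t path in this configuration
        stack, seen = [s], {s}
        found = s == t
        while stack and not found:
            u = stack.pop()
            for v in adj.get(u, ()):
                if v == t:
                    found = True
                    break
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if found:
            total += prob
    return total


def count_configurations(net: ProbabilisticNetwork) -> int:
    """Number of deterministic configurations the network represents."""
    return 1 << net.n_edges


def enumerate_simple_paths(
    net: ProbabilisticNetwork, s: str, t: str
) -> list[frozenset[int]]:
    """All simple directed s->t paths, each as its set of edge indices."""
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for e in net.edges:
        g.add_edge(e.source, e.target, index=e.index)
    if s not in g or t not in g:
        raise NetworkValidationError("source or target not in network")
    paths = []
    for edge_path in nx.all_simple_edge_paths(g, s, t):
        paths.append(frozenset(g.edges[u, v]["index"] for u, v in edge_path))
    return paths


def inclusion_exclusion_reachability(
    net: ProbabilisticNetwork, s: str, t: str, max_paths: int = 18
) -> float:
    """Inclusion-exclusion over simple s->t paths.

    P(some path fully present) = Σ_{∅≠Q⊆paths} (−1)^{|Q|+1} Π_{e ∈ ∪Q} p_e.
    Only simple paths matter: any walk that reaches t contains a simple
    path, so cycles need no special handling.
    """
    paths = enumerate_simple_paths(net, s, t)
    k = len(paths)
    if k > max_paths:
        raise OracleCapError(
            f"{k} simple paths exceed the {max_paths}-path cap; "
            "use the collapsing algorithm (sigreach.reach) instead"
        )
    if k == 0:
        return 0.0
    p = net.edge_probability()
    # union[mask] = edge-index union of the selected paths, built via lowbit
    union: list[frozenset[int]] = [frozenset()] * (1 << k)
    total = 0.0
    for mask in range(1, 1 << k):
        low = mask & -mask
        union[mask] = union[mask ^ low] | paths[low.bit_length() - 1]
        prod = 1.0
        for i in union[mask]:
            prod *= p[i]
        total += prod if bin(mask).count("1") % 2 else -prod
    return total
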