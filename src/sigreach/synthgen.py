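"""Synthetic probabilistic networks: scale-free generation and tiny fixtures.

Scale-free (preferential attachment) networks are the de facto model for
the topology of biological networks; the generator fixes the edge count at
exactly twice the node count so that network size is the single knob.  The
named fixtures are small hand-built networks with known closed-form or
enumerable reachability probabilities, used throughout the test-suite and
the documentation.
"""

from __future__ import annotations

import numpy as np

from .network import ProbabilisticNetwork, build_network

__all__ = ["barabasi_albert", "fixture", "FIXTURE_NAMES"]


def barabasi_albert(
    n_nodes: int,
    seed: int = 0,
    prob_low: float = 0.0,
    prob_high: float = 1.0,
    orientation: str = "age",
) -> ProbabilisticNetwork:
    """Directed scale-free network with exactly ``2 * n_nodes`` edges.

    Preferential attachment with m = 2 links per incoming node, grown from
    a 3-node star; because classic preferential attachment on n nodes with
    m = 2 yields only 2n − 4 edges, uniformly random extra non-duplicate
    edges are appended to reach exactly 2n.  Each edge gets an independent
    probability drawn uniformly from (prob_low, prob_high].  Fully
    reproducible from ``seed``.

    ``orientation`` controls how each undirected attachment becomes a
    directed edge.  The default ``"age"`` orients every edge from the older
    to the newer node, giving an acyclic, layered network like the
    hierarchical regulatory networks the analysis targets — and the layering
    is what lets the separator-based computation run in milliseconds.
    ``"random"`` orients each edge uniformly at random instead; note that
    this creates a giant strongly connected component, inside which no good
    node separator exists, so exact reachability on large random-orientation
    networks is intractable for any method.
    """
    if n_nodes < 5:
        raise ValueError("need at least 5 nodes")
    if not (0.0 <= prob_low <= prob_high <= 1.0) or prob_high <= 0:
        raise ValueError("need 0 <= prob_low <= prob_high <= 1 with prob_high > 0")
    if orientation not in ("age", "random"):
        raise ValueError("orientation must be 'age' or 'random'")
    rng = np.random.default_rng(seed)
    target_edges = 2 * n_nodes

    pairs: list[tuple[int, int]] = [(0, 1), (0, 2)]  # seed star on 3 nodes
    pair_set = {frozenset(p) for p in pairs}
    # repeated-nodes trick: attachment probability proportional to degree
    repeated: list[int] = [0, 1, 0, 2]
    for new in range(3, n_nodes):
        chosen: set[int] = set()
        while len(chosen) < 2:
            chosen.add(int(repeated[rng.integers(len(repeated))]))
        for old in sorted(chosen):
            pairs.append((new, old))
            pair_set.add(frozenset((new, old)))
            repeated.extend((new, old))
    while len(pairs) < target_edges:
        u, v = (int(x) for x in rng.integers(n_nodes, size=2))
        if u == v or frozenset((u, v)) in pair_set:
            continue
        pairs.append((u, v))
        pair_set.add(frozenset((u, v)))

    triples = []
    for u, v in pairs:
        if orientation == "age":
            if u > v:  # node index is creation order: older -> newer
                u, v = v, u
        elif rng.random() < 0.5:
            u, v = v, u
        p = prob_high - rng.random() * (prob_high - prob_low)  # in (low, high]
        triples.append((f"n{u}", f"n{v}", float(p)))
    net = build_network(triples, name=f"ba{n_nodes}_seed{seed}")
    assert net.n_edges == target_edges
    return net


FIXTURE_NAMES = ("series3", "parallel2", "bridge5", "fig2", "fig3")

_FIXTURE_EDGES: dict[str, list[tuple[str, str]]] = {
    # chain s -> a -> t: reachability p^2
    "series3": [("s", "a"), ("a", "t")],
    # two node-disjoint 2-edge routes: 1 - (1 - p^2)^2
    "parallel2": [("s", "a"), ("a", "t"), ("s", "b"), ("b", "t")],
    # the 5-edge directed bridge; 15 of the 32 configurations connect s to t
    "bridge5": [("s", "a"), ("s", "b"), ("a", "t"), ("b", "t"), ("a", "b")],
    # 8-node network around the separator {4, 5}: left nodes {1,2,3}, left
    # edges {e1,e2,e3,e5,e6}, backward edges {e4,e8}; {e3,e5} is a minimal
    # 1-8 cut and e2,e5,e6,e7,e10 form a 1->8 path
    "fig2": [
        ("1", "2"),  # e1
        ("1", "3"),  # e2
        ("2", "4"),  # e3
        ("6", "2"),  # e4
        ("3", "4"),  # e5
        ("4", "5"),  # e6
        ("5", "6"),  # e7
        ("7", "4"),  # e8
        ("4", "7"),  # e9
        ("6", "8"),  # e10
        ("7", "8"),  # e11
    ],
    # layered DAG with two disjoint 1-7 separators {2,3} and {4,5,6}
    "fig3": [
        ("1", "2"),
        ("1", "3"),
        ("2", "4"),
        ("2", "5"),
        ("3", "5"),
        ("3", "6"),
        ("4", "7"),
        ("5", "7"),
        ("6", "7"),
    ],
}

#: conventional (source, target) pair of each fixture
FIXTURE_PAIRS = {
    "series3": ("s", "t"),
    "parallel2": ("s", "t"),
    "bridge5": ("s", "t"),
    "fig2": ("1", "8"),
    "fig3": ("1", "7"),
}


def fixture(name: str, p: float = 0.5) -> ProbabilisticNetwork:
    """Return a named fixture network with probability ``p`` on every edge."""
    if name not in _FIXTURE_EDGES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    triples = [(u, v, p) for u, v in _FIXTURE_EDGES[name]]
    return build_network(triples, name=name)
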