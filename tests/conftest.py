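"""Shared fixtures: deterministic random-network factories."""

from __future__ import annotations

import random

import pytest

from sigreach.network import ProbabilisticNetwork, build_network


def random_network(
    rng: random.Random,
    n_nodes_range: tuple[int, int] = (4, 8),
    n_edges_range: tuple[int, int] = (3, 12),
    p_range: tuple[float, float] = (0.05, 1.0),
) -> ProbabilisticNetwork:
    """A random directed network; may be cyclic, may be disconnected."""
    n_nodes = rng.randint(*n_nodes_range)
    nodes = [f"v{i}" for i in range(n_nodes)]
    n_edges = rng.randint(*n_edges_range)
    n_edges = min(n_edges, n_nodes * (n_nodes - 1))
    pairs: set[tuple[str, str]] = set()
    while len(pairs) < n_edges:
        u, v = rng.sample(nodes, 2)
        pairs.add((u, v))
    triples = [(u, v, rng.uniform(*p_range)) for u, v in sorted(pairs)]
    return build_network(triples, extra_nodes=nodes)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20140611)


@pytest.fixture
def random_net_factory(rng):
    def factory(**kwargs) -> ProbabilisticNetwork:
        return random_network(rng, **kwargs)

    return factory
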