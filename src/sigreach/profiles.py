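"""Downstream analyses built on reachability probabilities.

* The **reachability profile** of a network is the sources × targets matrix
  R with R[i, j] the probability that a signal from source i reaches target
  j; it characterises the signalling state of a network as a whole.
* **Gene centrality** is the total drop in the profile caused by removing
  one node: summed over all source-target pairs it is the expected number
  of pairs for which that node is indispensable.
* **Network stability** is the mean absolute change in reachability when
  every edge probability is independently perturbed uniformly within ±δ
  (clipped to [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import NetworkValidationError, ProbabilisticNetwork, remove_node
from .reach import reachability_probability

__all__ = [
    "ReachabilityProfile",
    "StabilityResult",
    "pair_count",
    "compute_profile",
    "gene_centrality",
    "network_stability",
]


def pair_count(sources: Sequence[str], targets: Sequence[str]) -> int:
    """Number of ordered source-target pairs with source != target.

    |S|·|T| minus the pairs where the same node appears on both sides
    (e.g. all 300 nodes as both sources and targets -> 300·299 = 89 700
    pairs; 9 sources and 88 disjoint targets -> 8 712 pairs).
    """
    return len(sources) * len(targets) - len(set(sources) & set(targets))


@dataclass(frozen=True)
class ReachabilityProfile:
    """Sources × targets matrix of reachability probabilities.

    Entries for pairs with source == target are NaN (recorded as missing:
    self-reachability is left undefined).
    """

    sources: tuple[str, ...]
    targets: tuple[str, ...]
    R: np.ndarray

    @property
    def n_pairs(self) -> int:
        return pair_count(self.sources, self.targets)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.R, index=list(self.sources), columns=list(self.targets))


@dataclass(frozen=True)
class StabilityResult:
    """Outcome of the probability-perturbation experiment."""

    delta: float
    replicates: int
    mean_abs_change: float
    per_replicate: tuple[float, ...]
    seed: int


def _check_nodes(net: ProbabilisticNetwork, names: Sequence[str]) -> None:
    for v in names:
        if v not in net.nodes:
            raise NetworkValidationError(f"node {v!r} not in network")


def compute_profile(
    net: ProbabilisticNetwork,
    sources: Sequence[str],
    targets: Sequence[str],
) -> ReachabilityProfile:
    """R[i, j] = P(signal from sources[i] reaches targets[j])."""
    _check_nodes(net, sources)
    _check_nodes(net, targets)
    R = np.full((len(sources), len(targets)), np.nan)
    for i, s in enumerate(sources):
        for j, t in enumerate(targets):
            if s == t:
                continue
            R[i, j] = reachability_probability(net, s, t)
    return ReachabilityProfile(tuple(sources), tuple(targets), R)


def gene_centrality(
    net: ProbabilisticNetwork,
    sources: Sequence[str],
    targets: Sequence[str],
    g: str,
    skip_self_pairs: bool = False,
) -> float:
    """Total profile drop caused by deleting node ``g``.

    centrality(g) = Σ_s Σ_t [p(s,t) − p_ḡ(s,t)], the expected number of
    source-target pairs for which g is indispensable.  For pairs in which g
    is itself the source or the target the post-removal probability is
    taken as 0 (the gene can no longer send or receive); pass
    ``skip_self_pairs=True`` to exclude those pairs instead.  Always >= 0
    because deleting a node can only remove routes.
    """
    if g not in net.nodes:
        raise NetworkValidationError(f"node {g!r} not in network")
    base = compute_profile(net, sources, targets)
    reduced_net = remove_node(net, g)
    total = 0.0
    for i, s in enumerate(base.sources):
        for j, t in enumerate(base.targets):
            if s == t:
                continue
            before = base.R[i, j]
            if g in (s, t):
                after = 0.0 if not skip_self_pairs else before
            else:
                after = reachability_probability(reduced_net, s, t)
            total += before - after
    return total


def perturb_probabilities(
    net: ProbabilisticNetwork, delta: float, rng: np.random.Generator
) -> ProbabilisticNetwork:
    """Redraw every edge probability uniformly from [p−δ, p+δ] ∩ [0, 1]."""
    new_p = {}
    for e in net.edges:
        lo = max(0.0, e.p - delta)
        hi = min(1.0, e.p + delta)
        new_p[e.index] = lo if hi == lo else float(rng.uniform(lo, hi))
    return net.with_probabilities(new_p)


def network_stability(
    net: ProbabilisticNetwork,
    sources: Sequence[str],
    targets: Sequence[str],
    delta: float,
    replicates: int = 20,
    seed: int = 0,
) -> StabilityResult:
    """Mean absolute reachability change under ±δ probability perturbation.

    For each replicate a perturbed network G^δ is drawn (each edge
    probability independently uniform on [p−δ, p+δ] ∩ [0, 1]) and
    |p^δ(s,t) − p(s,t)| is averaged over all source-target pairs; the
    replicate means are then averaged.  Per-replicate RNG streams are
    derived from (seed, replicate index), so results do not depend on
    evaluation order.
    """
    if not (0.0 <= delta <= 1.0):
        raise ValueError(f"delta {delta} outside [0, 1]")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    base = compute_profile(net, sources, targets)
    mask = ~np.isnan(base.R)
    per_rep = []
    for rep in range(replicates):
        rng = np.random.default_rng([seed, rep])
        if delta == 0.0:
            per_rep.append(0.0)
            continue
        perturbed = perturb_probabilities(net, delta, rng)
        pr = compute_profile(perturbed, sources, targets)
        diffs = np.abs(pr.R[mask] - base.R[mask])
        per_rep.append(float(diffs.mean()) if diffs.size else 0.0)
    return StabilityResult(
        delta=float(delta),
        replicates=replicates,
        mean_abs_change=float(np.mean(per_rep)),
        per_replicate=tuple(per_rep),
        seed=seed,
    )
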